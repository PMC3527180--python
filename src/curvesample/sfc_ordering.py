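"""Space-filling-curve ordering of forest pixels.

A self-similar curve visits every cell of a square grid exactly once with
consecutive cells edge-adjacent, mapping the 2-D pixel lattice onto a 1-D
"number line" that preserves spatial locality: pixels close on the line
are close on the ground.  The forest pixels, taken in curve-visit order,
form the ordinal population list that the tessellation module segments.

Two curve families are provided behind the same contract: the base-3
serpentine Peano curve (default) and the base-2 Hilbert curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .geodata import EmptyDomainError, ForestGrid

__all__ = [
    "CurveOrder",
    "PixelOrder",
    "peano_curve",
    "hilbert_curve",
    "order_forest_pixels",
    "write_pixel_order",
]

#: refuse to materialize curves with more cells than this
MAX_CURVE_CELLS = 200_000_000

# Peano generator: boustrophedon visit order of the 3x3 block grid,
# down column 0, up column 1, down column 2.
_PEANO_GENERATOR = [
    (0, 0), (1, 0), (2, 0),
    (2, 1), (1, 1), (0, 1),
    (0, 2), (1, 2), (2, 2),
]


@dataclass(frozen=True)
class CurveOrder:
    """A space-filling curve over a ``side`` × ``side`` grid.

    ``rows``/``cols`` give the (row, col) of the t-th visited cell.
    """

    level: int
    side: int
    rows: np.ndarray
    cols: np.ndarray

    @property
    def visit_sequence(self) -> list[tuple[int, int]]:
        return list(zip(self.rows.tolist(), self.cols.tolist()))


@dataclass(frozen=True)
class PixelOrder:
    """Forest pixels of a grid in curve-visit order (the number line)."""

    rows: np.ndarray
    cols: np.ndarray
    level: int
    curve: str = "peano"

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def positions(self) -> list[tuple[int, int]]:
        return list(zip(self.rows.tolist(), self.cols.tolist()))


@lru_cache(maxsize=None)
def _peano_arrays(level: int) -> tuple[np.ndarray, np.ndarray]:
    if level == 0:
        return np.zeros(1, dtype=np.int64), np.zeros(1, dtype=np.int64)
    pr, pc = _peano_arrays(level - 1)
    side = 3 ** (level - 1)
    rows = np.empty(9 ** level, dtype=np.int64)
    cols = np.empty(9 ** level, dtype=np.int64)
    m = 9 ** (level - 1)
    for t, (br, bc) in enumerate(_PEANO_GENERATOR):
        # reflect the sub-curve so endpoints meet across block boundaries:
        # odd block-row flips columns, odd block-column flips rows
        rr = side - 1 - pr if bc % 2 else pr
        cc = side - 1 - pc if br % 2 else pc
        rows[t * m : (t + 1) * m] = br * side + rr
        cols[t * m : (t + 1) * m] = bc * side + cc
    return rows, cols


def peano_curve(level: int) -> CurveOrder:
    """The serpentine Peano curve on a ``3**level``-side grid.

    Built recursively from the 3×3 boustrophedon generator with
    reflections chosen so that consecutive cells are always 4-adjacent,
    including across sub-block boundaries.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if 9 ** level > MAX_CURVE_CELLS:
        raise MemoryError(
            f"Peano curve at level {level} has {9 ** level} cells "
            f"(cap {MAX_CURVE_CELLS})"
        )
    rows, cols = _peano_arrays(level)
    return CurveOrder(level=level, side=3 ** level, rows=rows, cols=cols)


@lru_cache(maxsize=None)
def _hilbert_arrays(level: int) -> tuple[np.ndarray, np.ndarray]:
    # iterative bitwise construction of the Hilbert curve (d -> (x, y))
    n = 2 ** level
    d = np.arange(n * n, dtype=np.int64)
    x = np.zeros_like(d)
    y = np.zeros_like(d)
    t = d.copy()
    s = 1
    while s < n:
        rx = 1 & (t // 2)
        ry = 1 & (t ^ rx)
        # rotate quadrant
        flip = ry == 0
        swap_mask = flip & (rx == 1)
        x_f = np.where(swap_mask, s - 1 - x, x)
        y_f = np.where(swap_mask, s - 1 - y, y)
        x, y = np.where(flip, y_f, x_f), np.where(flip, x_f, y_f)
        x = x + s * rx
        y = y + s * ry
        t //= 4
        s *= 2
    return y, x  # (row, col)


def hilbert_curve(level: int) -> CurveOrder:
    """The Hilbert curve on a ``2**level``-side grid (same contract as Peano)."""
    if level < 0:
        raise ValueError("level must be >= 0")
    if 4 ** level > MAX_CURVE_CELLS:
        raise MemoryError(f"Hilbert curve at level {level} exceeds the size cap")
    rows, cols = _hilbert_arrays(level)
    return CurveOrder(level=level, side=2 ** level, rows=rows, cols=cols)


def order_forest_pixels(grid: ForestGrid, curve: str = "peano") -> PixelOrder:
    """Order the forest pixels of ``grid`` along a space-filling curve.

    The grid is embedded in the smallest curve square covering
    ``max(n_rows, n_cols)``, anchored at the grid's top-left, and the full
    curve order is restricted to forest pixels.  Deterministic: no
    randomness enters here.
    """
    if grid.n_forest == 0:
        raise EmptyDomainError("cannot order an empty forest mask")
    extent = max(grid.n_rows, grid.n_cols)
    if curve == "peano":
        level = 0
        while 3 ** level < extent:
            level += 1
        full = peano_curve(level)
    elif curve == "hilbert":
        level = 0
        while 2 ** level < extent:
            level += 1
        full = hilbert_curve(level)
    else:
        raise ValueError(f"unknown curve family {curve!r}")
    rows, cols = full.rows, full.cols
    in_grid = (rows < grid.n_rows) & (cols < grid.n_cols)
    rows, cols = rows[in_grid], cols[in_grid]
    forest = grid.mask[rows, cols]
    return PixelOrder(rows=rows[forest], cols=cols[forest], level=level, curve=curve)


def write_pixel_order(path: Union[str, Path], order: PixelOrder) -> None:
    """Export the number line as CSV (ordinal, row, col) for audit/plots."""
    pd.DataFrame(
        {"ordinal": np.arange(len(order)), "row": order.rows, "col": order.cols}
    ).to_csv(path, index=False)
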