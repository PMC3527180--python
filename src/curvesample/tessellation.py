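"""Equal-length segmentation of the pixel number line.

Dividing the curve-ordered list of N forest pixels into n contiguous
segments of l pixels each (n = floor(N/l), remainder dropped) tessellates
the domain into equal-area — though not equal-shape — sample cells.  The
constraint that every cell must contain at least one lidar shot caps the
sample size: we search for the smallest l, over all rotations of the
(circular) line, for which every segment holds a shot.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .geodata import ForestGrid, write_ascii_grid
from .sfc_ordering import PixelOrder

__all__ = [
    "ShotFlagLine",
    "SegmentSolution",
    "NoShotsError",
    "build_number_line",
    "longest_shotless_gap",
    "find_minimal_segmentation",
    "segment_of_position",
    "write_solution",
    "segment_raster",
]

REMAINDER = "remainder"


class NoShotsError(ValueError):
    """The number line carries no shot-bearing position."""


@dataclass(frozen=True)
class ShotFlagLine:
    """Boolean number line: True where the pixel holds >=1 retained shot."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", np.asarray(self.flags, dtype=bool))

    def __len__(self) -> int:
        return len(self.flags)

    @property
    def shot_count(self) -> int:
        return int(self.flags.sum())


@dataclass(frozen=True)
class SegmentSolution:
    """Minimal equal-length segmentation of a (circular) number line.

    Segment k covers rotated positions [k*l, (k+1)*l); rotation by
    ``offset`` s maps original position p to rotated index (p - s) mod N.
    The last N - n*l rotated positions are the dropped remainder.
    """

    segment_length: int
    offset: int
    n_segments: int
    n_positions: int

    @property
    def remainder(self) -> int:
        return self.n_positions - self.n_segments * self.segment_length


def build_number_line(
    order: PixelOrder, shot_pixels: Iterable[tuple[int, int]]
) -> ShotFlagLine:
    """Flag each number-line position whose pixel holds a retained shot."""
    shot_set = set((int(r), int(c)) for r, c in shot_pixels)
    line_pixels = set(zip(order.rows.tolist(), order.cols.tolist()))
    stray = shot_set - line_pixels
    if stray:
        raise ValueError(
            f"{len(stray)} shot pixels are not on the number line "
            f"(e.g. {next(iter(stray))}); shots must lie on forest pixels"
        )
    flags = np.fromiter(
        ((r, c) in shot_set for r, c in zip(order.rows.tolist(), order.cols.tolist())),
        dtype=bool,
        count=len(order),
    )
    return ShotFlagLine(flags=flags)


def longest_shotless_gap(line: ShotFlagLine, circular: bool = True) -> int:
    """Length of the longest run of shotless positions.

    With ``circular`` the line's end wraps to its beginning, consistent
    with testing segmentation offsets by rotation.
    """
    if line.shot_count == 0:
        raise NoShotsError("gap length is undefined on a shotless line")
    flags = line.flags
    n = len(flags)
    shot_pos = np.flatnonzero(flags)
    if circular:
        # gaps between consecutive shots around the circle
        diffs = np.diff(shot_pos, append=shot_pos[0] + n)
        return int(diffs.max() - 1)
    runs = np.diff(shot_pos)  # interior gaps are diffs - 1
    best = shot_pos[0]  # leading run
    best = max(best, n - 1 - shot_pos[-1])  # trailing run
    if len(runs):
        best = max(best, int(runs.max()) - 1)
    return int(best)


def _first_viable_offset(window_has_shot: np.ndarray, l: int, n: int) -> int:
    """Smallest offset s whose n segments of length l all contain a shot, or -1.

    ``window_has_shot[t]`` says whether the circular window [t, t+l)
    contains a shot; offset s is viable iff the windows starting at
    s, s+l, ..., s+(n-1)*l all do.  Stepping by l around the circle
    splits the N offsets into gcd(l, N) cycles of length N/gcd; within a
    cycle, s is viable iff the next shotless window lies >= n steps
    ahead.  Next-zero distances for every cycle at once come from one
    reversed running minimum, so the whole scan is O(N) per length.
    """
    N = len(window_has_shot)
    g = math.gcd(l, N)
    m = N // g  # cycle length; n <= m always since n = N // l and g <= l
    # idx[c, j]: offset reached after j steps of +l from cycle start c
    idx = (np.arange(g)[:, None] + l * np.arange(m)[None, :]) % N
    w2 = np.concatenate([window_has_shot[idx]] * 2, axis=1)
    sentinel = 2 * m + n  # "no zero ahead"
    z = np.where(w2, sentinel, np.arange(2 * m)[None, :])
    next_zero = np.minimum.accumulate(z[:, ::-1], axis=1)[:, ::-1]
    viable = (next_zero[:, :m] - np.arange(m)[None, :]) >= n
    if not viable.any():
        return -1
    return int(idx[viable].min())


def find_minimal_segmentation(line: ShotFlagLine) -> SegmentSolution:
    """Smallest-l, then smallest-offset, viable equal-length segmentation.

    Candidate lengths are scanned upward from 1; for each l every
    rotation offset s = 0..N-1 is tested, tiling n = floor(N/l) segments
    from the rotated start and dropping the remainder.  Half the longest
    circular shotless gap is the scan start one would expect — a segment
    shorter than that usually falls entirely inside the gap — but because
    the dropped remainder can absorb part of a gap the true minimum can
    occasionally sit below it, so the scan is exhaustive from 1 (small
    lengths are rejected in O(N)).  l = N is always viable when at least
    one shot exists, so the scan terminates.
    """
    if line.shot_count == 0:
        raise NoShotsError("no viable segmentation: the line carries no shots")
    flags = line.flags
    N = len(flags)
    csum = np.concatenate([[0], np.cumsum(np.concatenate([flags, flags]))])
    for l in range(1, N + 1):
        n = N // l
        # circular window counts: shots in [t, t+l) for every start t
        window = (csum[l : l + N] - csum[:N]) > 0
        if int(window.sum()) < n:
            continue  # fewer shot-bearing windows than segments: infeasible
        s = _first_viable_offset(window, l, n)
        if s >= 0:
            return SegmentSolution(
                segment_length=l, offset=s, n_segments=n, n_positions=N
            )
    raise AssertionError("unreachable: l = N is always viable")  # pragma: no cover


def segment_of_position(
    solution: SegmentSolution, position: int
) -> Union[int, str]:
    """Segment id of a number-line position, or "remainder" if dropped."""
    if not 0 <= position < solution.n_positions:
        raise ValueError("position outside the number line")
    k = ((position - solution.offset) % solution.n_positions) // solution.segment_length
    return int(k) if k < solution.n_segments else REMAINDER


def segment_ids(solution: SegmentSolution) -> np.ndarray:
    """Segment id per number-line position; -1 marks the remainder."""
    N = solution.n_positions
    k = ((np.arange(N) - solution.offset) % N) // solution.segment_length
    return np.where(k < solution.n_segments, k, -1).astype(np.int64)


def write_solution(path: Union[str, Path], solution: SegmentSolution) -> None:
    out = asdict(solution)
    out["remainder"] = solution.remainder
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def segment_raster(
    path: Union[str, Path],
    grid: ForestGrid,
    order: PixelOrder,
    solution: SegmentSolution,
) -> None:
    """Write a segment-membership raster (ASCII grid, -9999 off-domain)."""
    raster = np.full((grid.n_rows, grid.n_cols), -9999, dtype=np.int64)
    raster[order.rows, order.cols] = segment_ids(solution)
    write_ascii_grid(
        path, raster, grid.resolution, grid.origin_x, grid.origin_y, nodata=-9999
    )
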