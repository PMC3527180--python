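"""Domain types and I/O for the forest mask and the shot / training tables.

The estimation domain is a binary forest mask on a regular, projected,
equal-area grid (square pixels, meter units).  Rasters are exchanged as
ESRI ASCII grids — a plain-text, georeferenced format every GIS reads.
Lidar shots and field training plots travel as CSV tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ForestGrid",
    "GeodataError",
    "EmptyDomainError",
    "SchemaError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_forest_mask",
    "read_shot_table",
    "read_training_table",
    "locate_shot_pixel",
    "SHOT_COLUMNS",
    "TRAINING_COLUMNS",
]

SHOT_COLUMNS = ["shot_id", "x", "y", "lorey_height_m", "quality_ok"]
TRAINING_COLUMNS = ["plot_id", "lorey_height_m", "biomass_mg_ha"]


class GeodataError(ValueError):
    """Base error for malformed geodata inputs."""


class EmptyDomainError(GeodataError):
    """The forest mask (or the shot set over it) is empty."""


class SchemaError(GeodataError):
    """A table is missing required columns."""


@dataclass(frozen=True)
class ForestGrid:
    """Binary forest mask on a regular grid in a projected CRS.

    ``origin_x``/``origin_y`` are the projected coordinates (m) of the
    *top-left corner* of pixel (0, 0); rows increase southward.  Pixel
    footprints are half-open: pixel (r, c) covers
    ``[origin_x + c*res, origin_x + (c+1)*res)`` ×
    ``(origin_y - (r+1)*res, origin_y - r*res]`` so no point belongs to
    two pixels.
    """

    mask: np.ndarray  # bool, shape (n_rows, n_cols)
    resolution: float  # m, square pixels
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or mask.shape[0] < 1 or mask.shape[1] < 1:
            raise GeodataError("mask must be a 2-D array with >=1 row and column")
        if not self.resolution > 0:
            raise GeodataError("resolution must be > 0")
        object.__setattr__(self, "mask", mask)

    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mask.shape[1]

    @property
    def n_forest(self) -> int:
        """Population size N: the number of forest pixels."""
        return int(self.mask.sum())

    @property
    def pixel_area_ha(self) -> float:
        """Area of one pixel in hectares: (resolution/100)^2."""
        return (self.resolution / 100.0) ** 2

    def forest_pixels(self) -> np.ndarray:
        """(N, 2) array of forest (row, col) in row-major scan order."""
        return np.argwhere(self.mask)


def locate_shot_pixel(
    grid: ForestGrid, x: float, y: float
) -> Optional[tuple[int, int]]:
    """Pixel (row, col) containing projected point (x, y), or None if outside.

    Uses the half-open pixel convention, so a point exactly on the shared
    edge of two pixels belongs to the pixel to its east/south, and points
    on the grid's far east/south boundary fall outside.
    """
    col = math.floor((x - grid.origin_x) / grid.resolution)
    row = math.floor((grid.origin_y - y) / grid.resolution)
    # top/west edges are inclusive: origin maps to pixel (0, 0)
    if y == grid.origin_y:
        row = 0
    if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
        return (row, col)
    return None


def _pixel_indices(grid: ForestGrid, x: np.ndarray, y: np.ndarray):
    """Vectorized locate_shot_pixel; returns (row, col, inside) arrays."""
    col = np.floor((x - grid.origin_x) / grid.resolution).astype(np.int64)
    row = np.floor((grid.origin_y - y) / grid.resolution).astype(np.int64)
    row = np.where(y == grid.origin_y, 0, row)
    inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    return row, col, inside


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def read_ascii_grid(path: Union[str, Path]) -> tuple[np.ndarray, float, float, float]:
    """Read an ESRI ASCII grid.

    Returns ``(values, cellsize, origin_x, origin_y)`` with values as an
    integer array (NODATA as -9999 by default) and the origin at the
    top-left corner.
    """
    path = Path(path)
    header: dict[str, float] = {}
    header_keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in header_keys:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GeodataError(f"ASCII grid {path} missing header field {key!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.loadtxt(lines[n_header:], dtype=np.int64).reshape(n_rows, n_cols)
    cellsize = header["cellsize"]
    origin_x = header["xllcorner"]
    origin_y = header["yllcorner"] + n_rows * cellsize
    return values, cellsize, origin_x, origin_y


def write_ascii_grid(
    path: Union[str, Path],
    values: np.ndarray,
    cellsize: float,
    origin_x: float = 0.0,
    origin_y: float = 0.0,
    nodata: int = -9999,
) -> None:
    """Write an integer array as an ESRI ASCII grid (top-left origin)."""
    values = np.asarray(values)
    n_rows, n_cols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {n_cols}\n")
        fh.write(f"nrows {n_rows}\n")
        fh.write(f"xllcorner {origin_x!r}\n")
        fh.write(f"yllcorner {origin_y - n_rows * cellsize!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, values.astype(np.int64), fmt="%d")


def write_forest_grid(path: Union[str, Path], grid: ForestGrid) -> None:
    """Write a ForestGrid as a 0/1 ASCII grid."""
    write_ascii_grid(
        path, grid.mask.astype(np.int64), grid.resolution, grid.origin_x, grid.origin_y
    )


def resample_nearest(
    values: np.ndarray, in_res: float, target_res: float
) -> np.ndarray:
    """Nearest-neighbor resample of a categorical raster to a new cell size.

    Output dimensions are ``round(in_dim * in_res / target_res)``; each
    output pixel takes the value of the input pixel containing its center.
    Being a pure lookup, it can never invent class codes.
    """
    if not target_res > 0:
        raise GeodataError("target resolution must be > 0")
    in_rows, in_cols = values.shape
    out_rows = max(1, round(in_rows * in_res / target_res))
    out_cols = max(1, round(in_cols * in_res / target_res))
    # centers of output pixels, in input pixel index space
    rr = np.floor((np.arange(out_rows) + 0.5) * target_res / in_res).astype(np.int64)
    cc = np.floor((np.arange(out_cols) + 0.5) * target_res / in_res).astype(np.int64)
    rr = np.clip(rr, 0, in_rows - 1)
    cc = np.clip(cc, 0, in_cols - 1)
    return values[np.ix_(rr, cc)]


def read_forest_mask(
    path: Union[str, Path],
    forest_classes: Sequence[int],
    target_resolution: float,
) -> ForestGrid:
    """Read a land-cover raster, resample, and binarize to a forest mask.

    Class codes in ``forest_classes`` become forest (True).  Resampling is
    nearest-neighbor, the only class-preserving choice for categorical
    data.  The raster must be in a projected, meter-unit CRS; suspiciously
    small cell sizes (< 1 m, typical of geographic degrees) are rejected
    because the method requires equal-area pixels.
    """
    values, cellsize, origin_x, origin_y = read_ascii_grid(path)
    if cellsize < 1.0:
        raise GeodataError(
            f"cell size {cellsize} looks like geographic degrees; "
            "a projected, meter-unit, equal-area grid is required"
        )
    values = resample_nearest(values, cellsize, target_resolution)
    mask = np.isin(values, list(forest_classes))
    if not mask.any():
        raise EmptyDomainError("no pixel belongs to any of the forest classes")
    return ForestGrid(
        mask=mask,
        resolution=float(target_resolution),
        origin_x=origin_x,
        origin_y=origin_y,
    )


# ---------------------------------------------------------------------------
# Tables


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns {missing}")


def read_shot_table(path: Union[str, Path], grid: ForestGrid) -> pd.DataFrame:
    """Read the lidar shot CSV and filter it to the estimation domain.

    Drops shots with a failing quality flag, shots outside the grid
    extent, and shots over non-forest pixels; attaches the containing
    pixel as ``row``/``col`` columns.
    """
    df = pd.read_csv(path)
    _require_columns(df, SHOT_COLUMNS, "shot table")
    df = df[df["quality_ok"].astype(bool)].copy()
    shots = filter_shots_to_grid(df, grid)
    if len(shots) == 0:
        raise EmptyDomainError("no retained shots fall on forest pixels")
    return shots


def filter_shots_to_grid(shots: pd.DataFrame, grid: ForestGrid) -> pd.DataFrame:
    """Keep shots inside the extent and over forest; attach row/col."""
    x = shots["x"].to_numpy(dtype=float)
    y = shots["y"].to_numpy(dtype=float)
    row, col, inside = _pixel_indices(grid, x, y)
    keep = inside.copy()
    keep[inside] = grid.mask[row[inside], col[inside]]
    out = shots.loc[keep].copy()
    out["row"] = row[keep]
    out["col"] = col[keep]
    return out.reset_index(drop=True)


def read_training_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read the field-plot training CSV (plot_id, Lorey's height, biomass)."""
    df = pd.read_csv(path)
    _require_columns(df, TRAINING_COLUMNS, "training table")
    if (df["biomass_mg_ha"] < 0).any() or (df["lorey_height_m"] < 0).any():
        raise GeodataError("training plots must have non-negative height and biomass")
    return df
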