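"""Drawing the S1 application sample: one shot per tessellation cell.

Two seeded randomizations, kept on independent RNG streams so either can
be re-drawn alone: (1) where several shots share a pixel, one is retained
as the pixel's representative; (2) within each segment, one shot-bearing
pixel is selected uniformly.  The resulting one-per-equal-area-cell
sample is treated downstream as a simple random sample, mirroring the
precedent of national-forest-inventory hexagon designs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .sfc_ordering import PixelOrder
from .tessellation import SegmentSolution, ShotFlagLine, segment_ids

__all__ = [
    "S1Sample",
    "collapse_shots_to_pixels",
    "draw_s1",
    "nn_distance_stats",
    "write_s1",
]


@dataclass(frozen=True)
class S1Sample:
    """One randomly selected shot per segment.

    ``records`` has columns segment_id, shot_id, row, col, x, y,
    lorey_height_m, sorted by segment_id.
    """

    records: pd.DataFrame
    seed: int

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def heights(self) -> np.ndarray:
        return self.records["lorey_height_m"].to_numpy(dtype=float)


def collapse_shots_to_pixels(shots: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Retain one shot per pixel, chosen uniformly among cohabitants.

    ``shots`` must carry row/col columns (as produced by the shot-table
    reader).  When a pixel holds k shots each survives with probability
    1/k; with one shot per pixel the table passes through unchanged.
    """
    if len(shots) == 0:
        return shots.copy()
    rng = np.random.default_rng(seed)
    # random priority, then keep the top-priority shot of each pixel
    prio = rng.random(len(shots))
    order = np.lexsort((prio, shots["col"].to_numpy(), shots["row"].to_numpy()))
    sorted_shots = shots.iloc[order]
    keep = ~sorted_shots.duplicated(subset=["row", "col"], keep="first")
    out = sorted_shots.loc[keep].sort_index().reset_index(drop=True)
    return out


def draw_s1(
    solution: SegmentSolution,
    line: ShotFlagLine,
    pixel_shots: pd.DataFrame,
    order: PixelOrder,
    seed: int,
) -> S1Sample:
    """Select one shot-bearing pixel uniformly at random in every segment.

    ``pixel_shots`` must hold at most one shot per pixel (collapse
    first).  Raises if any segment of the claimed-viable solution turns
    out shotless, which indicates inconsistent inputs.
    """
    seg_of_pos = segment_ids(solution)
    # number-line position of each shot pixel
    pos_of_pixel = {
        (int(r), int(c)): i
        for i, (r, c) in enumerate(zip(order.rows.tolist(), order.cols.tolist()))
    }
    positions = np.array(
        [
            pos_of_pixel[(int(r), int(c))]
            for r, c in zip(pixel_shots["row"], pixel_shots["col"])
        ],
        dtype=np.int64,
    )
    if not line.flags[positions].all():
        raise ValueError("shot table inconsistent with the number-line flags")
    seg = seg_of_pos[positions]
    in_seg = seg >= 0
    rng = np.random.default_rng(seed)
    prio = rng.random(len(positions))
    chosen_rows = []
    df = pixel_shots.reset_index(drop=True)
    by_seg: dict[int, int] = {}
    for i in np.flatnonzero(in_seg):
        s = int(seg[i])
        if s not in by_seg or prio[i] > prio[by_seg[s]]:
            by_seg[s] = int(i)
    missing = set(range(solution.n_segments)) - set(by_seg)
    if missing:
        raise ValueError(
            f"{len(missing)} segments contain no shot (e.g. segment "
            f"{min(missing)}); solution and shot table are inconsistent"
        )
    for s in range(solution.n_segments):
        chosen_rows.append(by_seg[s])
    records = df.iloc[chosen_rows].copy()
    records.insert(0, "segment_id", np.arange(solution.n_segments))
    cols = ["segment_id", "shot_id", "row", "col", "x", "y", "lorey_height_m"]
    records = records[[c for c in cols if c in records.columns]]
    return S1Sample(records=records.reset_index(drop=True), seed=seed)


def nn_distance_stats(points: np.ndarray) -> dict[str, float]:
    """Nearest-neighbor distance summary of a point pattern.

    Returns mean, median and min of each point's Euclidean distance to
    its closest neighbor, in the units of the input coordinates.  The
    summary describes the spatial dispersion of the sample — a uniform,
    non-clustered pattern shows comparable mean and median and no tiny
    minimum.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least 2 points of shape (n, 2)")
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    nn = dists[:, 1]
    return {
        "mean": float(nn.mean()),
        "median": float(np.median(nn)),
        "min": float(nn.min()),
    }


def write_s1(
    path: Union[str, Path], sample: S1Sample, seed_collapse: int
) -> None:
    """Export the S1 sample CSV plus a JSON sidecar recording the seeds."""
    path = Path(path)
    sample.records.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".seeds.json")
    sidecar.write_text(
        json.dumps({"seed_collapse": seed_collapse, "seed_draw": sample.seed}) + "\n"
    )
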