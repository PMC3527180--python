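"""Synthetic landscapes, lidar tracks, and Monte Carlo validation.

Generates data with the statistical structure the estimator assumes, so
the whole chain — ordering, tessellation, one-per-cell draw, model fit,
variance decomposition — can be exercised and frequentist-validated
without any satellite or field download:

* a clustered binary forest mask (thresholded smoothed random field);
* shots along straight ground tracks with a fixed along-track spacing
  and near-polar-orbit azimuth, with optionally clumped track density
  mimicking the arbitrary acquisition pattern of a spaceborne lidar;
* Lorey's heights from a spatially correlated Gaussian field (m);
* biomass Y = beta * height^2 + eps, eps ~ N(0, sigma^2), truncated at 0;
* a training sample of co-located "field plots" whose centers are
  jittered within a co-location radius of their host shot.

Everything is deterministic given (config, seed); per-stage seeds are
derived from one master seed via numpy SeedSequence spawning.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import estimation, srs_sampling, tessellation
from .geodata import ForestGrid, write_forest_grid
from .sfc_ordering import order_forest_pixels

__all__ = [
    "SimulationConfig",
    "well_specified_config",
    "simulate_landscape",
    "simulate_height_field",
    "simulate_tracks",
    "simulate_biomass",
    "build_s2",
    "population_truth",
    "run_replicate",
    "run_monte_carlo",
    "write_simulation",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic landscape and samples.

    Defaults follow the source mission's geometry (172 m along-track shot
    spacing, 94 degree orbit azimuth stand-in, 230 m processing pixels,
    35 training plots co-located within 120 m) on a desk-scale domain;
    the biomass coefficient is the published California value and the
    residual scale is chosen so that truncation at zero affects well
    under 0.1% of draws at typical heights.
    """

    n_rows: int = 80
    n_cols: int = 80
    resolution: float = 230.0  # m
    forest_fraction: float = 0.55
    clustering_scale: float = 1200.0  # m, mask smoothing length
    n_tracks: int = 24
    along_track_spacing: float = 172.0  # m
    track_inclination: float = 94.0  # degrees clockwise from north
    track_cluster_count: Optional[int] = 5  # None = uniform track density
    track_cluster_sd: float = 1500.0  # m, across-track clumping scale
    height_mean: float = 24.0  # m
    height_sd: float = 7.0  # m
    height_corr_length: float = 900.0  # m
    beta_true: float = 0.3717  # Mg/ha per m^2
    sigma_true: float = 60.0  # Mg/ha
    s2_size: int = 35
    coloc_radius: float = 120.0  # m

    def __post_init__(self) -> None:
        if not 0 < self.forest_fraction <= 1:
            raise ValueError("forest_fraction must be in (0, 1]")
        if self.s2_size < 2:
            raise ValueError("s2_size must be >= 2")
        for name in ("resolution", "along_track_spacing", "clustering_scale",
                     "height_corr_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def well_specified_config() -> SimulationConfig:
    """Conditions under which the estimator's assumptions hold cleanly.

    Used for frequentist validation of the variance estimator: uniform
    (unclumped) track density, dense enough tracks that shot-bearing
    pixels are not a thin sliver of the domain, and a short height
    correlation length so shot placement is effectively exchangeable
    with respect to heights — the regime in which the one-per-cell draw
    genuinely behaves like a simple random sample of the population.
    """
    return SimulationConfig(
        n_tracks=40,
        track_cluster_count=None,
        height_corr_length=300.0,
    )


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _smoothed_field(
    shape: tuple[int, int], corr_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized Gaussian random field via smoothed white noise."""
    z = rng.standard_normal(shape)
    if corr_px > 0:
        z = ndimage.gaussian_filter(z, sigma=corr_px, mode="wrap")
    z = (z - z.mean()) / z.std()
    return z


def simulate_landscape(config: SimulationConfig, seed: int) -> ForestGrid:
    """Clustered binary forest mask covering ``forest_fraction`` of the grid.

    A smoothed random field is thresholded at the quantile that yields
    the requested forest fraction, producing contiguous patches with a
    characteristic size of ``clustering_scale``.
    """
    rng = np.random.default_rng(seed)
    shape = (config.n_rows, config.n_cols)
    if config.forest_fraction == 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        z = _smoothed_field(shape, config.clustering_scale / config.resolution, rng)
        mask = z <= np.quantile(z, config.forest_fraction)
    return ForestGrid(mask=mask, resolution=config.resolution)


def simulate_height_field(config: SimulationConfig, seed: int) -> np.ndarray:
    """Per-pixel Lorey's height surface (m), truncated at 0."""
    rng = np.random.default_rng(seed)
    z = _smoothed_field(
        (config.n_rows, config.n_cols),
        config.height_corr_length / config.resolution,
        rng,
    )
    return np.clip(config.height_mean + config.height_sd * z, 0.0, None)


def simulate_tracks(
    grid: ForestGrid,
    height_field: np.ndarray,
    config: SimulationConfig,
    seed: int,
) -> pd.DataFrame:
    """Shots along straight ground tracks, filtered to forest pixels.

    Each track runs at the configured azimuth (ascending) or its mirror
    (descending), offset from the domain center by a random across-track
    displacement — uniform, or clumped around a few cluster centers to
    mimic arbitrarily uneven acquisition density.  Shots are placed every
    ``along_track_spacing`` meters; those falling outside the extent or
    over non-forest are dropped.  Heights are read from the height field
    at the shot's pixel.
    """
    rng = np.random.default_rng(seed)
    width = grid.n_cols * grid.resolution
    height = grid.n_rows * grid.resolution
    cx = grid.origin_x + width / 2.0
    cy = grid.origin_y - height / 2.0
    reach = float(np.hypot(width, height)) / 2.0

    if config.track_cluster_count:
        centers = rng.uniform(-reach, reach, size=config.track_cluster_count)
        which = rng.integers(0, config.track_cluster_count, size=config.n_tracks)
        offsets = rng.normal(centers[which], config.track_cluster_sd)
    else:
        offsets = rng.uniform(-reach, reach, size=config.n_tracks)

    rows = []
    shot_id = 0
    for track_idx in range(config.n_tracks):
        az = config.track_inclination
        if rng.random() < 0.5:
            az = 360.0 - az  # descending mirror
        rad = np.deg2rad(az)
        dx, dy = np.sin(rad), np.cos(rad)  # along-track unit vector
        px, py = dy, -dx  # across-track unit vector
        ax = cx + offsets[track_idx] * px
        ay = cy + offsets[track_idx] * py
        phase = rng.uniform(0.0, config.along_track_spacing)
        t = np.arange(-reach + phase, reach, config.along_track_spacing)
        xs = ax + t * dx
        ys = ay + t * dy
        col = np.floor((xs - grid.origin_x) / grid.resolution).astype(np.int64)
        row = np.floor((grid.origin_y - ys) / grid.resolution).astype(np.int64)
        inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
        keep = inside.copy()
        keep[inside] = grid.mask[row[inside], col[inside]]
        for x, y, r, c in zip(xs[keep], ys[keep], row[keep], col[keep]):
            rows.append((f"t{track_idx:03d}s{shot_id:06d}", x, y,
                         float(height_field[r, c]), 1, int(r), int(c)))
            shot_id += 1
    return pd.DataFrame(
        rows,
        columns=["shot_id", "x", "y", "lorey_height_m", "quality_ok", "row", "col"],
    )


def simulate_biomass(
    heights, beta_true: float, sigma_true: float, seed: int
) -> np.ndarray:
    """Biomass draws Y = beta * h^2 + eps, eps ~ N(0, sigma^2), floored at 0."""
    if sigma_true < 0:
        raise ValueError("sigma_true must be >= 0")
    h = np.asarray(heights, dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma_true, size=h.shape) if sigma_true > 0 else 0.0
    return np.clip(beta_true * h ** 2 + eps, 0.0, None)


def build_s2(
    shots: pd.DataFrame,
    height_field: np.ndarray,
    grid: ForestGrid,
    config: SimulationConfig,
    seed: int,
) -> pd.DataFrame:
    """Training plots co-located with a random subset of shots.

    ``s2_size`` host shots are drawn without replacement; each plot
    center is jittered uniformly within a disk of ``coloc_radius`` around
    its shot, its height is read from the height field at the jittered
    center's pixel, and its biomass is generated from that height — so
    the training pairs carry realistic co-location mismatch while the
    height-biomass model itself stays exact.
    """
    if config.s2_size > len(shots):
        raise ValueError(
            f"s2_size {config.s2_size} exceeds the {len(shots)} available shots"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(shots), size=config.s2_size, replace=False)
    host = shots.iloc[np.sort(idx)]
    # uniform jitter in a disk of radius coloc_radius
    theta = rng.uniform(0.0, 2.0 * np.pi, config.s2_size)
    r = config.coloc_radius * np.sqrt(rng.uniform(0.0, 1.0, config.s2_size))
    px = host["x"].to_numpy() + r * np.cos(theta)
    py = host["y"].to_numpy() + r * np.sin(theta)
    col = np.floor((px - grid.origin_x) / grid.resolution).astype(np.int64)
    row = np.floor((grid.origin_y - py) / grid.resolution).astype(np.int64)
    col = np.clip(col, 0, grid.n_cols - 1)
    row = np.clip(row, 0, grid.n_rows - 1)
    plot_heights = height_field[row, col]
    biomass = simulate_biomass(
        plot_heights, config.beta_true, config.sigma_true,
        int(rng.integers(0, 2 ** 31)),
    )
    return pd.DataFrame(
        {
            "plot_id": [f"p{i:03d}" for i in range(config.s2_size)],
            "lorey_height_m": plot_heights,
            "biomass_mg_ha": biomass,
        }
    )


def population_truth(
    grid: ForestGrid, height_field: np.ndarray, beta_true: float
) -> float:
    """True mean of beta * h^2 over all forest pixels (Mg/ha)."""
    h = height_field[grid.mask]
    return float(np.mean(beta_true * h ** 2))


def run_replicate(
    config: SimulationConfig, seed: int
) -> tuple[estimation.EstimateResult, float]:
    """One full realization: landscape through estimate; returns (result, truth)."""
    rngs = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(np.random.default_rng(s).integers(0, 2 ** 31)) for s in rngs]
    grid = simulate_landscape(config, seeds[0])
    heights = simulate_height_field(config, seeds[1])
    shots = simulate_tracks(grid, heights, config, seeds[2])
    if len(shots) == 0:
        raise RuntimeError("no shots fell on forest; enlarge n_tracks or the domain")
    order = order_forest_pixels(grid)
    pixel_shots = srs_sampling.collapse_shots_to_pixels(shots, seeds[3])
    line = tessellation.build_number_line(
        order, zip(pixel_shots["row"], pixel_shots["col"])
    )
    solution = tessellation.find_minimal_segmentation(line)
    s1 = srs_sampling.draw_s1(solution, line, pixel_shots, order, seeds[4])
    s2 = build_s2(shots, heights, grid, config, seeds[3] ^ 0x5F5F5F)
    fit = estimation.fit_biomass_model(s2, estimation.QUADRATIC_NO_INTERCEPT)
    result = estimation.estimate_population_mean(fit, s1.heights)
    truth = population_truth(grid, heights, config.beta_true)
    return result, truth


def run_monte_carlo(
    config: SimulationConfig, n_reps: int, seed: int
) -> dict[str, float]:
    """Frequentist validation of the estimator under the synthetic design.

    Each replicate regenerates the whole landscape, acquisition, and
    training sample, runs the full chain, and compares the estimate with
    that replicate's true forest-pixel mean of beta * h^2.  Reports the
    bias of the estimator, its empirical spread, the average of the
    estimated standard errors, and the coverage of the nominal 95%
    normal confidence interval.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for stable coverage estimates")
    child = np.random.SeedSequence(seed).spawn(n_reps)
    errors = np.empty(n_reps)
    ses = np.empty(n_reps)
    covered = np.zeros(n_reps, dtype=bool)
    for i, ss in enumerate(child):
        rep_seed = int(np.random.default_rng(ss).integers(0, 2 ** 31))
        result, truth = run_replicate(config, rep_seed)
        errors[i] = result.mean_estimate - truth
        ses[i] = result.standard_error
        covered[i] = abs(errors[i]) <= 1.96 * result.standard_error
    return {
        "n_reps": n_reps,
        "bias": float(errors.mean()),
        "mc_se_of_bias": float(errors.std(ddof=1) / np.sqrt(n_reps)),
        "empirical_sd": float(errors.std(ddof=1)),
        "mean_se": float(ses.mean()),
        "coverage_95": float(covered.mean()),
    }


def write_simulation(
    outdir: Union[str, Path], config: SimulationConfig, seed: int
) -> dict[str, Path]:
    """Write one synthetic dataset in the standard on-disk formats.

    Produces a forest-mask ASCII grid, a shot CSV, a training CSV and a
    YAML snapshot of the configuration and seed, so a synthetic run is
    indistinguishable from a real-data run downstream.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rngs = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(np.random.default_rng(s).integers(0, 2 ** 31)) for s in rngs]
    grid = simulate_landscape(config, seeds[0])
    heights = simulate_height_field(config, seeds[1])
    shots = simulate_tracks(grid, heights, config, seeds[2])
    s2 = build_s2(shots, heights, grid, config, seeds[3])
    paths = {
        "mask": outdir / "forest_mask.asc",
        "shots": outdir / "shots.csv",
        "training": outdir / "training.csv",
        "config": outdir / "simulation.yaml",
    }
    write_forest_grid(paths["mask"], grid)
    shots[["shot_id", "x", "y", "lorey_height_m", "quality_ok"]].to_csv(
        paths["shots"], index=False
    )
    s2.to_csv(paths["training"], index=False)
    snapshot = dataclasses.asdict(config)
    snapshot["seed"] = seed
    paths["config"].write_text(yaml.safe_dump(snapshot, sort_keys=False))
    return paths
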