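"""End-to-end workflow: mask -> order -> segment -> sample -> fit -> estimate."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import estimation, geodata, srs_sampling, tessellation
from .sfc_ordering import order_forest_pixels, write_pixel_order

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage of the workflow failed; the stage name prefixes the message."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one estimation run."""

    mask_path: str
    shots_path: str
    training_path: str
    out_dir: str
    target_resolution: float = 230.0
    forest_classes: tuple[int, ...] = (1,)
    seed_collapse: int = 1
    seed_draw: int = 2
    powers: tuple[int, ...] = (2,)
    include_intercept: bool = False
    curve: str = "peano"
    use_fpc: bool = False

    def config_hash(self) -> str:
        # out_dir does not affect the result, so it stays out of the hash
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise PipelineError(f"{name}: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig) -> estimation.EstimateResult:
    """Run the full estimation chain and write its artifacts.

    Writes, under ``out_dir``: the pixel-order CSV, the segmentation
    JSON and segment-membership raster, the S1 sample CSV with its seed
    sidecar, the estimate report JSON, and a run log recording N, shot
    counts, the segmentation (l, n) and any extrapolation warnings.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("curvesample")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        grid = _stage("mask")(
            geodata.read_forest_mask,
            config.mask_path,
            config.forest_classes,
            config.target_resolution,
        )
        logger.info("domain: N=%d forest pixels of %.0f m (%.2f ha each)",
                    grid.n_forest, grid.resolution, grid.pixel_area_ha)
        shots = _stage("shots")(geodata.read_shot_table, config.shots_path, grid)
        logger.info("shots: %d retained on forest pixels", len(shots))
        order = _stage("order")(order_forest_pixels, grid, config.curve)
        write_pixel_order(out / "pixel_order.csv", order)
        pixel_shots = _stage("sample")(
            srs_sampling.collapse_shots_to_pixels, shots, config.seed_collapse
        )
        line = _stage("segment")(
            tessellation.build_number_line,
            order,
            zip(pixel_shots["row"], pixel_shots["col"]),
        )
        logger.info("number line: %d positions, %d shot pixels",
                    len(line), line.shot_count)
        solution = _stage("segment")(tessellation.find_minimal_segmentation, line)
        logger.info("segmentation: l=%d pixels, n=%d segments, remainder=%d",
                    solution.segment_length, solution.n_segments, solution.remainder)
        tessellation.write_solution(out / "segmentation.json", solution)
        tessellation.segment_raster(out / "segments.asc", grid, order, solution)
        s1 = _stage("sample")(
            srs_sampling.draw_s1, solution, line, pixel_shots, order, config.seed_draw
        )
        srs_sampling.write_s1(out / "s1_sample.csv", s1, config.seed_collapse)
        training = _stage("fit")(geodata.read_training_table, config.training_path)
        spec = estimation.ModelSpec(
            powers=config.powers, include_intercept=config.include_intercept
        )
        fit = _stage("fit")(estimation.fit_biomass_model, training, spec)
        fpc = s1.n / grid.n_forest if config.use_fpc else None
        result = _stage("estimate")(
            estimation.estimate_population_mean, fit, s1.heights, fpc
        )
        report = {
            "config_hash": config.config_hash(),
            "seeds": {"collapse": config.seed_collapse, "draw": config.seed_draw},
            "beta_hat": fit.beta_hat.tolist(),
            "cov_beta": fit.cov_beta.tolist(),
            "mse": fit.mse,
            "dof": fit.dof,
            "mean_estimate_mg_ha": result.mean_estimate,
            "sampling_summand": result.sampling_summand,
            "model_summand": result.model_summand,
            "total_variance": result.total_variance,
            "standard_error": result.standard_error,
            "n_s1": result.n,
            "m_s2": fit.m,
            "n_population": grid.n_forest,
            "segment_length": solution.segment_length,
            "n_segments": solution.n_segments,
            "extrapolated_heights": list(result.extrapolated_heights),
        }
        (out / "estimate_report.json").write_text(json.dumps(report, indent=2) + "\n")
        logger.info("estimate: %.2f Mg/ha, SE %.2f (sampling %.2f + model %.2f)",
                    result.mean_estimate, result.standard_error,
                    result.sampling_summand, result.model_summand)
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
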