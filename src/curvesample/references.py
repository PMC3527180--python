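"""Published California case-study figures, kept for documentation and
internal-consistency checks.

The original study estimated mean aboveground biomass density for
California forests from a spaceborne-lidar sample.  Its input data (the
lidar shot set and the 35 co-located field plots) were never deposited,
so these headline numbers cannot be recomputed from raw inputs; they are
recorded here as the package's reference point, and simple arithmetic
relations among them (variance ratio, relative standard error, per-cell
shot density, segment area) serve as consistency checks of the reported
chain.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CaliforniaReference", "CALIFORNIA"]


@dataclass(frozen=True)
class CaliforniaReference:
    """Headline values of the published California application."""

    mean_estimate: float = 211.11  # Mg/ha
    standard_error: float = 20.70  # Mg/ha
    sampling_summand: float = 241.00  # (Mg/ha)^2
    model_summand: float = 186.31  # (Mg/ha)^2
    beta_hat: float = 0.3717  # Mg/ha per m^2
    var_beta_hat: float = 0.0005776397
    r2_no_intercept: float = 0.87
    r2_with_intercept: float = 0.64
    conditional_r2: float = 0.001
    n_segments: int = 182
    segment_length_px: int = 9054
    pixel_size_m: float = 230.0
    n_shot_pixels: float = 102_000.0  # "approximately 102,000" flagged pixels
    nn_mean_km: float = 19.6
    nn_median_km: float = 13.5
    nn_min_km: float = 2.4
    nfi_estimate: float = 208.95  # Mg/ha, design-based benchmark
    nfi_standard_error: float = 2.88  # Mg/ha
    nfi_n_plots: int = 5261
    cost_per_plot_usd: float = 2000.0
    m_s2: int = 35

    @property
    def variance_ratio(self) -> float:
        """Model-variance contribution relative to the sampling contribution."""
        return self.model_summand / self.sampling_summand

    @property
    def relative_se(self) -> float:
        """Standard error as a fraction of the estimate."""
        return self.standard_error / self.mean_estimate

    @property
    def shots_per_segment(self) -> float:
        """Average count of shot-bearing pixels per tessellation cell."""
        return self.n_shot_pixels / self.n_segments

    @property
    def nfi_cost_usd(self) -> float:
        """Ground-inventory cost at the standard per-plot valuation."""
        return self.nfi_n_plots * self.cost_per_plot_usd

    @property
    def segment_area_ha(self) -> float:
        """Area of one tessellation cell in hectares."""
        return self.segment_length_px * (self.pixel_size_m / 100.0) ** 2

    @property
    def estimate_gap(self) -> float:
        """Absolute disagreement with the design-based benchmark."""
        return abs(self.mean_estimate - self.nfi_estimate)


CALIFORNIA = CaliforniaReference()
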