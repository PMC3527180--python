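"""Model-based estimation of mean aboveground biomass density.

The biomass Y (Mg/ha) of a population element is modeled as a polynomial
in lidar-derived Lorey's height x (m),

    Y = sum_j beta_j x^j + eps,   eps ~ N(0, sigma^2),

fitted by ordinary least squares on the training sample S2 of co-located
field plots (OLS coincides with maximum likelihood under the Gaussian
error).  The population mean is estimated by averaging model predictions
over the application sample S1, and its variance decomposes into two
summands: the simple-random-sampling variance of the S1 mean of
predictions, plus the propagated parameter-covariance term

    sum_k sum_l Cov(beta_k, beta_l) * xbar*_k * xbar*_l,

where xbar*_k is the S1 mean of x^k.  For the single-term no-intercept
quadratic the double sum collapses to Var(beta) * (mean of x^2)^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "ModelFit",
    "EstimateResult",
    "fit_biomass_model",
    "predict_biomass",
    "estimate_population_mean",
    "r_squared_uncentered",
    "conditional_r_squared",
]

logger = logging.getLogger(__name__)

QUADRATIC_NO_INTERCEPT: "ModelSpec"


@dataclass(frozen=True)
class ModelSpec:
    """Which powers of Lorey's height enter the linear model.

    ``powers`` lists the exponents j of the covariate terms x^j; the
    intercept is power 0 and is controlled separately for clarity.
    """

    powers: tuple[int, ...] = (2,)
    include_intercept: bool = False

    def __post_init__(self) -> None:
        powers = tuple(int(p) for p in self.powers)
        if len(powers) == 0:
            raise ValueError("at least one power is required")
        if len(set(powers)) != len(powers) or any(p < 0 for p in powers):
            raise ValueError("powers must be distinct non-negative integers")
        if self.include_intercept and 0 in powers:
            raise ValueError("intercept requested twice (power 0 and flag)")
        object.__setattr__(self, "powers", powers)

    @property
    def all_powers(self) -> tuple[int, ...]:
        """Powers including the intercept term, intercept first."""
        return ((0,) if self.include_intercept else ()) + self.powers

    @property
    def n_params(self) -> int:
        return len(self.all_powers)

    def design_matrix(self, heights: np.ndarray) -> np.ndarray:
        x = np.asarray(heights, dtype=float)
        return np.column_stack([x ** p for p in self.all_powers])


QUADRATIC_NO_INTERCEPT = ModelSpec(powers=(2,), include_intercept=False)


@dataclass(frozen=True)
class ModelFit:
    """OLS fit of the biomass-height model on the S2 training sample."""

    spec: ModelSpec
    beta_hat: np.ndarray  # Mg/ha per m^j, ordered as spec.all_powers
    cov_beta: np.ndarray  # parameter covariance, (Mg/ha per m^j)^2
    mse: float  # residual mean square, (Mg/ha)^2
    dof: int  # residual degrees of freedom m - p
    m: int  # training-sample size
    sse: float  # residual sum of squares
    training_height_max: float = field(default=float("nan"))


def fit_biomass_model(training: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit Eqn-style polynomial biomass model by OLS on S2 plots.

    ``training`` needs columns lorey_height_m and biomass_mg_ha.  The
    residual mean square uses m - p degrees of freedom and the parameter
    covariance is the standard linear-model estimate mse * (X'X)^-1.
    """
    h = training["lorey_height_m"].to_numpy(dtype=float)
    y = training["biomass_mg_ha"].to_numpy(dtype=float)
    m, p = len(h), spec.n_params
    if m <= p:
        raise ValueError(
            f"insufficient training data: {m} plots for {p} parameters"
        )
    X = spec.design_matrix(h)
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("degenerate design: covariate powers are collinear")
    res = sm.OLS(y, X).fit()
    return ModelFit(
        spec=spec,
        beta_hat=np.asarray(res.params, dtype=float),
        cov_beta=np.asarray(res.cov_params(), dtype=float),
        mse=float(res.mse_resid),
        dof=int(res.df_resid),
        m=m,
        sse=float(res.ssr),
        training_height_max=float(h.max()),
    )


def predict_biomass(fit: ModelFit, lorey_height) -> np.ndarray:
    """Predicted biomass density (Mg/ha) at the given Lorey's height(s)."""
    h = np.asarray(lorey_height, dtype=float)
    if np.any(h < 0):
        raise ValueError("Lorey's height must be >= 0")
    return fit.spec.design_matrix(np.atleast_1d(h)) @ fit.beta_hat


@dataclass(frozen=True)
class EstimateResult:
    """Population-mean biomass estimate with its variance decomposition."""

    mean_estimate: float  # Mg/ha
    sampling_summand: float  # (Mg/ha)^2, SRS variance of the S1 mean
    model_summand: float  # (Mg/ha)^2, parameter-covariance propagation
    n: int  # S1 size
    design_moments: dict[int, float]  # S1 means of x^k per power k
    extrapolated_heights: tuple[float, ...] = ()

    @property
    def total_variance(self) -> float:
        return self.sampling_summand + self.model_summand

    @property
    def standard_error(self) -> float:
        return float(np.sqrt(self.total_variance))


def estimate_population_mean(
    fit: ModelFit,
    s1_heights: Sequence[float],
    fpc: Optional[float] = None,
) -> EstimateResult:
    """Estimate the domain-mean biomass from S1 heights and a fitted model.

    The mean of the n model predictions estimates the population mean;
    its variance is the SRS estimate s^2(Yhat)/n plus the double sum of
    the parameter covariances weighted by the S1 means of the covariate
    powers.  ``fpc``, if given, is the sampling fraction n/N applied as a
    finite-population correction (1 - n/N) to the first summand; it is
    off by default because the method targets n << N.

    S1 heights exceeding the training range are predicted anyway — the
    model is assumed valid over the whole population — but are reported
    and logged as extrapolations.
    """
    h = np.asarray(s1_heights, dtype=float)
    n = len(h)
    if n == 0:
        raise ValueError("S1 sample is empty")
    preds = predict_biomass(fit, h)
    mean_estimate = float(preds.mean())
    if n > 1:
        sampling = float(preds.var(ddof=1) / n)
    else:
        sampling = float("nan")
    if fpc is not None:
        sampling *= 1.0 - fpc
    moments = {int(k): float(np.mean(h ** k)) for k in fit.spec.all_powers}
    mvec = np.array([moments[k] for k in fit.spec.all_powers])
    model_summand = float(mvec @ fit.cov_beta @ mvec)
    extrapolated = tuple(
        float(v) for v in np.sort(h[h > fit.training_height_max])
    )
    if extrapolated:
        logger.warning(
            "%d of %d S1 heights exceed the training maximum %.1f m: %s",
            len(extrapolated),
            n,
            fit.training_height_max,
            np.round(extrapolated, 1).tolist(),
        )
    return EstimateResult(
        mean_estimate=mean_estimate,
        sampling_summand=sampling,
        model_summand=model_summand,
        n=n,
        design_moments=moments,
        extrapolated_heights=extrapolated,
    )


def r_squared_uncentered(fit: ModelFit, training: pd.DataFrame) -> float:
    """No-intercept R^2: 1 - SSE / sum(Y^2) (uncentered total sum of squares).

    The conventional centered R^2 is not meaningful without an intercept;
    this variant measures fit relative to the zero function and is not
    directly comparable to the centered figure of an intercept model.
    """
    y = training["biomass_mg_ha"].to_numpy(dtype=float)
    tss = float(np.sum(y ** 2))
    if tss <= 0:
        raise ValueError("uncentered R^2 undefined: all responses are zero")
    h = training["lorey_height_m"].to_numpy(dtype=float)
    resid = y - predict_biomass(fit, h)
    return 1.0 - float(np.sum(resid ** 2)) / tss


def conditional_r_squared(full_sse: float, reduced_sse: float) -> float:
    """Share of the reduced model's residual variation removed by the full model.

    1 - SSE_full / SSE_reduced; a value near 0 says the extra terms of
    the full model buy essentially nothing.
    """
    if reduced_sse <= 0:
        raise ValueError("conditional R^2 undefined: reduced SSE must be > 0")
    return 1.0 - full_sse / reduced_sse
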