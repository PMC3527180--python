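import logging

import numpy as np
import pandas as pd
import pytest

from curvesample.estimation import (
    ModelFit,
    ModelSpec,
    QUADRATIC_NO_INTERCEPT,
    conditional_r_squared,
    estimate_population_mean,
    fit_biomass_model,
    predict_biomass,
    r_squared_uncentered,
)


def normal_equations_fit(heights, biomass, spec):
    """Independent oracle: solve X'X b = X'y explicitly."""
    X = np.column_stack([np.asarray(heights, float) ** p for p in spec.all_powers])
    y = np.asarray(biomass, float)
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    mse = float(resid @ resid) / dof
    cov = mse * np.linalg.inv(xtx)
    return beta, cov, mse


def make_training(heights, biomass):
    return pd.DataFrame(
        {
            "plot_id": [f"p{i}" for i in range(len(heights))],
            "lorey_height_m": heights,
            "biomass_mg_ha": biomass,
        }
    )


class TestFit:
    def test_exact_quadratic_recovered_with_zero_uncertainty(self):
        fit = fit_biomass_model(
            make_training([1, 2, 3], [1, 4, 9]), QUADRATIC_NO_INTERCEPT
        )
        assert fit.beta_hat[0] == pytest.approx(1.0)
        assert fit.mse == pytest.approx(0.0, abs=1e-24)
        assert fit.cov_beta[0, 0] == pytest.approx(0.0, abs=1e-24)

    def test_two_plot_closed_form(self, toy_training):
        # beta = sum(x^2 y)/sum(x^4) = 18/17; SSE from the two residuals; dof 1
        fit = fit_biomass_model(toy_training, QUADRATIC_NO_INTERCEPT)
        assert fit.beta_hat[0] == pytest.approx(18 / 17, rel=1e-12)
        assert fit.mse == pytest.approx(16 / 17, rel=1e-12)
        assert fit.cov_beta[0, 0] == pytest.approx(16 / 17 / 17, rel=1e-12)
        assert fit.dof == 1

    def test_matches_normal_equations_on_random_sets(self, rng):
        specs = [
            QUADRATIC_NO_INTERCEPT,
            ModelSpec(powers=(1, 2), include_intercept=True),
            ModelSpec(powers=(1,), include_intercept=False),
        ]
        for i in range(100):
            spec = specs[i % len(specs)]
            m = int(rng.integers(spec.n_params + 1, 40))
            h = rng.uniform(1, 45, m)
            y = 0.4 * h ** 2 + rng.normal(0, 20, m)
            fit = fit_biomass_model(make_training(h, y), spec)
            beta, cov, mse = normal_equations_fit(h, y, spec)
            np.testing.assert_allclose(fit.beta_hat, beta, rtol=1e-10)
            np.testing.assert_allclose(fit.cov_beta, cov, rtol=1e-9, atol=1e-14)
            assert fit.mse == pytest.approx(mse, rel=1e-10)

    def test_too_few_plots_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_biomass_model(make_training([5.0], [10.0]), QUADRATIC_NO_INTERCEPT)

    def test_degenerate_design_rejected(self):
        training = make_training([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_biomass_model(training, QUADRATIC_NO_INTERCEPT)

    def test_duplicate_powers_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(powers=(2, 2))


class TestPredict:
    def test_no_intercept_model_predicts_zero_at_zero_height(self, toy_training):
        fit = fit_biomass_model(toy_training, QUADRATIC_NO_INTERCEPT)
        assert predict_biomass(fit, 0.0)[0] == 0.0

    def test_published_coefficient_arithmetic(self):
        fit = ModelFit(
            spec=QUADRATIC_NO_INTERCEPT,
            beta_hat=np.array([0.3717]),
            cov_beta=np.zeros((1, 1)),
            mse=0.0,
            dof=1,
            m=2,
            sse=0.0,
        )
        assert predict_biomass(fit, 20.0)[0] == pytest.approx(148.68)

    def test_unit_coefficient(self):
        fit = fit_biomass_model(
            make_training([1, 2, 3], [1, 4, 9]), QUADRATIC_NO_INTERCEPT
        )
        assert predict_biomass(fit, 3.0)[0] == pytest.approx(9.0)

    def test_negative_height_rejected(self, toy_training):
        fit = fit_biomass_model(toy_training, QUADRATIC_NO_INTERCEPT)
        with pytest.raises(ValueError):
            predict_biomass(fit, -1.0)


class TestEstimate:
    def test_constant_heights_have_zero_sampling_variance(self, toy_training):
        fit = fit_biomass_model(toy_training, QUADRATIC_NO_INTERCEPT)
        res = estimate_population_mean(fit, [2.0, 2.0, 2.0])
        assert res.sampling_summand == pytest.approx(0.0)
        assert res.model_summand == pytest.approx(
            fit.cov_beta[0, 0] * (4.0 ** 2), rel=1e-12
        )

    def test_two_plot_hand_computation(self, toy_training):
        fit = fit_biomass_model(toy_training, QUADRATIC_NO_INTERCEPT)
        res = estimate_population_mean(fit, [1.0, 3.0])
        assert res.mean_estimate == pytest.approx(90 / 17, rel=1e-12)  # ~5.2941
        assert res.sampling_summand == pytest.approx(17.9378, rel=1e-4)
        assert res.model_summand == pytest.approx(16 / 17 / 17 * 25, rel=1e-12)
        assert res.standard_error == pytest.approx(4.3957, rel=1e-4)
        assert res.design_moments[2] == pytest.approx(5.0)

    def test_variance_is_the_sum_of_its_summands(self, toy_training, rng):
        fit = fit_biomass_model(toy_training, QUADRATIC_NO_INTERCEPT)
        res = estimate_population_mean(fit, rng.uniform(1, 2, 50))
        assert res.total_variance == res.sampling_summand + res.model_summand
        assert res.standard_error == pytest.approx(np.sqrt(res.total_variance))

    def test_single_term_collapse_matches_generic_double_sum(self, rng):
        # the generic double sum over (k, l) must reduce to V(beta)*(mean x^2)^2
        h = rng.uniform(5, 40, 30)
        y = 0.4 * h ** 2 + rng.normal(0, 15, 30)
        fit = fit_biomass_model(make_training(h, y), QUADRATIC_NO_INTERCEPT)
        s1 = rng.uniform(5, 40, 80)
        res = estimate_population_mean(fit, s1)
        collapsed = fit.cov_beta[0, 0] * np.mean(s1 ** 2) ** 2
        assert res.model_summand == pytest.approx(collapsed, rel=1e-12)

    def test_generic_double_sum_against_loop_oracle(self, rng):
        spec = ModelSpec(powers=(1, 2), include_intercept=True)
        h = rng.uniform(5, 40, 30)
        y = 10 + 2 * h + 0.4 * h ** 2 + rng.normal(0, 15, 30)
        fit = fit_biomass_model(make_training(h, y), spec)
        s1 = rng.uniform(5, 40, 80)
        res = estimate_population_mean(fit, s1)
        powers = spec.all_powers
        oracle = sum(
            fit.cov_beta[a, b] * np.mean(s1 ** powers[a]) * np.mean(s1 ** powers[b])
            for a in range(len(powers))
            for b in range(len(powers))
        )
        assert res.model_summand == pytest.approx(oracle, rel=1e-12)

    def test_zero_noise_recovery(self, rng):
        h = rng.uniform(5, 40, 20)
        fit = fit_biomass_model(make_training(h, 0.37 * h ** 2), QUADRATIC_NO_INTERCEPT)
        s1 = rng.uniform(5, 40, 60)
        res = estimate_population_mean(fit, s1)
        assert fit.beta_hat[0] == pytest.approx(0.37, rel=1e-10)
        assert res.model_summand == pytest.approx(0.0, abs=1e-15)
        assert res.mean_estimate == pytest.approx(np.mean(0.37 * s1 ** 2), rel=1e-10)

    def test_scale_equivariance(self, rng):
        h = rng.uniform(5, 40, 25)
        y = 0.4 * h ** 2 + rng.normal(0, 10, 25)
        s1 = rng.uniform(5, 40, 40)
        c = 3.7
        res1 = estimate_population_mean(
            fit_biomass_model(make_training(h, y), QUADRATIC_NO_INTERCEPT), s1
        )
        res2 = estimate_population_mean(
            fit_biomass_model(make_training(h, c * y), QUADRATIC_NO_INTERCEPT), s1
        )
        assert res2.mean_estimate == pytest.approx(c * res1.mean_estimate, rel=1e-10)
        assert res2.sampling_summand == pytest.approx(
            c ** 2 * res1.sampling_summand, rel=1e-10
        )
        assert res2.model_summand == pytest.approx(
            c ** 2 * res1.model_summand, rel=1e-10
        )

    def test_fpc_shrinks_only_the_sampling_summand(self, toy_training):
        fit = fit_biomass_model(toy_training, QUADRATIC_NO_INTERCEPT)
        plain = estimate_population_mean(fit, [1.0, 3.0])
        fpc = estimate_population_mean(fit, [1.0, 3.0], fpc=0.5)
        assert fpc.sampling_summand == pytest.approx(0.5 * plain.sampling_summand)
        assert fpc.model_summand == plain.model_summand

    def test_extrapolated_heights_are_reported_and_logged(self, toy_training, caplog):
        fit = fit_biomass_model(toy_training, QUADRATIC_NO_INTERCEPT)
        with caplog.at_level(logging.WARNING, logger="curvesample.estimation"):
            res = estimate_population_mean(fit, [1.0, 2.5, 3.0])
        assert res.extrapolated_heights == (2.5, 3.0)
        assert "exceed the training maximum" in caplog.text

    def test_empty_sample_rejected(self, toy_training):
        fit = fit_biomass_model(toy_training, QUADRATIC_NO_INTERCEPT)
        with pytest.raises(ValueError):
            estimate_population_mean(fit, [])


class TestRSquared:
    def test_perfect_fit_is_one(self):
        training = make_training([1, 2, 3], [1, 4, 9])
        fit = fit_biomass_model(training, QUADRATIC_NO_INTERCEPT)
        assert r_squared_uncentered(fit, training) == pytest.approx(1.0)

    def test_zero_prediction_is_zero(self):
        training = make_training([1.0, 2.0], [3.0, 5.0])
        fit = ModelFit(
            spec=QUADRATIC_NO_INTERCEPT,
            beta_hat=np.array([0.0]),
            cov_beta=np.zeros((1, 1)),
            mse=0.0,
            dof=1,
            m=2,
            sse=34.0,
        )
        assert r_squared_uncentered(fit, training) == pytest.approx(0.0)

    def test_all_zero_responses_rejected(self):
        training = make_training([1.0, 2.0], [0.0, 0.0])
        fit = fit_biomass_model(make_training([1, 2, 3], [1, 4, 9]), QUADRATIC_NO_INTERCEPT)
        with pytest.raises(ValueError):
            r_squared_uncentered(fit, training)


class TestConditionalRSquared:
    def test_no_gain_is_zero(self):
        assert conditional_r_squared(10.0, 10.0) == pytest.approx(0.0)

    def test_perfect_full_model_is_one(self):
        assert conditional_r_squared(0.0, 10.0) == pytest.approx(1.0)

    def test_zero_reduced_sse_rejected(self):
        with pytest.raises(ValueError):
            conditional_r_squared(0.0, 0.0)

    def test_nested_models_on_data(self, rng):
        h = rng.uniform(5, 40, 30)
        y = 0.4 * h ** 2 + rng.normal(0, 15, 30)
        training = make_training(h, y)
        reduced = fit_biomass_model(training, QUADRATIC_NO_INTERCEPT)
        full = fit_biomass_model(
            training, ModelSpec(powers=(2,), include_intercept=True)
        )
        r2 = conditional_r_squared(full.sse, reduced.sse)
        assert 0.0 <= r2 < 1.0
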