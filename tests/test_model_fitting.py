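"""Quadratic regression, critical R², adequacy rule, and bootstrap uncertainty."""

import numpy as np
import pytest
from scipy import stats

from nadex import (
    ExtractionObservation,
    ModelParams,
    adequacy_decision,
    critical_r_squared,
    epsilon_opt_uncertainty,
    fit_transformed_quadratic,
    predict_concentration,
    r_squared,
)
from nadex.synthetic_data import SimulationConfig, generate_study

EPS_GRID = (26.0, 34.0, 41.0, 50.0, 61.0)


def noiseless_obs(params, system, grid=EPS_GRID):
    return [
        ExtractionObservation(epsilon=e, concentration=predict_concentration(params, e, system))
        for e in grid
    ]


class TestFitTransformedQuadratic:
    def test_exact_recovery_on_noiseless_points(self, system):
        truth = ModelParams(b=17400.0, d=-2 * 17400.0 / 45.0, f=1.0 + 17400.0 / 45.0**2)
        fit = fit_transformed_quadratic(noiseless_obs(truth, system), system)
        assert fit.params.b == pytest.approx(truth.b, rel=1e-9)
        assert fit.params.d == pytest.approx(truth.d, rel=1e-9)
        assert fit.params.f == pytest.approx(truth.f, rel=1e-9)
        assert fit.r2_e == pytest.approx(1.0, abs=1e-12)
        assert fit.epsilon_opt == pytest.approx(45.0, rel=1e-9)
        assert fit.adequate

    def test_agrees_with_statsmodels_ols(self, system):
        """Independent route: statsmodels OLS on the same design matrix."""
        import statsmodels.api as sm

        cfg = SimulationConfig(sigma=0.1, seed=11)
        obs, _ = generate_study(cfg)
        fit = fit_transformed_quadratic(obs, system)
        X = sm.add_constant(np.column_stack([fit.x, fit.x**2]))
        res = sm.OLS(fit.y, X).fit()
        assert fit.params.f == pytest.approx(res.params[0], rel=1e-8)
        assert fit.params.d == pytest.approx(res.params[1], rel=1e-8)
        assert fit.params.b == pytest.approx(res.params[2], rel=1e-8)
        assert fit.r2_e == pytest.approx(res.rsquared, rel=1e-10)

    def test_needs_four_points(self, system):
        truth = ModelParams(1000.0, -40.0, 2.0)
        with pytest.raises(ValueError, match=">= 4"):
            fit_transformed_quadratic(noiseless_obs(truth, system, EPS_GRID[:3]), system)

    def test_rank_deficiency_with_two_distinct_eps(self, system):
        truth = ModelParams(1000.0, -40.0, 2.0)
        obs = noiseless_obs(truth, system, (26.0, 26.0, 34.0, 34.0))
        with pytest.raises(ValueError, match="rank"):
            fit_transformed_quadratic(obs, system)

    def test_shift_equivariance(self, system):
        """Scaling all concentrations shifts y; only f changes."""
        truth = ModelParams(17400.0, -800.0, 9.0)
        obs1 = noiseless_obs(truth, system)
        fit1 = fit_transformed_quadratic(obs1, system)
        shift = 0.6
        obs2 = [
            ExtractionObservation(
                epsilon=o.epsilon,
                concentration=system.m0
                / (system.V * (1 + np.exp(np.log(system.m0 / (o.concentration * system.V) - 1) + shift))),
            )
            for o in obs1
        ]
        fit2 = fit_transformed_quadratic(obs2, system)
        assert fit2.params.b == pytest.approx(fit1.params.b, rel=1e-7, abs=1e-6)
        assert fit2.params.d == pytest.approx(fit1.params.d, rel=1e-7, abs=1e-6)
        assert fit2.params.f - fit1.params.f == pytest.approx(shift, rel=1e-7)

    def test_noisy_recovery_within_reported_range(self, system, true_params):
        cfg = SimulationConfig(sigma=0.05, seed=3)
        obs, truth = generate_study(cfg)
        fit = fit_transformed_quadratic(obs, system)
        assert 40.0 <= fit.epsilon_opt <= 50.0


class TestRSquared:
    def test_perfect_fit(self):
        assert r_squared([1.0, 2.0, 4.0], [1.0, 2.0, 4.0]) == 1.0

    def test_mean_predictor_scores_zero(self):
        y = [0.0, 1.0, 2.0]
        assert r_squared(y, [1.0, 1.0, 1.0]) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert r_squared([0.0, 1.0, 2.0], [0.0, 1.0, 1.0]) == pytest.approx(0.5)

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 1.0])


class TestCriticalRSquared:
    def test_printed_table_value(self):
        """n = 5 points at 99% acceptance probability gives the 0.919 table value."""
        assert critical_r_squared(5, alpha=0.01, p=1) == pytest.approx(0.919, abs=5e-4)

    def test_t_quantile_oracle(self):
        """Independent oracle: R2_t = t²/(t²+df) with t the 0.995 quantile at df=3."""
        t = stats.t.ppf(1 - 0.01 / 2, 3)
        assert t == pytest.approx(5.8409, abs=1e-4)
        assert critical_r_squared(5, 0.01, 1) == pytest.approx(t**2 / (t**2 + 3), rel=1e-12)

    def test_monotone_in_n_and_alpha(self):
        values_n = [critical_r_squared(n, 0.01, 1) for n in range(4, 20)]
        assert all(a > b for a, b in zip(values_n, values_n[1:]))
        assert critical_r_squared(5, 0.001, 1) > critical_r_squared(5, 0.01, 1)

    def test_stricter_p2_convention_available(self):
        assert critical_r_squared(5, 0.01, p=2) > critical_r_squared(5, 0.01, p=1)

    def test_invalid_df(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            critical_r_squared(2, 0.01, 1)


class TestAdequacy:
    def test_study_values_adequate(self, system, true_params):
        fit = fit_transformed_quadratic(noiseless_obs(true_params, system), system)
        fit.r2_e = 0.993
        verdict, report = adequacy_decision(fit)
        assert verdict and report["r2_t"] == pytest.approx(0.919, abs=5e-4)

    def test_strict_inequality_at_boundary(self, system, true_params):
        fit = fit_transformed_quadratic(noiseless_obs(true_params, system), system)
        fit.r2_e = fit.r2_t
        verdict, _ = adequacy_decision(fit)
        assert not verdict

    def test_poor_fit_not_adequate(self, system, true_params):
        fit = fit_transformed_quadratic(noiseless_obs(true_params, system), system)
        fit.r2_e = 0.5
        assert not adequacy_decision(fit)[0]


class TestBootstrapUncertainty:
    def test_noiseless_halfwidth_vanishes(self, system, true_params):
        obs = noiseless_obs(true_params, system)
        fit = fit_transformed_quadratic(obs, system)
        res = epsilon_opt_uncertainty(fit, obs, system, n_boot=200, seed=0)
        assert res.halfwidth < 1e-6

    def test_reproducible_under_seed(self, system):
        cfg = SimulationConfig(sigma=0.05, seed=5)
        obs, _ = generate_study(cfg)
        fit = fit_transformed_quadratic(obs, system)
        r1 = epsilon_opt_uncertainty(fit, obs, system, n_boot=500, seed=9)
        r2 = epsilon_opt_uncertainty(fit, obs, system, n_boot=500, seed=9)
        assert r1.halfwidth == r2.halfwidth
        assert np.array_equal(r1.epsilon_opt_samples, r2.epsilon_opt_samples)
        assert 0 < r1.halfwidth < 10  # plausible single-digit half-width

    def test_more_noise_wider_interval(self, system):
        medians = []
        for sigma in (0.05, 0.1):
            widths = []
            for seed in range(20):
                cfg = SimulationConfig(sigma=sigma, seed=100 + seed)
                obs, _ = generate_study(cfg)
                fit = fit_transformed_quadratic(obs, system)
                if fit.epsilon_opt is None:
                    continue
                widths.append(
                    epsilon_opt_uncertainty(fit, obs, system, n_boot=300, seed=seed).halfwidth
                )
            medians.append(np.median(widths))
        assert medians[1] > medians[0]
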