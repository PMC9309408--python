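"""Unit and property tests for the joint frailty-logistic model core."""

import math

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import poisson

from accept2.exceptions import ConfigurationError, MissingPredictorError
from accept2.model_core import (
    count_pmf,
    fit_joint_model,
    linear_predictor,
    marginal_rate,
    outcome_probabilities,
    pattern_probabilities,
    predict_cohort,
    severity_probability,
    solve_eta_rate_for_marginal,
    solve_eta_sev_for_severity,
)
from accept2.types import CoefficientSet, EventHistory
from conftest import simulate_pattern_probs


class TestLinearPredictor:
    def test_intercept_only(self, toy_covariates):
        assert linear_predictor(toy_covariates, {"intercept": 0.3}) == pytest.approx(0.3)

    def test_single_term(self, toy_covariates):
        toy_covariates.age = 60.0
        assert linear_predictor(toy_covariates, {"intercept": 0.0, "age": 0.01}) == pytest.approx(0.6)

    def test_matches_hand_summed_dot_product(self, toy_covariates):
        coefs = {
            "intercept": -0.4,
            "n_moderate_prior": 0.25,
            "age": 0.004,
            "fev1_pct_pred": -0.011,
            "sgrq": 0.009,
            "ics": 0.1,
        }
        expected = (
            -0.4 + 0.25 * 1 + 0.004 * 63.0 - 0.011 * 48.0 + 0.009 * 45.0 + 0.1 * 1
        )
        assert linear_predictor(toy_covariates, coefs) == pytest.approx(expected, abs=1e-12)

    def test_missing_predictor_named(self, toy_covariates):
        toy_covariates.lama = None
        with pytest.raises(MissingPredictorError, match="lama"):
            linear_predictor(toy_covariates, {"intercept": 0.0, "lama": 0.1})


class TestMarginalRate:
    def test_zero_eta_zero_sigma(self):
        assert marginal_rate(0.0, 0.0, 1.0) == pytest.approx(1.0)

    def test_lognormal_mean_identity(self):
        assert marginal_rate(0.0, 1.0, 1.0) == pytest.approx(math.exp(0.5))

    @pytest.mark.parametrize("eta", [-1.5, 0.0, 0.7])
    def test_degenerate_frailty(self, eta):
        assert marginal_rate(eta, 0.0, 2.5) == pytest.approx(2.5 * math.exp(eta))

    def test_rejects_nonpositive_horizon(self):
        with pytest.raises(ValueError):
            marginal_rate(0.0, 0.5, 0.0)

    def test_invertible(self):
        eta = solve_eta_rate_for_marginal(1.7, 0.8)
        assert marginal_rate(eta, 0.8, 1.0) == pytest.approx(1.7)


class TestSeverityProbability:
    def test_no_random_effect_is_expit(self):
        assert severity_probability(0.0, 0.0) == pytest.approx(0.5)
        assert severity_probability(1.3, 0.0) == pytest.approx(expit(1.3))

    def test_matches_monte_carlo(self):
        # E[expit(z)], z ~ N(0, 4), via 1e6 draws
        rng = np.random.default_rng(7)
        draws = expit(rng.normal(0.0, 2.0, size=10**6))
        mc, se = draws.mean(), draws.std() / 1000.0
        assert severity_probability(0.0, 2.0) == pytest.approx(mc, abs=3 * se)

    def test_boundary(self):
        assert severity_probability(-30.0, 1.0) < 1e-10

    def test_inversion_round_trip(self):
        eta = solve_eta_sev_for_severity(0.23, 1.1)
        assert severity_probability(eta, 1.1) == pytest.approx(0.23, abs=1e-10)


class TestCountPmf:
    def test_poisson_limit(self):
        pmf = count_pmf(0.0, 0.0, 1.0, 10)
        np.testing.assert_allclose(pmf, poisson.pmf(np.arange(11), 1.0), atol=1e-10)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(11)
        lam = np.exp(0.0 + 0.5 * rng.standard_normal(10**6))
        draws = rng.poisson(lam)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # truncation is immaterial here
            pmf = count_pmf(0.0, 0.5, 1.0, 6)
        for k in range(7):
            frac = np.mean(draws == k)
            se = math.sqrt(frac * (1 - frac) / 10**6)
            assert pmf[k] == pytest.approx(frac, abs=3 * se + 1e-9)

    def test_no_exposure(self):
        pmf = count_pmf(0.0, 0.7, 1e-9, 3)
        assert pmf[0] == pytest.approx(1.0, abs=1e-6)

    def test_warns_on_truncated_tail(self):
        with pytest.warns(RuntimeWarning, match="residual tail mass"):
            count_pmf(2.0, 0.5, 1.0, 1)


class TestOutcomeProbabilities:
    def test_closed_form_poisson_thinning(self, toy_covariates):
        # lambda = 1, p = 0.2, t = 1, no random effects
        coef = CoefficientSet(
            beta_rate={"intercept": 0.0},
            gamma_sev={"intercept": math.log(0.2 / 0.8)},
            sigma1=0.0,
            sigma2=0.0,
            rho=0.0,
        )
        res = outcome_probabilities(toy_covariates, coef, horizon=1.0)
        assert res.p_any == pytest.approx(1 - math.exp(-1.0), abs=1e-8)
        assert res.p_any_severe == pytest.approx(1 - math.exp(-0.2), abs=1e-8)
        assert res.p_primary == pytest.approx(1 - math.exp(-1.0) * (1 + 0.8), abs=1e-8)

    def test_no_events_limit(self, toy_covariates):
        coef = CoefficientSet(
            beta_rate={"intercept": -30.0}, gamma_sev={"intercept": 0.0},
            sigma1=0.5, sigma2=0.5, rho=0.0,
        )
        res = outcome_probabilities(toy_covariates, coef)
        assert res.p_any < 1e-8 and res.p_primary < 1e-8 and res.p_any_severe < 1e-8

    def test_matches_event_level_simulation(self):
        est, se = simulate_pattern_probs(0.2, -0.8, 0.8, 0.5, 0.3, 1.0, 10**6, seed=5)
        out = pattern_probabilities(0.2, -0.8, 0.8, 0.5, 0.3, 1.0)
        for key in ("p_any", "p_any_severe", "p_primary"):
            assert float(out[key][0]) == pytest.approx(est[key], abs=3 * se[key])

    def test_rejects_invalid_correlation(self):
        with pytest.raises(ConfigurationError):
            pattern_probabilities(0.0, 0.0, 0.5, 0.5, 1.5, 1.0)

    @pytest.mark.parametrize("horizon", [0.5, 1.0, 2.0])
    def test_severe_rate_below_all_rate(self, horizon):
        out = pattern_probabilities(0.3, 0.2, 0.9, 0.7, -0.4, horizon)
        assert out["rate_severe"][0] <= out["rate_all"][0] + 1e-12
        assert out["p_any_severe"][0] <= out["p_any"][0] + 1e-12
        assert out["p_primary"][0] <= out["p_any"][0] + 1e-12

    def test_thinning_consistency_without_severity_effects(self):
        # with sigma2 = rho = 0 the severe rate is exactly rate_all * p
        out = pattern_probabilities(0.1, -0.7, 0.8, 0.0, 0.0, 1.0)
        assert out["rate_severe"][0] == pytest.approx(
            out["rate_all"][0] * expit(-0.7), rel=1e-10
        )

    def test_monotone_in_horizon_and_rate(self):
        horizons = [0.25, 0.5, 1.0, 2.0, 4.0]
        vals = [
            pattern_probabilities(0.0, -0.5, 0.6, 0.4, 0.2, h)["p_primary"][0]
            for h in horizons
        ]
        assert np.all(np.diff(vals) > 0)
        etas = np.linspace(-2, 2, 9)
        out = pattern_probabilities(etas, -0.5, 0.6, 0.4, 0.2, 1.0)
        for key in ("p_any", "p_any_severe", "p_primary"):
            assert np.all(np.diff(out[key]) > 0)

    def test_sigma_zero_matches_closed_form_on_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            eta_r = rng.uniform(-1.5, 1.0)
            eta_s = rng.uniform(-2.0, 1.0)
            t = rng.uniform(0.3, 2.0)
            lam, p = math.exp(eta_r), expit(eta_s)
            out = pattern_probabilities(eta_r, eta_s, 0.0, 0.0, 0.0, t)
            assert out["p_any"][0] == pytest.approx(1 - math.exp(-t * lam), abs=1e-8)
            assert out["p_any_severe"][0] == pytest.approx(
                1 - math.exp(-t * lam * p), abs=1e-8
            )
            assert out["p_primary"][0] == pytest.approx(
                1 - math.exp(-t * lam) * (1 + t * lam * (1 - p)), abs=1e-8
            )


from conftest import simulate_fit_cohort as _simulate_fit_cohort  # noqa: E402


class TestFitJointModel:
    def test_recovers_poisson_logistic_without_frailty(self):
        beta = np.array([0.2, 0.4, -0.3, 0.0])
        gamma = np.array([-0.5, 0.6, 0.0, -0.4])
        cohort = _simulate_fit_cohort(2000, beta, gamma, 0.0, 0.0, 0.0, seed=123)
        fit = fit_joint_model(
            cohort, variant="custom", predictors=["x1", "x2", "x3"],
            n_starts=1, compute_se=False,
        )
        est_b = [fit.coefficients.beta_rate[k] for k in ("intercept", "x1", "x2", "x3")]
        est_g = [fit.coefficients.gamma_sev[k] for k in ("intercept", "x1", "x2", "x3")]
        np.testing.assert_allclose(est_b, beta, atol=0.1)
        np.testing.assert_allclose(est_g, gamma, atol=0.1)
        assert fit.coefficients.sigma1 < 0.1
        assert fit.coefficients.sigma2 < 0.3

    def test_degenerate_all_moderate(self):
        rng = np.random.default_rng(4)
        cohort = []
        for _ in range(60):
            n = int(rng.poisson(2.0))
            times = sorted(max(float(t), 1e-9) for t in rng.random(n))
            cohort.append(({"x1": float(rng.standard_normal())},
                           EventHistory(1.0, [(t, 0) for t in times])))
        fit = fit_joint_model(cohort, variant="custom", predictors=["x1"],
                              n_starts=1, compute_se=False)
        # no severe events: severity intercept driven to a large negative value
        assert fit.coefficients.gamma_sev["intercept"] < -3.0

    def test_loglik_not_below_moment_start(self):
        cohort = _simulate_fit_cohort(
            300, np.array([0.0, 0.3, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0, 0.0]),
            0.6, 0.4, 0.2, seed=9,
        )
        fit = fit_joint_model(cohort, variant="custom", predictors=["x1", "x2", "x3"],
                              n_starts=2, compute_se=False)
        assert np.isfinite(fit.loglik)

    def test_bias_shrinks_with_sample_size(self):
        beta = np.array([0.1, 0.35, -0.25, 0.15])
        gamma = np.array([-0.8, 0.5, -0.3, 0.2])
        s1, s2, rho = 0.7, 0.8, 0.4
        errs = {}
        for n in (500, 4000):
            devs = []
            for rep in range(3):
                cohort = _simulate_fit_cohort(n, beta, gamma, s1, s2, rho, seed=100 * n + rep)
                fit = fit_joint_model(
                    cohort, variant="custom", predictors=["x1", "x2", "x3"],
                    n_starts=1, compute_se=False,
                )
                est = np.r_[
                    [fit.coefficients.beta_rate[k] for k in ("intercept", "x1", "x2", "x3")],
                    [fit.coefficients.gamma_sev[k] for k in ("intercept", "x1", "x2", "x3")],
                    fit.coefficients.sigma1, fit.coefficients.sigma2, fit.coefficients.rho,
                ]
                truth = np.r_[beta, gamma, s1, s2, rho]
                devs.append(np.abs(est - truth).mean())
            errs[n] = np.mean(devs)
        assert errs[4000] < errs[500]


class TestPredictCohort:
    def test_matches_scalar_path(self, toy_covariates, simple_coefficients):
        import pandas as pd

        df = pd.DataFrame([toy_covariates.as_dict()])
        batch = predict_cohort(df, simple_coefficients, horizon=1.0)
        single = outcome_probabilities(toy_covariates, simple_coefficients, horizon=1.0)
        for key in ("rate_all", "rate_severe", "p_any", "p_any_severe", "p_primary"):
            assert batch[key].iloc[0] == pytest.approx(getattr(single, key), rel=1e-12)

    def test_missing_column_raises(self, simple_coefficients):
        import pandas as pd

        df = pd.DataFrame({"age": [60.0]})
        with pytest.raises(MissingPredictorError):
            predict_cohort(df, simple_coefficients)
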