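"""Tests for calibration and discrimination metrics."""

import math

import numpy as np
import pytest

from accept2.exceptions import ConfigurationError, InsufficientDataError
from accept2.types import EventHistory
from accept2.validation import (
    TimeToOutcome,
    calibration_in_the_large,
    compare_auc,
    compare_ici_bootstrap,
    decile_calibration_table,
    derive_time_to_outcome,
    empirical_roc,
    integrated_calibration_index,
    mroc_curve,
    mroc_test,
    risk_distribution_summary,
    roc_auc_trapezoid,
    time_dependent_auc,
)


class TestDeriveTimeToOutcome:
    def test_two_moderates_trigger_primary_at_second(self):
        h = EventHistory(1.0, [(0.2, 0), (0.5, 0)])
        t = derive_time_to_outcome(h, "primary")
        assert t.observed == 1 and t.outcome_time == pytest.approx(0.5)

    def test_single_severe_triggers_primary_and_any_severe(self):
        h = EventHistory(1.0, [(0.3, 1)])
        for outcome in ("primary", "any_severe", "any"):
            t = derive_time_to_outcome(h, outcome)
            assert t.observed == 1 and t.outcome_time == pytest.approx(0.3)

    def test_single_moderate_triggers_only_any(self):
        h = EventHistory(1.0, [(0.4, 0)])
        assert derive_time_to_outcome(h, "any").observed == 1
        assert derive_time_to_outcome(h, "primary").observed == 0
        assert derive_time_to_outcome(h, "any_severe").observed == 0

    def test_no_events_censors_at_followup(self):
        h = EventHistory(0.8, [])
        for outcome in ("any", "any_severe", "primary"):
            t = derive_time_to_outcome(h, outcome)
            assert t.observed == 0 and t.censor_time == pytest.approx(0.8)


class TestDecileCalibration:
    def test_calibrated_simulation_covers_predictions(self):
        rng = np.random.default_rng(1)
        n = 10_000
        pred = np.exp(rng.normal(0.0, 0.5, n))
        fu = rng.uniform(0.5, 1.5, n)
        counts = rng.poisson(pred * fu)
        tab = decile_calibration_table(pred, counts, fu, scale="rate")
        covered = (
            (tab["ci_low"] <= tab["mean_predicted"]) & (tab["mean_predicted"] <= tab["ci_high"])
        ).sum()
        assert covered >= 8
        assert tab["n"].sum() == n
        assert tab["mean_predicted"].is_monotonic_increasing
        assert tab["n"].max() - tab["n"].min() <= 1

    def test_constant_predictions_warn(self):
        with pytest.warns(RuntimeWarning, match="constant predictions"):
            decile_calibration_table(np.ones(100), np.ones(100), np.ones(100), scale="rate")

    def test_doubled_predictions_show_half_observed(self):
        rng = np.random.default_rng(2)
        n = 20_000
        true_rate = np.exp(rng.normal(0.0, 0.5, n))
        fu = np.ones(n)
        counts = rng.poisson(true_rate)
        tab = decile_calibration_table(2 * true_rate, counts, fu, scale="rate")
        ratio = tab["observed"] / tab["mean_predicted"]
        np.testing.assert_allclose(ratio, 0.5, rtol=0.15)

    def test_risk_scale_binomial(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(0.05, 0.9, 5000)
        y = (rng.random(5000) < pred).astype(float)
        tab = decile_calibration_table(pred, y, scale="risk")
        covered = (
            (tab["ci_low"] <= tab["mean_predicted"]) & (tab["mean_predicted"] <= tab["ci_high"])
        ).sum()
        assert covered >= 8

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientDataError):
            decile_calibration_table(np.arange(5), np.zeros(5), np.ones(5))


class TestCalibrationInTheLarge:
    def test_self_simulation_near_zero(self):
        rng = np.random.default_rng(4)
        n = 50_000
        rate = np.exp(rng.normal(0.0, 0.4, n))
        fu = rng.uniform(0.5, 2.0, n)
        counts = rng.poisson(rate * fu)
        # the statistic compares mean predicted rate with total-event rate;
        # with variable follow-up these weight patients differently, so
        # compare against predictions matching the generating rates
        v = calibration_in_the_large(rate, counts, fu)
        person_time_rate = np.sum(rate * fu) / fu.sum()
        assert abs(v - (rate.mean() - person_time_rate)) < 0.02

    def test_zero_predictions(self):
        counts = np.array([1.0, 2.0, 0.0])
        fu = np.array([1.0, 1.0, 1.0])
        assert calibration_in_the_large(np.zeros(3), counts, fu) == pytest.approx(-1.0)

    def test_injected_offset_recovered(self):
        rng = np.random.default_rng(5)
        n = 50_000
        rate = np.exp(rng.normal(0.0, 0.4, n))
        counts = rng.poisson(rate)
        v = calibration_in_the_large(rate + 0.13, counts, np.ones(n))
        assert v == pytest.approx(0.13, abs=0.02)


class TestICI:
    def test_calibrated_predictions_give_small_ici(self):
        rng = np.random.default_rng(6)
        pred = rng.uniform(0.05, 0.9, 20_000)
        y = (rng.random(20_000) < pred).astype(float)
        assert integrated_calibration_index(pred, y) < 0.01

    def test_injected_bias_is_measured(self):
        rng = np.random.default_rng(7)
        pred = rng.uniform(0.05, 0.8, 20_000)
        y = (rng.random(20_000) < pred).astype(float)
        biased = np.clip(pred + 0.1, 0, 1)
        assert integrated_calibration_index(biased, y) == pytest.approx(0.1, abs=0.02)

    def test_flat_predictions_at_prevalence(self):
        rng = np.random.default_rng(8)
        y = (rng.random(5000) < 0.3).astype(float)
        pred = np.full(5000, y.mean())
        assert integrated_calibration_index(pred, y) < 1e-10

    def test_invariant_to_ordering(self):
        rng = np.random.default_rng(9)
        pred = rng.uniform(0, 1, 2000)
        y = (rng.random(2000) < pred).astype(float)
        perm = rng.permutation(2000)
        a = integrated_calibration_index(pred, y)
        b = integrated_calibration_index(pred[perm], y[perm])
        assert a == pytest.approx(b, abs=1e-12)

    def test_warns_below_fifty(self):
        with pytest.warns(RuntimeWarning, match="fewer than 50"):
            integrated_calibration_index(np.linspace(0.1, 0.9, 30), np.zeros(30))


class TestCompareICI:
    def test_identical_models(self):
        rng = np.random.default_rng(10)
        pred = rng.uniform(0, 1, 500)
        y = (rng.random(500) < pred).astype(float)
        out = compare_ici_bootstrap(pred, pred, y, B=200, seed=1)
        assert out["delta"] == 0.0
        assert out["p"] == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        predA = rng.uniform(0, 1, 400)
        predB = np.clip(predA + 0.05, 0, 1)
        y = (rng.random(400) < predA).astype(float)
        out1 = compare_ici_bootstrap(predA, predB, y, B=200, seed=7)
        out2 = compare_ici_bootstrap(predA, predB, y, B=200, seed=7)
        assert out1 == out2

    def test_detects_biased_competitor(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            pred = rng.uniform(0.05, 0.8, 2000)
            y = (rng.random(2000) < pred).astype(float)
            biased = np.clip(pred + 0.1, 0, 1)
            out = compare_ici_bootstrap(biased, pred, y, B=200, seed=rep)
            hits += out["p"] < 0.05
        assert hits >= 8


class TestMROC:
    def test_degenerate_risks_pass_through_corner(self):
        fpr, tpr = mroc_curve(np.array([1.0, 1.0, 0.0, 0.0]))
        # perfect expected separation: reaches TPR=1 while FPR=0
        assert tpr[np.searchsorted(fpr, 1e-12, side="right") - 1] == pytest.approx(1.0)

    def test_constant_predictions_give_diagonal(self):
        with pytest.warns(RuntimeWarning, match="diagonal"):
            fpr, tpr = mroc_curve(np.full(100, 0.5))
        np.testing.assert_allclose(tpr, fpr, atol=1e-12)

    def test_area_matches_bernoulli_expectation(self):
        rng = np.random.default_rng(12)
        pred = rng.uniform(0, 1, 10**5)
        fpr, tpr = mroc_curve(pred)
        area = roc_auc_trapezoid(fpr, tpr)
        # brute-force expectation: empirical AUC under outcomes ~ Bernoulli(pred)
        y = (rng.random(10**5) < pred).astype(float)
        e_fpr, e_tpr = empirical_roc(pred, y)
        area_mc = roc_auc_trapezoid(e_fpr, e_tpr)
        assert area == pytest.approx(area_mc, abs=0.005)

    def test_mroc_matches_empirical_roc_under_calibration(self):
        # sup distance shrinks toward zero as the sample grows
        sups = {}
        for n in (20_000, 100_000):
            rng = np.random.default_rng(13)
            pred = rng.uniform(0, 1, n)
            y = (rng.random(n) < pred).astype(float)
            m_fpr, m_tpr = mroc_curve(pred)
            e_fpr, e_tpr = empirical_roc(pred, y)
            sups[n] = np.max(np.abs(np.interp(e_fpr, m_fpr, m_tpr) - e_tpr))
        assert sups[20_000] < 0.06
        assert sups[100_000] < 0.02
        assert sups[100_000] < sups[20_000]


class TestMrocTest:
    def test_perfect_binary_predictions(self):
        pred = np.array([0.0] * 50 + [1.0] * 50)
        out = mroc_test(pred, pred.copy(), B=500, seed=0)
        assert out["p"] > 0.5

    def test_biased_predictions_rejected(self):
        rng = np.random.default_rng(14)
        pred = rng.uniform(0.05, 0.8, 2000)
        y = (rng.random(2000) < pred).astype(float)
        out = mroc_test(np.clip(pred + 0.15, 0, 1), y, B=500, seed=1)
        assert out["p"] < 0.05

    def test_calibrated_predictions_not_rejected(self):
        rng = np.random.default_rng(15)
        pred = rng.uniform(0.05, 0.8, 2000)
        y = (rng.random(2000) < pred).astype(float)
        out = mroc_test(pred, y, B=500, seed=2)
        assert out["p"] > 0.05


def _make_tto(times, events):
    return (np.asarray(times, float), np.asarray(events, float))


class TestTimeDependentAUC:
    def test_null_marker(self):
        rng = np.random.default_rng(16)
        n = 5000
        marker = rng.standard_normal(n)
        t = rng.exponential(1.0, n)
        fu = np.full(n, 2.0)
        times = np.minimum(t, fu)
        events = (t <= fu).astype(float)
        out = time_dependent_auc(marker, _make_tto(times, events), t_star=1.0, ci=False)
        assert out["auc"] == pytest.approx(0.5, abs=0.02)

    def test_reduces_to_mann_whitney_without_censoring(self):
        rng = np.random.default_rng(17)
        n = 800
        marker = rng.standard_normal(n)
        t = rng.exponential(np.exp(-marker))
        times = np.minimum(t, 3.0)
        events = (t <= 3.0).astype(float)
        out = time_dependent_auc(marker, _make_tto(times, events), t_star=1.0, ci=False)
        cases = times <= 1.0
        mc, mctl = marker[cases], marker[~cases]
        comp = (mc[:, None] > mctl[None, :]).sum() + 0.5 * (mc[:, None] == mctl[None, :]).sum()
        assert out["auc"] == pytest.approx(comp / (len(mc) * len(mctl)), abs=1e-12)

    def test_matches_numerical_oracle_under_censoring(self):
        # marker m ~ N(0,1); T | m ~ Exp(rate e^m); independent censoring.
        # The true case/control AUC at t* has a computable closed form by
        # numerical integration over the marker densities.
        from scipy.stats import norm

        t_star = 1.0
        grid = np.linspace(-6, 6, 4001)
        f = norm.pdf(grid)
        p_case = 1.0 - np.exp(-t_star * np.exp(grid))
        w_case = f * p_case
        w_ctrl = f * (1.0 - p_case)
        w_case /= np.trapezoid(w_case, grid)
        w_ctrl /= np.trapezoid(w_ctrl, grid)
        F_ctrl = np.concatenate([[0.0], np.cumsum((w_ctrl[1:] + w_ctrl[:-1]) / 2 * np.diff(grid))])
        auc_true = np.trapezoid(w_case * F_ctrl, grid)

        rng = np.random.default_rng(18)
        n = 10_000
        m = rng.standard_normal(n)
        t = rng.exponential(np.exp(-m))
        c = rng.uniform(0.2, 2.0, n)
        times = np.minimum(t, c)
        events = (t <= c).astype(float)
        out = time_dependent_auc(m, _make_tto(times, events), t_star=t_star, ci=False)
        assert out["auc"] == pytest.approx(auc_true, abs=0.02)

    def test_undefined_without_cases(self):
        with pytest.raises(InsufficientDataError):
            time_dependent_auc(
                np.arange(10.0), _make_tto(np.full(10, 2.0), np.zeros(10)), t_star=1.0
            )


class TestCompareAUC:
    def _data(self, seed, n=1500):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal(n)
        t = rng.exponential(np.exp(-m))
        times = np.minimum(t, 2.0)
        events = (t <= 2.0).astype(float)
        return m, _make_tto(times, events), rng

    def test_identical_markers(self):
        m, tto, _ = self._data(19)
        out = compare_auc(m, m, tto, B=100, seed=0)
        assert out["delta_auc"] == 0.0
        assert out["p"] == pytest.approx(1.0)

    def test_swap_flips_sign(self):
        m, tto, rng = self._data(20)
        noisy = m + rng.standard_normal(len(m))
        a = compare_auc(m, noisy, tto, B=100, seed=3)
        b = compare_auc(noisy, m, tto, B=100, seed=3)
        assert a["delta_auc"] == pytest.approx(-b["delta_auc"], abs=1e-12)

    def test_detects_noise_degraded_marker(self):
        hits = 0
        for rep in range(5):
            m, tto, rng = self._data(300 + rep, n=3000)
            noisy = m + 1.5 * rng.standard_normal(len(m))
            out = compare_auc(m, noisy, tto, B=200, seed=rep)
            hits += (out["delta_auc"] > 0) and (out["p"] < 0.05)
        assert hits >= 4


class TestRiskDistributionSummary:
    def test_identical_samples(self):
        x = np.linspace(0, 1, 100)
        out = risk_distribution_summary(x, x)
        assert out["smd"] == 0.0 and out["ks"] == 0.0

    def test_shifted_copy_has_unit_smd(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal(20_000)
        out = risk_distribution_summary(x + 1.0, x)
        assert out["smd"] == pytest.approx(1.0, abs=0.05)

    def test_disjoint_supports(self):
        out = risk_distribution_summary([1.0, 2.0, 3.0], [10.0, 11.0])
        assert out["ks"] == pytest.approx(1.0)
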