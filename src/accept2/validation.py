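"""Calibration and discrimination metrics for risk predictions on cohorts
with variable follow-up.

Calibration: decile tables of predicted vs observed rates/risks,
calibration-in-the-large, the integrated calibration index (ICI, mean
absolute distance between predictions and a smoothed observed curve), and a
model-based ROC (mROC) test of miscalibration.  Discrimination:
time-dependent (cumulative-case / dynamic-control) ROC and AUC at a landmark
time with inverse-probability-of-censoring weights, plus paired bootstrap
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import ConfigurationError, InsufficientDataError
from .types import EventHistory

__all__ = [
    "TimeToOutcome",
    "derive_time_to_outcome",
    "decile_calibration_table",
    "calibration_in_the_large",
    "integrated_calibration_index",
    "integrated_calibration_index_rate",
    "compare_ici_bootstrap",
    "mroc_curve",
    "empirical_roc",
    "mroc_test",
    "time_dependent_auc",
    "compare_auc",
    "risk_distribution_summary",
]


@dataclass
class TimeToOutcome:
    """First time an outcome pattern is met, with censoring information."""

    outcome_time: float
    observed: int
    censor_time: float

    def __post_init__(self) -> None:
        if self.observed not in (0, 1):
            raise ConfigurationError("observed must be 0/1")
        if self.observed and self.outcome_time > self.censor_time + 1e-12:
            raise ConfigurationError("observed outcomes must occur before censoring")

    @property
    def time(self) -> float:
        return self.outcome_time if self.observed else self.censor_time


def derive_time_to_outcome(history: EventHistory, outcome: str = "primary") -> TimeToOutcome:
    """Time at which an outcome pattern is first met within a history.

    Patterns: ``any`` (first event), ``any_severe`` (first severe event),
    ``primary`` (second moderate event or first severe event, whichever is
    earlier — the guideline 'frequent exacerbator' trigger of >=2 moderate or
    >=1 severe).  Censored at the follow-up time otherwise.
    """
    if outcome not in ("any", "any_severe", "primary"):
        raise ConfigurationError(f"unknown outcome pattern {outcome!r}")
    fu = history.followup
    t_hit = None
    n_moderate = 0
    for t, severe in history.events:
        if outcome == "any":
            t_hit = t
            break
        if severe:
            t_hit = t
            break
        if outcome == "primary":
            n_moderate += 1
            if n_moderate >= 2:
                t_hit = t
                break
    if t_hit is None:
        return TimeToOutcome(outcome_time=fu, observed=0, censor_time=fu)
    return TimeToOutcome(outcome_time=t_hit, observed=1, censor_time=fu)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def _poisson_rate_ci(count: float, exposure: float, alpha: float = 0.05):
    """Exact (Garwood) CI for a Poisson rate from a count and person-time."""
    lo = stats.chi2.ppf(alpha / 2.0, 2.0 * count) / 2.0 if count > 0 else 0.0
    hi = stats.chi2.ppf(1.0 - alpha / 2.0, 2.0 * (count + 1.0)) / 2.0
    return lo / exposure, hi / exposure


def _binomial_ci(k: float, n: float, alpha: float = 0.05):
    """Clopper-Pearson exact CI for a proportion."""
    lo = stats.beta.ppf(alpha / 2.0, k, n - k + 1.0) if k > 0 else 0.0
    hi = stats.beta.ppf(1.0 - alpha / 2.0, k + 1.0, n - k) if k < n else 1.0
    return float(lo), float(hi)


def decile_calibration_table(
    pred,
    observed,
    followup=None,
    scale: str = "rate",
    n_groups: int = 10,
) -> pd.DataFrame:
    """Group by deciles of the prediction and compare predicted vs observed.

    On the ``rate`` scale ``observed`` are event counts and ``followup``
    person-years: observed rate = sum(counts)/sum(person-years) with an exact
    Poisson CI.  On the ``risk`` scale ``observed`` is binary and the CI is
    exact binomial.  Ties spanning group boundaries are resolved by a stable
    sort, so group sizes differ by at most one.
    """
    pred = np.asarray(pred, dtype=float)
    n = len(pred)
    if n < n_groups:
        raise InsufficientDataError(f"need at least {n_groups} subjects, got {n}")
    observed = np.asarray(observed, dtype=float)
    if scale == "rate":
        if followup is None:
            raise ConfigurationError("rate scale requires follow-up times")
        followup = np.asarray(followup, dtype=float)
    elif scale == "risk":
        if not np.all(np.isin(observed, (0.0, 1.0))):
            raise ConfigurationError("risk scale requires a binary observed vector")
    else:
        raise ConfigurationError("scale must be 'rate' or 'risk'")
    if np.ptp(pred) == 0:
        warnings.warn(
            "constant predictions: decile grouping is degenerate (all groups identical)",
            RuntimeWarning,
            stacklevel=2,
        )

    order = np.argsort(pred, kind="stable")
    bounds = np.linspace(0, n, n_groups + 1).round().astype(int)
    rows = []
    for g in range(n_groups):
        idx = order[bounds[g] : bounds[g + 1]]
        mean_pred = float(pred[idx].mean())
        if scale == "rate":
            count = float(observed[idx].sum())
            py = float(followup[idx].sum())
            obs = count / py
            lo, hi = _poisson_rate_ci(count, py)
        else:
            count = float(observed[idx].sum())
            obs = count / len(idx)
            lo, hi = _binomial_ci(count, len(idx))
        rows.append(
            {
                "decile": g + 1,
                "n": len(idx),
                "mean_predicted": mean_pred,
                "observed": obs,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def calibration_in_the_large(pred_rate, observed_counts, followup) -> float:
    """Mean predicted rate minus the overall observed rate (events/person-yr)."""
    pred_rate = np.asarray(pred_rate, dtype=float)
    observed_counts = np.asarray(observed_counts, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if not (len(pred_rate) == len(observed_counts) == len(followup)):
        raise ConfigurationError("input vectors must have equal length")
    return float(pred_rate.mean() - observed_counts.sum() / followup.sum())


def _lowess_smooth(x, y, span: float) -> np.ndarray:
    """Local-linear smooth of y on x, evaluated at the x's themselves."""
    if np.ptp(x) == 0:
        # degenerate design: the only sensible smooth is the overall mean
        return np.full(len(x), np.mean(y))
    return lowess(y, x, frac=span, it=0, delta=0.01 * np.ptp(x), return_sorted=False)


def integrated_calibration_index(
    pred_risk, outcome, span: float = 0.75
) -> float:
    """ICI on the risk scale: mean |pred_i - smooth(outcome | pred)_i|.

    The smooth is a locally weighted linear regression (span 0.75 of the
    data) of the binary outcome on the predicted risk.  Lower is better; 0
    means the smoothed observed curve coincides with the predictions.
    """
    pred_risk = np.asarray(pred_risk, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if len(pred_risk) != len(outcome):
        raise ConfigurationError("pred and outcome must have equal length")
    if np.any((pred_risk < 0) | (pred_risk > 1)):
        raise ConfigurationError("pred_risk must lie in [0, 1]")
    if len(pred_risk) < 50:
        warnings.warn(
            "fewer than 50 observations: the calibration smoother is unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    smooth = _lowess_smooth(pred_risk, outcome, span)
    return float(np.mean(np.abs(pred_risk - smooth)))


def integrated_calibration_index_rate(
    pred_rate, observed_counts, followup, span: float = 0.75
) -> float:
    """Rate-scale ICI: mean |predicted rate - smoothed observed rate|.

    Per-patient observed rates (counts / follow-up) are smoothed against the
    predicted rates with the same local-linear smoother as the risk-scale
    ICI.
    """
    pred_rate = np.asarray(pred_rate, dtype=float)
    obs_rate = np.asarray(observed_counts, dtype=float) / np.asarray(followup, dtype=float)
    smooth = _lowess_smooth(pred_rate, obs_rate, span)
    return float(np.mean(np.abs(pred_rate - smooth)))


def compare_ici_bootstrap(
    predA, predB, outcome, B: int = 500, seed: int = 0, span: float = 0.75
) -> dict:
    """Patient-level bootstrap of the ICI difference between paired models.

    Returns ``{"delta": ICI_A - ICI_B, "ci95": (lo, hi), "p": two-sided}``
    with the p-value from the percentile bootstrap distribution of delta.
    """
    predA = np.asarray(predA, dtype=float)
    predB = np.asarray(predB, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if B < 200:
        warnings.warn("B < 200: bootstrap CI may be unreliable", RuntimeWarning, stacklevel=2)
    n = len(outcome)
    delta = integrated_calibration_index(predA, outcome, span) - integrated_calibration_index(
        predB, outcome, span
    )
    rng = np.random.default_rng(seed)
    deltas = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        deltas[b] = integrated_calibration_index(
            predA[idx], outcome[idx], span
        ) - integrated_calibration_index(predB[idx], outcome[idx], span)
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    # two-sided p: how often the bootstrap distribution crosses zero
    p_low = np.mean(deltas <= 0.0)
    p_high = np.mean(deltas >= 0.0)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return {"delta": float(delta), "ci95": (float(lo), float(hi)), "p": float(p)}


# ---------------------------------------------------------------------------
# mROC
# ---------------------------------------------------------------------------


def mroc_curve(pred_risk) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve expected under perfect calibration of the predicted risks.

    Walking subjects in descending predicted risk, each contributes
    ``pred_i / sum(pred)`` to the TPR and ``(1 - pred_i) / sum(1 - pred)``
    to the FPR — its expected contribution were the outcome truly
    Bernoulli(pred_i).  Divergence of the empirical ROC from this curve
    signals miscalibration.
    """
    pred = np.asarray(pred_risk, dtype=float)
    if np.any((pred < 0) | (pred > 1)):
        raise ConfigurationError("pred_risk must lie in [0, 1]")
    if np.ptp(pred) == 0:
        warnings.warn("all predictions equal: mROC is the diagonal", RuntimeWarning, stacklevel=2)
    order = np.argsort(-pred, kind="stable")
    p = pred[order]
    sum_p = p.sum()
    sum_q = (1.0 - p).sum()
    tpr = np.concatenate([[0.0], np.cumsum(p) / sum_p]) if sum_p > 0 else np.zeros(len(p) + 1)
    fpr = (
        np.concatenate([[0.0], np.cumsum(1.0 - p) / sum_q])
        if sum_q > 0
        else np.zeros(len(p) + 1)
    )
    if sum_p == 0:
        tpr = np.linspace(0, 1, len(p) + 1)
    if sum_q == 0:
        fpr = np.linspace(0, 1, len(p) + 1)
    return fpr, tpr


def empirical_roc(pred, outcome) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC by walking subjects in descending prediction order."""
    pred = np.asarray(pred, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    order = np.argsort(-pred, kind="stable")
    y = outcome[order]
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    tpr = np.concatenate([[0.0], np.cumsum(y) / max(n_pos, 1.0)])
    fpr = np.concatenate([[0.0], np.cumsum(1.0 - y) / max(n_neg, 1.0)])
    return fpr, tpr


def roc_auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def _roc_sup_distance(fpr_a, tpr_a, fpr_b, tpr_b) -> float:
    """Max vertical distance between two ROC curves (both directions)."""
    d1 = np.max(np.abs(tpr_a - np.interp(fpr_a, fpr_b, tpr_b)))
    d2 = np.max(np.abs(tpr_b - np.interp(fpr_b, fpr_a, tpr_a)))
    return float(max(d1, d2))


def mroc_test(pred_risk, outcome, B: int = 1000, seed: int = 0) -> dict:
    """Simulation-based test of calibration via the mROC construction.

    Two statistics are computed: (a) the absolute difference between mean
    predicted risk and outcome prevalence, and (b) the sup vertical distance
    between the empirical ROC and the mROC.  Their null distribution is
    obtained by redrawing outcomes as Bernoulli(pred_i); each statistic is
    standardized by its null moments and the test statistic is the larger of
    the two z-scores, giving a single p-value sensitive to both mean-level
    and shape miscalibration.
    """
    pred = np.asarray(pred_risk, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if len(pred) != len(outcome):
        raise ConfigurationError("pred and outcome must have equal length")
    if B < 500:
        warnings.warn("B < 500: mROC test p-value is coarse", RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    n = len(pred)

    order = np.argsort(-pred, kind="stable")
    p_sorted = pred[order]
    m_fpr, m_tpr = mroc_curve(pred)

    def _stats(y_sorted) -> tuple[float, float]:
        a = abs(p_sorted.mean() - y_sorted.mean())
        n_pos = y_sorted.sum()
        n_neg = n - n_pos
        if n_pos == 0 or n_neg == 0:
            return a, 1.0
        tpr = np.concatenate([[0.0], np.cumsum(y_sorted) / n_pos])
        fpr = np.concatenate([[0.0], np.cumsum(1.0 - y_sorted) / n_neg])
        return a, _roc_sup_distance(fpr, tpr, m_fpr, m_tpr)

    a_obs, b_obs = _stats(outcome[order])
    null = np.empty((B, 2))
    U = rng.random((B, n))
    for b in range(B):
        null[b] = _stats((U[b] < p_sorted).astype(float))
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z_null = (null - mu) / sd
    t_null = z_null.max(axis=1)
    t_obs = max((a_obs - mu[0]) / sd[0], (b_obs - mu[1]) / sd[1])
    p = (1.0 + np.sum(t_null >= t_obs)) / (B + 1.0)
    return {
        "p": float(p),
        "stat_cil": float(a_obs),
        "stat_sup": float(b_obs),
        "B": B,
    }


# ---------------------------------------------------------------------------
# Time-dependent discrimination
# ---------------------------------------------------------------------------


def _tto_arrays(tto) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(tto, tuple) and len(tto) == 2:
        return np.asarray(tto[0], dtype=float), np.asarray(tto[1], dtype=float)
    times = np.array([t.time for t in tto], dtype=float)
    events = np.array([t.observed for t in tto], dtype=float)
    return times, events


def _censoring_km(times, events):
    """Kaplan-Meier of the censoring distribution G(t) (censoring = event)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=1.0 - events)
    return kmf


def _ipcw_auc(marker, times, events, t_star, G=None) -> float:
    cases = (times <= t_star) & (events == 1)
    # a subject observed outcome-free through exactly t_star is a valid
    # control: their true outcome time necessarily exceeds t_star
    controls = (times > t_star) | ((times >= t_star) & (events == 0))
    if not cases.any() or not controls.any():
        raise InsufficientDataError(
            f"AUC undefined at t={t_star}: need both cases and controls"
        )
    if G is None:
        w_case = np.ones(cases.sum())
        w_ctrl = 1.0
    else:
        eps = 1e-9
        g_case = np.asarray(
            G.survival_function_at_times(np.maximum(times[cases] - eps, 0.0))
        )
        g_ctrl = float(G.survival_function_at_times([t_star]).iloc[0])
        g_case = np.maximum(g_case, 1e-8)
        g_ctrl = max(g_ctrl, 1e-8)
        w_case = 1.0 / g_case
        w_ctrl = 1.0 / g_ctrl  # common to all controls; cancels in the ratio
    m_case = np.asarray(marker, dtype=float)[cases]
    m_ctrl = np.asarray(marker, dtype=float)[controls]
    # weighted Mann-Whitney via sorting: O((n_case+n_ctrl) log n)
    order = np.argsort(m_ctrl, kind="stable")
    m_ctrl_sorted = m_ctrl[order]
    n_ctrl = len(m_ctrl)
    left = np.searchsorted(m_ctrl_sorted, m_case, side="left")
    right = np.searchsorted(m_ctrl_sorted, m_case, side="right")
    conc_per_case = left + 0.5 * (right - left)  # controls below + half ties
    num = float(np.sum(w_case * conc_per_case) * w_ctrl)
    den = float(w_case.sum() * n_ctrl * w_ctrl)
    return num / den


def time_dependent_auc(
    marker, tto, t_star: float = 1.0, B: int = 200, seed: int = 0, ci: bool = True
) -> dict:
    """Cumulative-case / dynamic-control AUC at a landmark time.

    Cases are subjects whose outcome occurred by ``t_star``; controls are
    those still outcome-free past ``t_star``.  Censoring before ``t_star`` is
    handled by inverse-probability-of-censoring weights from the
    Kaplan-Meier estimator of the censoring distribution.  With no censoring
    before ``t_star`` the estimator reduces exactly to the Mann-Whitney
    statistic of cases vs controls.  The CI is a patient-level percentile
    bootstrap.
    """
    if not t_star > 0:
        raise ConfigurationError("t_star must be > 0")
    marker = np.asarray(marker, dtype=float)
    times, events = _tto_arrays(tto)
    censored_early = (times < t_star) & (events == 0)
    G = _censoring_km(times, events) if censored_early.any() else None
    auc = _ipcw_auc(marker, times, events, t_star, G)
    out = {"auc": float(auc), "t_star": t_star}
    if ci:
        rng = np.random.default_rng(seed)
        n = len(marker)
        reps = []
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            try:
                Gb = (
                    _censoring_km(times[idx], events[idx])
                    if ((times[idx] < t_star) & (events[idx] == 0)).any()
                    else None
                )
                reps.append(_ipcw_auc(marker[idx], times[idx], events[idx], t_star, Gb))
            except InsufficientDataError:
                continue
        if reps:
            lo, hi = np.percentile(reps, [2.5, 97.5])
            out["ci95"] = (float(lo), float(hi))
    return out


def compare_auc(
    markerA, markerB, tto, t_star: float = 1.0, B: int = 500, seed: int = 0
) -> dict:
    """Paired patient-level bootstrap comparison of two time-dependent AUCs.

    Returns the AUC difference (A minus B) and a two-sided percentile
    bootstrap p-value; swapping the markers flips the sign of delta exactly
    for the same seed.
    """
    markerA = np.asarray(markerA, dtype=float)
    markerB = np.asarray(markerB, dtype=float)
    times, events = _tto_arrays(tto)
    n = len(markerA)

    def _auc_pair(idx) -> float:
        t, e = times[idx], events[idx]
        G = _censoring_km(t, e) if ((t < t_star) & (e == 0)).any() else None
        return _ipcw_auc(markerA[idx], t, e, t_star, G) - _ipcw_auc(
            markerB[idx], t, e, t_star, G
        )

    delta = _auc_pair(np.arange(n))
    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            deltas.append(_auc_pair(idx))
        except InsufficientDataError:
            continue
    deltas = np.asarray(deltas)
    p_low = np.mean(deltas <= 0.0)
    p_high = np.mean(deltas >= 0.0)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return {"delta_auc": float(delta), "p": float(p), "B": int(len(deltas))}


def risk_distribution_summary(predA, predB) -> dict:
    """Descriptive comparison of two predicted-risk distributions.

    Used to check, e.g., whether patients excluded for short follow-up have
    a different risk profile from those retained.  Reports means, SDs, the
    standardized mean difference (pooled-SD denominator), and the two-sample
    Kolmogorov-Smirnov distance.  Purely descriptive — no inference.
    """
    a = np.asarray(predA, dtype=float)
    b = np.asarray(predB, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigurationError("both samples must be non-empty")
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0) if min(len(a), len(b)) > 1 else 0.0
    smd = (a.mean() - b.mean()) / pooled if pooled > 0 else (0.0 if a.mean() == b.mean() else np.inf)
    ks = stats.ks_2samp(a, b).statistic
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        "sd_b": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
        "smd": float(smd),
        "ks": float(ks),
    }
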