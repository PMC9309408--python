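"""Synthetic COPD cohorts with the statistical structure the tool assumes.

Covariates are drawn independently from trial-like marginals; exacerbations
are generated by running the joint frailty-logistic model forward: each
patient draws correlated random effects (z1, z2), events arrive as a
homogeneous Poisson process with annual rate exp(eta_rate + z1), and each
event is severe with probability expit(eta_sev + z2).  Follow-up mixes
administrative censoring at the horizon with early exponential dropout.

Two ready-made profiles emulate the observational recalibration sample
("eclipse_like": mean age 63.3 y, 65.2% male, 1.20 moderate/severe and 0.27
severe events per person-year) and the trial placebo-arm validation sample
("torch_like": mean age 65.5 y, 77.2% male, 1.02 and 0.18 events per
person-year, medication-use indicator wholly missing).  They are software
test fixtures with matching headline margins, not reconstructions of the
underlying trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .model_core import cohort_linear_predictor, pattern_probabilities
from .types import CoefficientSet, EventHistory

__all__ = [
    "SimulationProfile",
    "eclipse_like",
    "torch_like",
    "demo_coefficients",
    "generate_covariates",
    "simulate_exacerbations",
    "split_predictor_outcome_windows",
    "miscalibration_scenario",
]

#: Follow-up (after the 1-year predictor window) below which a patient is
#: excluded from validation analyses.
MIN_OUTCOME_FOLLOWUP = 0.3

#: Caps applied to predictor-window event counts.  The scoring model is
#: log-linear in the history counts, so a handful of frailty-driven extreme
#: year-one counts would otherwise produce astronomically large predicted
#: rates; real risk scores accept history inputs only over a bounded
#: clinically plausible range.
PRIOR_MODERATE_CAP = 10
PRIOR_SEVERE_CAP = 5


@dataclass
class SimulationProfile:
    """Everything needed to generate one synthetic cohort reproducibly.

    ``covariates`` maps field names to distribution specs:
    ``("normal", mean, sd, lo, hi)`` (truncated), ``("bernoulli", p)`` or
    ``("poisson", mean)``.  ``missing`` maps fields to the fraction set to
    NaN after drawing.  ``horizon`` defaults to 2 years: year one is the
    predictor window, year two the outcome window.
    """

    n: int
    covariates: dict[str, tuple]
    true_coefficients: CoefficientSet
    horizon: float = 2.0
    dropout_fraction: float = 0.0
    dropout_mean: float = 1.0
    missing: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ConfigurationError("dropout_fraction must lie in [0, 1]")
        for name, spec in self.covariates.items():
            kind = spec[0]
            if kind == "bernoulli" and not 0.0 <= spec[1] <= 1.0:
                raise ConfigurationError(f"{name}: Bernoulli p must lie in [0, 1]")
            if kind == "normal" and spec[2] < 0:
                raise ConfigurationError(f"{name}: SD must be >= 0")
            if kind == "poisson" and spec[1] < 0:
                raise ConfigurationError(f"{name}: Poisson mean must be >= 0")
            if kind not in ("normal", "bernoulli", "poisson"):
                raise ConfigurationError(f"{name}: unknown distribution {kind!r}")


_ECLIPSE_COVARIATES = {
    # marginals: age and sex from the recalibration-sample description; the
    # remainder are realistic values for a moderate-to-severe COPD cohort.
    "n_moderate_prior": ("poisson", 0.9),
    "n_severe_prior": ("poisson", 0.2),
    "age": ("normal", 63.3, 7.1, 40.0, 90.0),
    "sex": ("bernoulli", 0.652),
    "smoker": ("bernoulli", 0.36),
    "fev1_pct_pred": ("normal", 48.0, 15.5, 15.0, 110.0),
    "sgrq": ("normal", 49.0, 17.0, 0.0, 100.0),
    "bmi": ("normal", 26.6, 5.6, 13.0, 55.0),
    "oxygen": ("bernoulli", 0.06),
    "statin": ("bernoulli", 0.25),
    "lama": ("bernoulli", 0.43),
    "laba": ("bernoulli", 0.45),
    "ics": ("bernoulli", 0.60),
}

_TORCH_COVARIATES = {
    **_ECLIPSE_COVARIATES,
    "age": ("normal", 65.5, 8.2, 40.0, 90.0),
    "sex": ("bernoulli", 0.772),
    "smoker": ("bernoulli", 0.43),
    "fev1_pct_pred": ("normal", 44.0, 12.5, 15.0, 100.0),
    "sgrq": ("normal", 51.0, 17.0, 0.0, 100.0),
    "bmi": ("normal", 25.4, 5.2, 13.0, 55.0),
    "n_moderate_prior": ("poisson", 0.75),
    "n_severe_prior": ("poisson", 0.13),
}

# slopes on plausible clinical scales; intercepts are calibrated numerically
# against the profile's target population rates at profile construction
_DEMO_BETA = {
    "intercept": 0.0,
    "n_moderate_prior": 0.22,
    "n_severe_prior": 0.33,
    "age": 0.005,
    "sex": -0.05,
    "smoker": 0.08,
    "fev1_pct_pred": -0.012,
    "sgrq": 0.008,
    "bmi": -0.010,
    "oxygen": 0.25,
    "statin": 0.05,
    "lama": 0.10,
    "laba": 0.08,
    "ics": 0.12,
}
_DEMO_GAMMA = {
    "intercept": 0.0,
    "n_moderate_prior": 0.05,
    "n_severe_prior": 0.45,
    "age": 0.012,
    "sex": 0.10,
    "smoker": 0.10,
    "fev1_pct_pred": -0.018,
    "sgrq": 0.010,
    "bmi": -0.020,
    "oxygen": 0.60,
    "statin": 0.10,
    "lama": 0.05,
    "laba": 0.05,
    "ics": 0.05,
}


def demo_coefficients(
    sigma1: float = 0.75, sigma2: float = 0.5, rho: float = 0.3
) -> CoefficientSet:
    """A synthetic demonstration coefficient set for the full model.

    Slopes are plausible in sign and magnitude but are NOT the published
    tool's coefficients (those are configuration inputs); the intercepts are
    placeholders until calibrated against a covariate profile.
    """
    return CoefficientSet(
        beta_rate=dict(_DEMO_BETA),
        gamma_sev=dict(_DEMO_GAMMA),
        sigma1=sigma1,
        sigma2=sigma2,
        rho=rho,
        variant="full",
    )


def _calibrate_intercepts(
    profile: SimulationProfile,
    target_rate_all: float,
    target_rate_severe: float,
    n_tune: int = 50_000,
    tune_seed: int = 987_654_321,
) -> CoefficientSet:
    """Shift the intercepts so population marginal rates hit the targets.

    The all-event rate scales exactly with exp(intercept shift); the severe
    rate is then matched by a 1-D root find on the severity intercept.
    """
    coef = profile.true_coefficients
    tune_profile = replace(
        profile, n=n_tune, seed=tune_seed, missing={}, true_coefficients=coef
    )
    df = generate_covariates(tune_profile)
    eta1 = cohort_linear_predictor(df, coef.beta_rate)
    eta2 = cohort_linear_predictor(df, coef.gamma_sev)

    mean_rate = float(np.mean(np.exp(eta1 + 0.5 * coef.sigma1**2)))
    shift1 = math.log(target_rate_all / mean_rate)
    eta1 = eta1 + shift1

    def severe_rate(shift2: float) -> float:
        out = pattern_probabilities(
            eta1, eta2 + shift2, coef.sigma1, coef.sigma2, coef.rho,
            horizon=1.0, quadrature_nodes=8,
        )
        return float(np.mean(out["rate_severe"]))

    from scipy.optimize import brentq

    shift2 = brentq(lambda s: severe_rate(s) - target_rate_severe, -15.0, 15.0, xtol=1e-8)

    beta = dict(coef.beta_rate)
    gamma = dict(coef.gamma_sev)
    beta["intercept"] = beta.get("intercept", 0.0) + shift1
    gamma["intercept"] = gamma.get("intercept", 0.0) + float(shift2)
    return CoefficientSet(
        beta_rate=beta, gamma_sev=gamma, sigma1=coef.sigma1, sigma2=coef.sigma2,
        rho=coef.rho, variant=coef.variant,
    )


_TUNED_CACHE: dict[str, CoefficientSet] = {}


def eclipse_like(n: int = 2000, seed: int = 0) -> SimulationProfile:
    """Observational-study-like profile: population rates 1.20 all / 0.27
    severe events per person-year, ~13% short follow-up."""
    profile = SimulationProfile(
        n=n,
        covariates=dict(_ECLIPSE_COVARIATES),
        true_coefficients=demo_coefficients(),
        horizon=2.0,
        dropout_fraction=0.18,
        dropout_mean=1.0,
        seed=seed,
    )
    if "eclipse" not in _TUNED_CACHE:
        _TUNED_CACHE["eclipse"] = _calibrate_intercepts(profile, 1.20, 0.27)
    profile.true_coefficients = _TUNED_CACHE["eclipse"]
    return profile


def torch_like(n: int = 1100, seed: int = 0) -> SimulationProfile:
    """Trial-placebo-arm-like profile: rates 1.02 all / 0.18 severe per
    person-year, ~28% short follow-up, medication indicator wholly missing
    and symptom score missing for ~24% (to exercise imputation)."""
    profile = SimulationProfile(
        n=n,
        covariates=dict(_TORCH_COVARIATES),
        true_coefficients=demo_coefficients(),
        horizon=2.0,
        dropout_fraction=0.39,
        dropout_mean=1.0,
        missing={"lama": 1.0, "sgrq": 0.24},
        seed=seed,
    )
    if "torch" not in _TUNED_CACHE:
        tune = replace(profile, missing={})
        _TUNED_CACHE["torch"] = _calibrate_intercepts(tune, 1.02, 0.18)
    profile.true_coefficients = _TUNED_CACHE["torch"]
    return profile


def generate_covariates(profile: SimulationProfile) -> pd.DataFrame:
    """Draw a cohort of covariates per the profile's marginals.

    Returns a DataFrame indexed by ``patient_id`` with one column per
    covariate plus the derived ``no_prior`` indicator (no exacerbation of
    either kind in the prior year).  Deterministic given the profile seed.
    """
    rng = np.random.default_rng([profile.seed, 0])
    n = profile.n
    cols: dict[str, np.ndarray] = {}
    for name, spec in profile.covariates.items():
        kind = spec[0]
        if kind == "normal":
            _, mean, sd, lo, hi = spec
            if sd == 0:
                cols[name] = np.full(n, float(mean))
            else:
                a, b = (lo - mean) / sd, (hi - mean) / sd
                cols[name] = stats.truncnorm.rvs(
                    a, b, loc=mean, scale=sd, size=n, random_state=rng
                )
        elif kind == "bernoulli":
            cols[name] = (rng.random(n) < spec[1]).astype(float)
        elif kind == "poisson":
            cols[name] = rng.poisson(spec[1], size=n).astype(float)
    df = pd.DataFrame(cols, index=pd.RangeIndex(n, name="patient_id"))
    if "n_moderate_prior" in df.columns and "n_severe_prior" in df.columns:
        df["no_prior"] = (
            (df["n_moderate_prior"] == 0) & (df["n_severe_prior"] == 0)
        ).astype(float)
    for name, frac in profile.missing.items():
        if frac > 0:
            mask = rng.random(n) < frac
            df.loc[mask, name] = np.nan
    return df


def simulate_exacerbations(
    cohort: pd.DataFrame,
    coef: CoefficientSet,
    profile: SimulationProfile,
    seed: int | None = None,
) -> list[EventHistory]:
    """Run the generative model forward over the full horizon.

    Per patient: draw (z1, z2) bivariate normal, follow-up from the
    censoring mixture, an event count N ~ Poisson(rate x follow-up) with
    rate exp(eta_rate + z1), event times uniform on (0, follow-up] (the
    order statistics of a homogeneous Poisson process), and severities
    Bernoulli(expit(eta_sev + z2)).
    """
    rng = np.random.default_rng([profile.seed if seed is None else seed, 1])
    n = len(cohort)
    eta1 = cohort_linear_predictor(cohort, coef.beta_rate)
    eta2 = cohort_linear_predictor(cohort, coef.gamma_sev)

    z = rng.standard_normal((n, 2))
    z1 = coef.sigma1 * z[:, 0]
    z2 = coef.sigma2 * (
        coef.rho * z[:, 0] + math.sqrt(max(0.0, 1.0 - coef.rho**2)) * z[:, 1]
    )
    lam = np.exp(eta1 + z1)
    p_sev = 1.0 / (1.0 + np.exp(-(eta2 + z2)))

    drops = rng.random(n) < profile.dropout_fraction
    dropout_t = rng.exponential(profile.dropout_mean, size=n)
    followup = np.where(drops, np.minimum(dropout_t, profile.horizon), profile.horizon)
    followup = np.maximum(followup, 1e-6)

    counts = rng.poisson(lam * followup)
    histories: list[EventHistory] = []
    for i in range(n):
        k = int(counts[i])
        if k == 0:
            histories.append(EventHistory(followup=float(followup[i]), events=[]))
            continue
        times = np.sort(rng.random(k)) * followup[i]
        times = np.maximum(times, 1e-9)
        severe = rng.random(k) < p_sev[i]
        histories.append(
            EventHistory(
                followup=float(followup[i]),
                events=[(float(t), int(s)) for t, s in zip(times, severe)],
            )
        )
    return histories


def split_predictor_outcome_windows(
    histories: list[EventHistory],
    split: float = 1.0,
    min_outcome_followup: float = MIN_OUTCOME_FOLLOWUP,
) -> tuple[pd.DataFrame, list[EventHistory | None]]:
    """Split each history into a predictor window and an outcome window.

    Events before ``split`` become the prior-year counts (capped at
    ``PRIOR_MODERATE_CAP`` / ``PRIOR_SEVERE_CAP``, the bounded input range a
    log-linear history score accepts); the outcome window is re-indexed to
    start at zero.  Patients whose outcome-window follow-up is below
    ``min_outcome_followup`` (or empty) are flagged ``excluded``.
    """
    rows = []
    outcome_histories: list[EventHistory | None] = []
    for hist in histories:
        n_mod = min(sum(1 for t, s in hist.events if t < split and not s), PRIOR_MODERATE_CAP)
        n_sev = min(sum(1 for t, s in hist.events if t < split and s), PRIOR_SEVERE_CAP)
        out_fu = hist.followup - split
        if out_fu <= 0:
            outcome_histories.append(None)
            excluded = True
        else:
            events = [(t - split, s) for t, s in hist.events if t > split]
            outcome_histories.append(EventHistory(followup=float(out_fu), events=events))
            excluded = out_fu < min_outcome_followup
        rows.append(
            {
                "n_moderate_prior": float(n_mod),
                "n_severe_prior": float(n_sev),
                "outcome_followup": max(out_fu, 0.0),
                "excluded": excluded,
            }
        )
    return pd.DataFrame(rows), outcome_histories


def miscalibration_scenario(
    base_profile: SimulationProfile,
    overestimate_nonexacerbators: float = 2.0,
    global_factor: float = 1.0,
) -> tuple[CoefficientSet, CoefficientSet]:
    """Scoring vs generating coefficient pair with a known distortion.

    The scoring model believes the base profile's coefficients; the
    generating (truth) model divides the event rate of patients with no
    prior-year exacerbations by ``overestimate_nonexacerbators`` (via the
    derived ``no_prior`` indicator) and every patient's rate by
    ``global_factor``.  Feeding data generated under the truth to the
    scoring model reproduces the situation of a model that over-predicts in
    non-exacerbators, which recalibration is expected to repair.
    """
    if overestimate_nonexacerbators <= 0 or global_factor <= 0:
        raise ConfigurationError("distortion factors must be > 0")
    scoring = base_profile.true_coefficients
    beta = dict(scoring.beta_rate)
    beta["intercept"] = beta.get("intercept", 0.0) - math.log(global_factor)
    if overestimate_nonexacerbators != 1.0:
        beta["no_prior"] = beta.get("no_prior", 0.0) - math.log(overestimate_nonexacerbators)
    generating = CoefficientSet(
        beta_rate=beta,
        gamma_sev=dict(scoring.gamma_sev),
        sigma1=scoring.sigma1,
        sigma2=scoring.sigma2,
        rho=scoring.rho,
        variant="custom",
    )
    return scoring, generating
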