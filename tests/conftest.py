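"""Shared fixtures and simulation oracles for the test suite."""

import math

import numpy as np
import pytest

from accept2.types import CoefficientSet, CovariateVector


def simulate_pattern_probs(
    eta_rate, eta_sev, sigma1, sigma2, rho, horizon, n, seed
):
    """Monte-Carlo oracle for the marginal outcome-pattern probabilities.

    Simulates the generative process patient-by-patient at the count level:
    draw correlated random effects, a Poisson total count, and a binomial
    severe count.  Returns point estimates and their MC standard errors.
    Independent of the quadrature code path it is used to check.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    z1 = sigma1 * z[:, 0]
    z2 = sigma2 * (rho * z[:, 0] + math.sqrt(1.0 - rho**2) * z[:, 1])
    lam = np.exp(eta_rate + z1)
    p = 1.0 / (1.0 + np.exp(-(eta_sev + z2)))
    N = rng.poisson(lam * horizon)
    K = rng.binomial(N, p)
    est = {
        "p_any": np.mean(N >= 1),
        "p_any_severe": np.mean(K >= 1),
        "p_primary": np.mean((N - K >= 2) | (K >= 1)),
        "rate_all": np.mean(N) / horizon,
        "rate_severe": np.mean(K) / horizon,
    }
    se = {
        k: (math.sqrt(v * (1 - v) / n) if k.startswith("p_") else np.std(N) / math.sqrt(n))
        for k, v in est.items()
    }
    se["rate_all"] = np.std(N / horizon) / math.sqrt(n)
    se["rate_severe"] = np.std(K / horizon) / math.sqrt(n)
    return est, se


def simulate_fit_cohort(n, beta, gamma, s1, s2, rho, seed, followup=2.0):
    """Self-contained generator for fitting tests: 3 standard-normal covariates.

    Independent of the package's synthetic module; draws correlated random
    effects, Poisson totals and binomial severe counts directly.
    """
    from accept2.types import EventHistory

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 3))
    eta1 = beta[0] + X @ beta[1:]
    eta2 = gamma[0] + X @ gamma[1:]
    z = rng.standard_normal((n, 2))
    z1 = s1 * z[:, 0]
    z2 = s2 * (rho * z[:, 0] + math.sqrt(1 - rho**2) * z[:, 1])
    lam = np.exp(eta1 + z1)
    p = 1.0 / (1.0 + np.exp(-(eta2 + z2)))
    N = rng.poisson(lam * followup)
    K = rng.binomial(N, p)
    cohort = []
    for i in range(n):
        times = np.sort(rng.random(N[i])) * followup
        severe = np.zeros(N[i], dtype=int)
        severe[: K[i]] = 1
        rng.shuffle(severe)
        x = {"x1": X[i, 0], "x2": X[i, 1], "x3": X[i, 2]}
        events = [(max(float(t), 1e-9), int(s)) for t, s in zip(times, severe)]
        cohort.append((x, EventHistory(followup=followup, events=events)))
    return cohort


@pytest.fixture
def toy_covariates():
    return CovariateVector(
        n_moderate_prior=1,
        n_severe_prior=0,
        age=63.0,
        sex=1,
        smoker=0,
        fev1_pct_pred=48.0,
        bmi=26.0,
        oxygen=0,
        statin=1,
        laba=1,
        ics=1,
        sgrq=45.0,
        lama=0,
    )


@pytest.fixture
def simple_coefficients():
    """A small, fully specified coefficient set on a few predictors."""
    return CoefficientSet(
        beta_rate={"intercept": -0.2, "n_moderate_prior": 0.3, "age": 0.005},
        gamma_sev={"intercept": -1.2, "n_severe_prior": 0.5},
        sigma1=0.6,
        sigma2=0.4,
        rho=0.25,
        variant="full",
    )


@pytest.fixture(scope="session")
def eclipse_profile():
    from accept2.synthetic import eclipse_like

    return eclipse_like(n=2000, seed=42)
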