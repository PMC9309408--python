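"""Joint frailty-logistic model for exacerbation rate and severity.

The model: a patient with covariates x experiences moderate/severe
exacerbations as a homogeneous Poisson process with annual rate
``lambda = exp(eta_rate + z1)``, ``eta_rate = x' beta``; each event is severe
with probability ``p = expit(eta_sev + z2)``, ``eta_sev = x' gamma``.  The
random effects (z1, z2) are bivariate normal with SDs (sigma1, sigma2) and
correlation rho, shared across a patient's events, inducing overdispersion
and within-patient clustering of both event counts and severity.

Marginal (frailty-averaged) quantities are computed by Gauss-Hermite
quadrature; maximum-likelihood fitting integrates the random effects out of
the per-patient likelihood the same way.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, gammaln, logsumexp

from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    InsufficientDataError,
    MissingPredictorError,
)
from .types import CoefficientSet, CovariateVector, EventHistory, PredictionResult

__all__ = [
    "linear_predictor",
    "marginal_rate",
    "severity_probability",
    "solve_eta_rate_for_marginal",
    "solve_eta_sev_for_severity",
    "count_pmf",
    "outcome_probabilities",
    "pattern_probabilities",
    "cohort_linear_predictor",
    "predict_cohort",
    "fit_joint_model",
    "JointModelFit",
]

DEFAULT_QUAD_NODES = 32


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights for E[f(Z)], Z ~ N(0,1)."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * math.sqrt(2.0), w / math.sqrt(math.pi)


def linear_predictor(x, coef_map: dict[str, float]) -> float:
    """Intercept plus dot product of coefficients with predictor values.

    ``x`` may be a CovariateVector, mapping, or pandas row.  Raises
    MissingPredictorError naming the first absent/None predictor.
    """
    eta = float(coef_map.get("intercept", 0.0))
    for name, coef in coef_map.items():
        if name == "intercept":
            continue
        if isinstance(x, CovariateVector):
            value = x.get(name)
        else:
            try:
                value = x[name]
            except (KeyError, IndexError):
                raise MissingPredictorError(name) from None
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise MissingPredictorError(name, "flagged missing")
        eta += coef * float(value)
    return eta


def marginal_rate(eta_rate: float, sigma1: float, horizon: float = 1.0) -> float:
    """Expected event count over the horizon, frailty averaged.

    E[horizon * exp(eta + z1)] = horizon * exp(eta + sigma1^2 / 2)
    by the lognormal mean identity.
    """
    if sigma1 < 0:
        raise ConfigurationError("sigma1 must be >= 0")
    if not horizon > 0:
        raise ValueError("horizon must be > 0")
    return horizon * math.exp(eta_rate + 0.5 * sigma1 * sigma1)


def severity_probability(
    eta_sev: float, sigma2: float, quadrature_nodes: int = DEFAULT_QUAD_NODES
) -> float:
    """Marginal probability that an event is severe, E[expit(eta + z2)]."""
    if sigma2 < 0:
        raise ConfigurationError("sigma2 must be >= 0")
    if quadrature_nodes < 1:
        raise ValueError("need at least one quadrature node")
    if sigma2 == 0.0:
        return float(expit(eta_sev))
    z, w = _gh_nodes(quadrature_nodes)
    return float(np.dot(w, expit(eta_sev + sigma2 * z)))


def solve_eta_rate_for_marginal(rate: float, sigma1: float) -> float:
    """Linear predictor whose frailty-averaged annual rate equals ``rate``."""
    if not rate > 0:
        raise ValueError("rate must be > 0")
    return math.log(rate) - 0.5 * sigma1 * sigma1


def solve_eta_sev_for_severity(
    p: float, sigma2: float, quadrature_nodes: int = DEFAULT_QUAD_NODES
) -> float:
    """Invert severity_probability in eta for fixed sigma2."""
    if not 0.0 < p < 1.0:
        if p <= 0.0:
            return -math.inf
        return math.inf
    if sigma2 == 0.0:
        return math.log(p / (1.0 - p))
    f = lambda eta: severity_probability(eta, sigma2, quadrature_nodes) - p
    return float(optimize.brentq(f, -40.0, 40.0, xtol=1e-12))


def count_pmf(
    eta_rate: float,
    sigma1: float,
    horizon: float,
    n_max: int,
    quadrature_nodes: int = 64,
    tail_tolerance: float = 1e-6,
) -> np.ndarray:
    """Marginal pmf P(N = 0..n_max) of the event count over the horizon.

    N | z1 ~ Poisson(horizon * exp(eta_rate + z1)); the frailty is integrated
    out by quadrature.  Warns when the mass beyond n_max exceeds
    ``tail_tolerance``.
    """
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    if not horizon > 0:
        raise ValueError("horizon must be > 0")
    z, w = _gh_nodes(quadrature_nodes)
    mu = horizon * np.exp(eta_rate + sigma1 * z)  # (Q,)
    n = np.arange(n_max + 1)[:, None]  # (n_max+1, 1)
    log_pois = n * np.log(mu[None, :]) - mu[None, :] - gammaln(n + 1.0)
    pmf = np.exp(log_pois) @ w
    residual = 1.0 - pmf.sum()
    if residual > tail_tolerance:
        warnings.warn(
            f"count_pmf truncated at n_max={n_max}: residual tail mass {residual:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
    return pmf


def pattern_probabilities(
    eta_rate,
    eta_sev,
    sigma1: float,
    sigma2: float,
    rho: float,
    horizon: float = 1.0,
    quadrature_nodes: int = DEFAULT_QUAD_NODES,
) -> dict[str, np.ndarray]:
    """Vectorized marginal outcome-pattern probabilities and rates.

    With lambda(z1) = exp(eta_rate + z1), p(z2) = expit(eta_sev + z2) and
    t = horizon:

    * ``p_any``        = 1 - E[exp(-t lambda)]
    * ``p_any_severe`` = 1 - E[exp(-t lambda p)]  (severe events are a
      thinned Poisson process given the random effects)
    * ``p_primary``    = 1 - E[exp(-t lambda) + t lambda (1-p) exp(-t lambda)]
      (the complement is zero events, or exactly one and it is moderate)

    Accepts scalar or array ``eta_rate`` / ``eta_sev`` (broadcast together).
    """
    if sigma1 < 0 or sigma2 < 0:
        raise ConfigurationError("random-effect SDs must be >= 0")
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError("rho must lie in [-1, 1] (non-PSD covariance)")
    if not horizon > 0:
        raise ValueError("horizon must be > 0")

    eta_rate = np.atleast_1d(np.asarray(eta_rate, dtype=float))
    eta_sev = np.atleast_1d(np.asarray(eta_sev, dtype=float))
    eta_rate, eta_sev = np.broadcast_arrays(eta_rate, eta_sev)
    t = float(horizon)

    u, w = _gh_nodes(quadrature_nodes)
    # correlated bivariate normal via Cholesky of the standard grid
    u1 = np.repeat(u, quadrature_nodes)
    u2 = np.tile(u, quadrature_nodes)
    wq = np.repeat(w, quadrature_nodes) * np.tile(w, quadrature_nodes)
    z1 = sigma1 * u1
    z2 = sigma2 * (rho * u1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * u2)

    lam = np.exp(eta_rate[..., None] + z1)  # (..., Q^2) annual rate
    p = expit(eta_sev[..., None] + z2)
    tl = t * lam
    e_neg = np.exp(-tl)

    p_any = 1.0 - e_neg @ wq
    p_any_severe = 1.0 - np.exp(-tl * p) @ wq
    p_primary = 1.0 - (e_neg * (1.0 + tl * (1.0 - p))) @ wq
    rate_all = lam @ wq
    rate_severe = (lam * p) @ wq
    p_severity = expit(eta_sev[..., None] + z2) @ wq

    clip = lambda a: np.clip(a, 0.0, 1.0)
    return {
        "rate_all": rate_all,
        "rate_severe": np.minimum(rate_severe, rate_all),
        "p_severity": clip(p_severity),
        "p_any": clip(p_any),
        "p_any_severe": clip(np.minimum(p_any_severe, p_any)),
        "p_primary": clip(np.minimum(p_primary, p_any)),
    }


def outcome_probabilities(
    x: CovariateVector,
    coef: CoefficientSet,
    horizon: float = 1.0,
    quadrature_nodes: int = DEFAULT_QUAD_NODES,
) -> PredictionResult:
    """Full marginal prediction for one patient."""
    eta_r = linear_predictor(x, coef.beta_rate)
    eta_s = linear_predictor(x, coef.gamma_sev)
    out = pattern_probabilities(
        eta_r, eta_s, coef.sigma1, coef.sigma2, coef.rho, horizon, quadrature_nodes
    )
    return PredictionResult(
        rate_all=float(out["rate_all"][0]),
        rate_severe=float(out["rate_severe"][0]),
        p_severity=float(out["p_severity"][0]),
        p_any=float(out["p_any"][0]),
        p_any_severe=float(out["p_any_severe"][0]),
        p_primary=float(out["p_primary"][0]),
        horizon=horizon,
    )


def cohort_linear_predictor(cohort_df, coef_map: dict[str, float]) -> np.ndarray:
    """Vectorized linear predictor over a cohort DataFrame."""
    eta = np.full(len(cohort_df), float(coef_map.get("intercept", 0.0)))
    for name, c in coef_map.items():
        if name == "intercept":
            continue
        if name not in cohort_df.columns:
            raise MissingPredictorError(name)
        col = cohort_df[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise MissingPredictorError(name, "NaN values present")
        eta += c * col
    return eta


def predict_cohort(
    cohort_df,
    coef: CoefficientSet,
    horizon: float = 1.0,
    quadrature_nodes: int = DEFAULT_QUAD_NODES,
):
    """Score a cohort DataFrame; returns a DataFrame of PredictionResult fields.

    The DataFrame must contain every predictor column the coefficient set
    uses, with no missing values in those columns.
    """
    import pandas as pd

    out = pattern_probabilities(
        cohort_linear_predictor(cohort_df, coef.beta_rate),
        cohort_linear_predictor(cohort_df, coef.gamma_sev),
        coef.sigma1,
        coef.sigma2,
        coef.rho,
        horizon,
        quadrature_nodes,
    )
    res = pd.DataFrame({k: np.asarray(v) for k, v in out.items()}, index=cohort_df.index)
    res["horizon"] = horizon
    return res


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

_SIGMA_FLOOR = 1e-6


@dataclass
class JointModelFit:
    """Result of fit_joint_model: estimates, SEs, and optimizer diagnostics."""

    coefficients: CoefficientSet
    loglik: float
    se_beta: dict[str, float]
    se_gamma: dict[str, float]
    se_sigma1: float
    se_sigma2: float
    se_rho: float
    converged: bool
    n_patients: int
    optimizer_status: object = None


def _design(cohort, predictors) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    X = np.empty((len(cohort), len(predictors) + 1))
    X[:, 0] = 1.0
    n_tot = np.empty(len(cohort))
    n_sev = np.empty(len(cohort))
    t = np.empty(len(cohort))
    for i, (x, hist) in enumerate(cohort):
        for j, name in enumerate(predictors):
            X[i, j + 1] = x.get(name) if isinstance(x, CovariateVector) else float(x[name])
        n_tot[i] = hist.n_total
        n_sev[i] = hist.n_severe
        t[i] = hist.followup
    return X, n_tot, n_sev, t


def _nll_factory(X, n_tot, n_sev, t, quad_nodes):
    """Negative marginal log-likelihood over theta = [beta, gamma, log s1, log s2, atanh rho]."""
    p = X.shape[1]
    u, w = _gh_nodes(quad_nodes)
    u1 = np.repeat(u, quad_nodes)
    u2 = np.tile(u, quad_nodes)
    logw = np.log(np.repeat(w, quad_nodes) * np.tile(w, quad_nodes))
    log_t = np.log(t)
    # patient-level likelihood constants: log C(n, k) - log n!
    const = -gammaln(n_sev + 1.0) - gammaln(n_tot - n_sev + 1.0)

    def nll(theta: np.ndarray) -> float:
        beta = theta[:p]
        gamma = theta[p : 2 * p]
        s1 = math.exp(theta[2 * p])
        s2 = math.exp(theta[2 * p + 1])
        rho = math.tanh(theta[2 * p + 2])
        eta1 = X @ beta
        eta2 = X @ gamma
        z1 = s1 * u1
        z2 = s2 * (rho * u1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * u2)
        log_mu = eta1[:, None] + z1[None, :] + log_t[:, None]  # (n, Q^2)
        lin2 = eta2[:, None] + z2[None, :]
        # log Poisson kernel + log binomial kernel, constants added afterwards
        ll_q = (
            n_tot[:, None] * log_mu
            - np.exp(log_mu)
            - n_sev[:, None] * np.log1p(np.exp(-lin2))
            - (n_tot - n_sev)[:, None] * np.log1p(np.exp(lin2))
        )
        ll = logsumexp(ll_q + logw[None, :], axis=1) + const
        if not np.all(np.isfinite(ll)):
            return 1e10
        return -float(ll.sum())

    return nll


def fit_joint_model(
    cohort,
    variant: str = "full",
    predictors=None,
    init: CoefficientSet | None = None,
    quadrature_nodes: int = 9,
    n_starts: int = 3,
    seed: int = 0,
    compute_se: bool = True,
    maxiter: int = 500,
) -> JointModelFit:
    """Fit the joint frailty-logistic model by marginal maximum likelihood.

    ``cohort`` is a sequence of ``(CovariateVector | mapping, EventHistory)``
    pairs.  ``predictors`` selects the covariates entering both components
    (defaults to every predictor the variant admits that is present in the
    data).  The random effects are integrated out on a product Gauss-Hermite
    grid; the optimizer is L-BFGS-B on the unconstrained parameterization
    (log SDs, atanh correlation) with short exploratory runs from ``n_starts``
    jittered starting points followed by a full polish from the best.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise InsufficientDataError("need at least 2 patients")
    if predictors is None:
        from .types import variant_predictors

        if variant == "custom":
            raise ConfigurationError("variant 'custom' requires an explicit predictor list")
        variant_preds = variant_predictors(variant)
        first = cohort[0][0]
        present = []
        for name in variant_preds:
            try:
                if isinstance(first, CovariateVector):
                    first.get(name)
                else:
                    if first[name] is None:
                        raise KeyError
                present.append(name)
            except Exception:
                continue
        predictors = present
    predictors = list(predictors)

    X, n_tot, n_sev, t = _design(cohort, predictors)
    if not np.any(n_tot > 0):
        raise InsufficientDataError("no events in cohort")
    p = X.shape[1]
    nll = _nll_factory(X, n_tot, n_sev, t, quadrature_nodes)

    # starting values: Poisson / binomial moment fits ignoring the frailty
    if init is not None:
        beta0 = np.array([init.beta_rate.get("intercept", 0.0)] +
                         [init.beta_rate.get(f, 0.0) for f in predictors])
        gamma0 = np.array([init.gamma_sev.get("intercept", 0.0)] +
                          [init.gamma_sev.get(f, 0.0) for f in predictors])
        s10 = max(init.sigma1, 0.1)
        s20 = max(init.sigma2, 0.1)
        rho0 = np.clip(init.rho, -0.95, 0.95)
    else:
        rate = max(n_tot.sum() / t.sum(), 1e-3)
        beta0 = np.r_[math.log(rate), np.zeros(p - 1)]
        sev_frac = n_sev.sum() / max(n_tot.sum(), 1.0)
        sev_frac = min(max(sev_frac, 1e-3), 1 - 1e-3)
        gamma0 = np.r_[math.log(sev_frac / (1 - sev_frac)), np.zeros(p - 1)]
        s10, s20, rho0 = 0.5, 0.5, 0.0
    theta0 = np.r_[beta0, gamma0, math.log(s10), math.log(s20), math.atanh(rho0)]

    bounds = (
        [(-30.0, 30.0)] * (2 * p)
        + [(math.log(_SIGMA_FLOOR), math.log(10.0))] * 2
        + [(-5.0, 5.0)]
    )

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        jitter = rng.normal(0.0, 0.3, size=theta0.shape)
        starts.append(np.clip(theta0 + jitter, [b[0] for b in bounds], [b[1] for b in bounds]))

    # optimize the per-patient mean: O(1) gradients keep L-BFGS-B's first
    # projected step well inside the box (the summed objective's huge
    # gradients make it jump straight to a bound corner and stall there)
    n_pat = float(len(cohort))
    obj = lambda th: nll(th) / n_pat  # noqa: E731

    candidates = []
    for s in starts:
        r = optimize.minimize(
            obj, s, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 40, "ftol": 1e-11},
        )
        candidates.append(r)
    best = min(candidates, key=lambda r: r.fun)
    result = optimize.minimize(
        obj, best.x, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11},
    )
    if not result.success and result.fun > best.fun:
        result = best
    if not np.isfinite(result.fun):
        raise ConvergenceError("joint model likelihood diverged", status=result)

    theta = result.x
    loglik = -result.fun * n_pat
    # guarantee loglik(est) >= loglik(init)
    if nll(theta0) / n_pat < result.fun - 1e-6:
        raise ConvergenceError(
            "optimizer ended below the starting log-likelihood", status=result
        )

    beta = dict(zip(["intercept"] + predictors, theta[:p]))
    gamma = dict(zip(["intercept"] + predictors, theta[p : 2 * p]))
    s1 = math.exp(theta[2 * p])
    s2 = math.exp(theta[2 * p + 1])
    rho = math.tanh(theta[2 * p + 2])
    if s1 <= 2 * _SIGMA_FLOOR:
        s1 = 0.0
    if s2 <= 2 * _SIGMA_FLOOR:
        s2 = 0.0
    coef = CoefficientSet(
        beta_rate=beta, gamma_sev=gamma, sigma1=s1, sigma2=s2, rho=rho, variant=variant
    )

    se = np.full(theta.shape, np.nan)
    if compute_se:
        H = _numeric_hessian(nll, theta)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            se = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            pass
    # delta method to natural scale
    se_s1 = se[2 * p] * math.exp(theta[2 * p])
    se_s2 = se[2 * p + 1] * math.exp(theta[2 * p + 1])
    se_rho = se[2 * p + 2] * (1.0 - rho * rho)

    return JointModelFit(
        coefficients=coef,
        loglik=loglik,
        se_beta=dict(zip(["intercept"] + predictors, se[:p])),
        se_gamma=dict(zip(["intercept"] + predictors, se[p : 2 * p])),
        se_sigma1=float(se_s1),
        se_sigma2=float(se_s2),
        se_rho=float(se_rho),
        converged=bool(result.success),
        n_patients=len(cohort),
        optimizer_status=result,
    )


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; adequate for SE estimation at an optimum."""
    k = len(x)
    H = np.empty((k, k))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        for j in range(i, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * steps[i] * steps[j])
    return H
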