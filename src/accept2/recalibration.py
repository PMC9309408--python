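"""Natural-cubic-spline recalibration of predicted exacerbation rates.

A fitted risk model can be systematically miscalibrated in subpopulations it
was not developed on (here: patients without a recent exacerbation).  Rather
than refitting every regression coefficient, a parsimonious fix is to learn a
smooth map from predicted to observed rates and compose it with the original
model.  The map is a three-knot natural cubic spline (cubic between knots,
linear beyond the boundary knots) fitted as a count regression with a log
link and a log follow-up offset, separately for all (moderate/severe) and
severe exacerbations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .exceptions import ConfigurationError, InsufficientDataError
from .model_core import (
    pattern_probabilities,
    solve_eta_rate_for_marginal,
    solve_eta_sev_for_severity,
)
from .types import CoefficientSet, PredictionResult

__all__ = [
    "natural_spline_basis",
    "RecalibrationMap",
    "fit_recalibration_map",
    "apply_recalibration",
    "recalibrated_prediction",
]

MIN_PATIENTS = 30


def natural_spline_basis(x, knots) -> np.ndarray:
    """Natural cubic spline basis with K knots -> (n, K-1) matrix.

    Columns (excluding the intercept, which the regression supplies) follow
    the truncated-power construction: N_1(x) = x and, for k = 1..K-2,
    N_{k+1}(x) = d_k(x) - d_{K-1}(x) with
    d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k).
    The basis is C^2 everywhere and linear outside [xi_1, xi_K].
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) <= 0):
        raise ConfigurationError("knots must be strictly increasing and distinct")
    K = len(knots)
    if K < 3:
        raise ConfigurationError("need at least 3 knots")

    def d(k):
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[-1], 0.0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


@dataclass
class RecalibrationMap:
    """A fitted predicted-rate -> observed-rate transform.

    ``knots`` are on the input scale recorded in ``input_scale``
    (``"log_rate"`` by default: the spline covariate is log predicted rate).
    ``coefficients`` is ``[intercept, b_1, ..., b_{K-1}]`` on the log observed
    rate scale, so the map output ``exp(intercept + basis . b)`` is positive
    for every input and linear in log-rate beyond the boundary knots.
    """

    target: str  # "all" or "severe"
    knots: list[float]
    coefficients: list[float]
    input_scale: str = "log_rate"
    training_range: tuple[float, float] | None = None  # rate scale

    def __post_init__(self) -> None:
        if self.target not in ("all", "severe"):
            raise ConfigurationError("target must be 'all' or 'severe'")
        if len(self.knots) != 3:
            raise ConfigurationError("exactly 3 knots required")
        if np.any(np.diff(self.knots) <= 0):
            raise ConfigurationError("knots must be strictly increasing")
        if self.input_scale not in ("rate", "log_rate"):
            raise ConfigurationError("input_scale must be 'rate' or 'log_rate'")

    def to_json(self, path=None) -> str:
        payload = {
            "target": self.target,
            "knots": list(map(float, self.knots)),
            "coefficients": list(map(float, self.coefficients)),
            "input_scale": self.input_scale,
            "training_range": list(self.training_range) if self.training_range else None,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RecalibrationMap":
        if isinstance(source, dict):
            payload = source
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                payload = json.load(fh)
        tr = payload.get("training_range")
        return cls(
            target=payload["target"],
            knots=list(payload["knots"]),
            coefficients=list(payload["coefficients"]),
            input_scale=payload.get("input_scale", "log_rate"),
            training_range=tuple(tr) if tr else None,
        )


def fit_recalibration_map(
    pred_rate,
    observed_counts,
    followup,
    target: str = "all",
    knot_quantiles=(0.10, 0.50, 0.90),
    check_monotone: bool = True,
) -> RecalibrationMap:
    """Fit the 3-knot natural-spline map from predicted to observed rates.

    Fits a Poisson regression of the observed event counts on the natural
    spline basis of log predicted rate, with log follow-up as offset; knots
    sit at the ``knot_quantiles`` of the predicted rates.  The Poisson family
    is used as a quasi-likelihood for the conditional mean: only the fitted
    mean function is retained, so overdispersion does not bias the map.
    """
    pred_rate = np.asarray(pred_rate, dtype=float)
    observed_counts = np.asarray(observed_counts, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if not (len(pred_rate) == len(observed_counts) == len(followup)):
        raise ConfigurationError("input vectors must have equal length")
    if len(pred_rate) < MIN_PATIENTS:
        raise InsufficientDataError(
            f"insufficient data: need >= {MIN_PATIENTS} patients, got {len(pred_rate)}"
        )
    if np.any(pred_rate <= 0):
        raise ConfigurationError("pred_rate must be strictly positive")
    if np.any(followup <= 0):
        raise ConfigurationError("followup must be strictly positive")
    if np.ptp(pred_rate) == 0:
        raise ConfigurationError("zero variance in predicted rates; cannot place knots")

    log_pred = np.log(pred_rate)
    knots = np.quantile(log_pred, knot_quantiles)
    if np.any(np.diff(knots) <= 0):
        # heavy ties: fall back to evenly spaced knots over the range
        knots = np.linspace(log_pred.min(), log_pred.max(), 3)
        if np.any(np.diff(knots) <= 0):
            raise ConfigurationError("predicted rates too degenerate for knot placement")

    if observed_counts.sum() == 0:
        # no events at all: the fitted mean is zero everywhere; represent it
        # as a flat map at a negligible rate
        return RecalibrationMap(
            target=target,
            knots=list(knots),
            coefficients=[-30.0, 0.0, 0.0],
            input_scale="log_rate",
            training_range=(float(pred_rate.min()), float(pred_rate.max())),
        )

    basis = sm.add_constant(natural_spline_basis(log_pred, knots))
    model = sm.GLM(
        observed_counts,
        basis,
        family=sm.families.Poisson(),
        offset=np.log(followup),
    )
    res = model.fit()
    rmap = RecalibrationMap(
        target=target,
        knots=list(knots),
        coefficients=list(res.params),
        input_scale="log_rate",
        training_range=(float(pred_rate.min()), float(pred_rate.max())),
    )
    if check_monotone and not _is_monotone(rmap):
        warnings.warn(
            f"recalibration map for target={target!r} is non-monotone over the "
            "training range; ranking of patients may change",
            RuntimeWarning,
            stacklevel=2,
        )
    return rmap


def _is_monotone(rmap: RecalibrationMap, n_grid: int = 512) -> bool:
    lo, hi = rmap.training_range or (np.exp(rmap.knots[0]), np.exp(rmap.knots[-1]))
    grid = np.geomspace(max(lo, 1e-12), hi, n_grid)
    out = apply_recalibration(rmap, grid)
    return bool(np.all(np.diff(out) >= -1e-12))


def apply_recalibration(rmap: RecalibrationMap, pred_rate):
    """Map predicted rates through the fitted spline; returns rates >= 0.

    Beyond the boundary knots the natural-spline constraint makes the map
    linear in log predicted rate (hence monotone over each extrapolated
    segment, with no polynomial oscillation).
    """
    arr = np.atleast_1d(np.asarray(pred_rate, dtype=float))
    if np.any(arr <= 0):
        raise ValueError("pred_rate must be > 0")
    x = np.log(arr) if rmap.input_scale == "log_rate" else arr
    basis = natural_spline_basis(x, rmap.knots)
    coef = np.asarray(rmap.coefficients, dtype=float)
    out = np.exp(coef[0] + basis @ coef[1:])
    if np.isscalar(pred_rate) or np.ndim(pred_rate) == 0:
        return float(out[0])
    return out


def recalibrated_prediction(
    raw: PredictionResult,
    map_all: RecalibrationMap,
    map_severe: RecalibrationMap,
    coef: CoefficientSet,
    horizon: float | None = None,
    quadrature_nodes: int = 32,
) -> PredictionResult:
    """Recalibrate a raw prediction and recompute its pattern probabilities.

    The all-event and severe-event rates are mapped separately, then
    reconciled (severe capped at all); the per-event severity probability is
    their ratio, and the pattern probabilities are recomputed from the joint
    model with the linear predictors solved so the marginal rates match the
    recalibrated values (random-effect variances unchanged).
    """
    if map_all.target == map_severe.target:
        raise ConfigurationError(
            f"recalibration maps must target different outcomes; both are "
            f"{map_all.target!r}"
        )
    if map_all.target != "all":
        map_all, map_severe = map_severe, map_all
    horizon = raw.horizon if horizon is None else horizon

    rate_all = float(apply_recalibration(map_all, raw.rate_all)) if raw.rate_all > 0 else 0.0
    rate_sev = (
        float(apply_recalibration(map_severe, raw.rate_severe)) if raw.rate_severe > 0 else 0.0
    )
    rate_sev = min(rate_sev, rate_all)
    p_severity = rate_sev / rate_all if rate_all > 0 else 0.0
    p_severity = min(max(p_severity, 0.0), 1.0)

    if rate_all <= 0:
        return PredictionResult(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, horizon)

    eta_rate = solve_eta_rate_for_marginal(rate_all, coef.sigma1)
    eta_sev = solve_eta_sev_for_severity(p_severity, coef.sigma2, quadrature_nodes)
    out = pattern_probabilities(
        eta_rate, eta_sev, coef.sigma1, coef.sigma2, coef.rho, horizon, quadrature_nodes
    )
    return PredictionResult(
        rate_all=rate_all,
        rate_severe=min(float(out["rate_severe"][0]), rate_all),
        p_severity=p_severity,
        p_any=float(out["p_any"][0]),
        p_any_severe=float(out["p_any_severe"][0]),
        p_primary=float(out["p_primary"][0]),
        horizon=horizon,
    )
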