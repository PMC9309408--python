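"""Multiple imputation of missing predictors and pooling of predictions.

Two predictor types arise in practice: a binary medication indicator that is
wholly unobserved in some cohorts (imputed from a logistic regression fitted
on cohorts where it was recorded) and a continuous symptom score missing for
a subset of patients (imputed from a Gaussian linear model fitted on the
observed scores).  Uncertainty is propagated by drawing several completed
datasets and averaging the resulting predictions; because the prediction
model itself is fixed, averaging predictions (rather than pooling
coefficients) is the appropriate combination rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ConfigurationError, ConvergenceError
from .types import PredictionResult

__all__ = [
    "ImputationModel",
    "fit_binary_imputer",
    "fit_continuous_imputer",
    "multiply_impute",
    "pooled_prediction",
]


@dataclass
class ImputationModel:
    """A fitted single-variable imputation model."""

    target: str
    kind: str  # "binary_logistic" or "continuous_gaussian"
    coefficients: dict[str, float]  # includes "intercept"
    residual_sd: float | None = None  # continuous only

    def __post_init__(self) -> None:
        if self.kind not in ("binary_logistic", "continuous_gaussian"):
            raise ConfigurationError(f"unknown imputer kind {self.kind!r}")
        if self.target in self.coefficients:
            raise ConfigurationError("target may not appear among its own predictors")
        if "intercept" not in self.coefficients:
            raise ConfigurationError("coefficients must include an intercept")
        if self.kind == "continuous_gaussian" and self.residual_sd is None:
            raise ConfigurationError("continuous imputer requires residual_sd")

    @property
    def predictors(self) -> list[str]:
        return [k for k in self.coefficients if k != "intercept"]

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(df), self.coefficients["intercept"])
        for name in self.predictors:
            if name not in df.columns:
                raise ConfigurationError(f"imputer predictor {name!r} missing from cohort")
            col = df[name].to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ConfigurationError(
                    f"imputer predictor {name!r} itself has missing values"
                )
            eta += self.coefficients[name] * col
        return eta


def fit_binary_imputer(
    training: pd.DataFrame, target: str, predictors: list[str]
) -> ImputationModel:
    """Maximum-likelihood logistic regression of a binary target on predictors.

    Raises on single-class targets and on (quasi-)complete separation, naming
    the offending predictor.
    """
    if target in predictors:
        raise ConfigurationError("target may not be among its own predictors")
    y = training[target].to_numpy(dtype=float)
    if len(np.unique(y[~np.isnan(y)])) < 2:
        raise ConfigurationError(f"target {target!r} has a single observed class")
    mask = ~np.isnan(y)
    X = sm.add_constant(training.loc[mask, predictors].to_numpy(dtype=float))
    try:
        res = sm.Logit(y[mask], X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and kin
        raise ConvergenceError(f"logistic imputer failed: {exc}") from exc
    params = np.asarray(res.params)
    if (
        not res.mle_retvals.get("converged", True)
        or not np.all(np.isfinite(params))
        or np.any(np.abs(params) > 30)
    ):
        j = int(np.argmax(np.abs(params[1:])))
        raise ConvergenceError(
            f"separation detected in logistic imputer (predictor {predictors[j]!r})"
        )
    coefs = {"intercept": float(params[0])}
    coefs.update({p: float(c) for p, c in zip(predictors, params[1:])})
    return ImputationModel(target=target, kind="binary_logistic", coefficients=coefs)


def fit_continuous_imputer(
    training: pd.DataFrame, target: str, predictors: list[str]
) -> ImputationModel:
    """Gaussian linear model of a continuous target on predictors."""
    if target in predictors:
        raise ConfigurationError("target may not be among its own predictors")
    y = training[target].to_numpy(dtype=float)
    mask = ~np.isnan(y)
    if mask.sum() < len(predictors) + 2:
        raise ConfigurationError("too few observed values to fit continuous imputer")
    X = sm.add_constant(training.loc[mask, predictors].to_numpy(dtype=float))
    res = sm.OLS(y[mask], X).fit()
    params = np.asarray(res.params)
    coefs = {"intercept": float(params[0])}
    coefs.update({p: float(c) for p, c in zip(predictors, params[1:])})
    resid_sd = float(np.sqrt(res.scale))
    return ImputationModel(
        target=target, kind="continuous_gaussian", coefficients=coefs, residual_sd=resid_sd
    )


def multiply_impute(
    cohort: pd.DataFrame, model: ImputationModel, m: int = 10, seed: int = 0
) -> list[pd.DataFrame]:
    """Draw ``m`` completed copies of the cohort.

    Missing binary values are drawn Bernoulli(fitted probability); missing
    continuous values are drawn from the Gaussian predictive distribution.
    Observed entries are never altered.  Deterministic given the seed.
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    if model.target not in cohort.columns:
        raise ConfigurationError(f"target column {model.target!r} absent from cohort")
    missing = cohort[model.target].isna().to_numpy()
    completed = []
    rng = np.random.default_rng(seed)
    if not missing.any():
        return [cohort.copy() for _ in range(m)]
    eta = model.linear_predictor(cohort.loc[missing])
    for _ in range(m):
        filled = cohort.copy()
        if model.kind == "binary_logistic":
            prob = 1.0 / (1.0 + np.exp(-eta))
            draws = (rng.random(missing.sum()) < prob).astype(float)
        else:
            draws = eta + rng.normal(0.0, model.residual_sd, size=missing.sum())
        filled.loc[missing, model.target] = draws
        completed.append(filled)
    return completed


_PRED_FIELDS = ("rate_all", "rate_severe", "p_severity", "p_any", "p_any_severe", "p_primary")


def pooled_prediction(per_imputation_predictions):
    """Element-wise mean of predictions across imputations.

    Accepts a list of PredictionResult (one subject) or a list of aligned
    DataFrames (one per imputation, same index).  Invariants of the averaged
    prediction are re-validated.
    """
    preds = list(per_imputation_predictions)
    if not preds:
        raise ConfigurationError("need at least one imputation")
    if isinstance(preds[0], PredictionResult):
        horizon = preds[0].horizon
        if any(p.horizon != horizon for p in preds):
            raise ConfigurationError("mismatched horizons across imputations")
        means = {}
        for f in _PRED_FIELDS:
            vals = [getattr(p, f) for p in preds]
            # keep the exact common value when every imputation agrees, so
            # zero missingness is bit-equivalent to direct prediction
            means[f] = vals[0] if all(v == vals[0] for v in vals) else float(np.mean(vals))
        return PredictionResult(horizon=horizon, **means)
    first = preds[0]
    for p in preds[1:]:
        if not p.index.equals(first.index):
            raise ConfigurationError("mismatched subject sets across imputations")
    cols = list(first.columns)
    cube = np.stack([p[cols].to_numpy(dtype=float) for p in preds])  # (m, n, k)
    mean = cube.mean(axis=0)
    agree = (cube == cube[0]).all(axis=0)
    mean[agree] = cube[0][agree]
    out = pd.DataFrame(mean, index=first.index, columns=cols)
    out["rate_severe"] = np.minimum(out["rate_severe"], out["rate_all"])
    return out
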