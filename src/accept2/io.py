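"""Cohort file formats, run configuration, and the pipeline driver.

Cohort data travel as two UTF-8 CSVs: a per-patient table (``patient_id``,
the predictor columns, ``followup``; missing values are empty cells) and a
long-format event table (``patient_id``, ``time``, ``severe``).  Model
coefficients and recalibration maps are JSON.  Every stochastic stage draws
from a named substream of one root seed, so a run is reproducible from its
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ConfigurationError, DataValidationError
from .types import (
    BINARY_FIELDS,
    OPTIONAL_FIELDS,
    PREDICTOR_FIELDS,
    CoefficientSet,
    EventHistory,
)

logger = logging.getLogger("accept2")

COHORT_COLUMNS = ("patient_id",) + PREDICTOR_FIELDS + ("followup",)


def write_cohort(cohort: pd.DataFrame, histories, cohort_path, events_path) -> None:
    """Write a cohort and its event histories in the canonical CSV dialect."""
    df = cohort.copy()
    if "patient_id" not in df.columns:
        df.insert(0, "patient_id", df.index)
    if "followup" not in df.columns:
        df["followup"] = [h.followup for h in histories]
    cols = [c for c in COHORT_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in COHORT_COLUMNS
    ]
    df[cols].to_csv(cohort_path, index=False, float_format="%.10g")

    rows = []
    for pid, hist in zip(df["patient_id"], histories):
        if hist is None:
            continue
        for t, s in hist.events:
            rows.append({"patient_id": pid, "time": t, "severe": s})
    pd.DataFrame(rows, columns=["patient_id", "time", "severe"]).to_csv(
        events_path, index=False, float_format="%.10g"
    )


def _validate_cohort_rows(df: pd.DataFrame) -> None:
    errors = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        fu = row.get("followup", np.nan)
        if not np.isnan(fu) and fu <= 0:
            errors.append(f"line {line}: followup must be > 0 (got {fu})")
        for fname, cond, msg in (
            ("bmi", lambda v: v > 0, "must be > 0"),
            ("fev1_pct_pred", lambda v: v > 0, "must be > 0"),
            ("n_moderate_prior", lambda v: v >= 0, "must be >= 0"),
            ("n_severe_prior", lambda v: v >= 0, "must be >= 0"),
            ("sgrq", lambda v: 0 <= v <= 100, "must lie in [0, 100]"),
        ):
            if fname in df.columns:
                v = row[fname]
                if not np.isnan(v) and not cond(v):
                    errors.append(f"line {line}: {fname} {msg} (got {v})")
        for fname in BINARY_FIELDS & set(df.columns):
            v = row[fname]
            if not np.isnan(v) and v not in (0.0, 1.0):
                errors.append(f"line {line}: {fname} must be 0/1 (got {v})")
    if errors:
        raise DataValidationError("; ".join(errors))


def read_cohort(
    cohort_path,
    events_path=None,
    exclude_short_followup: bool = False,
    min_followup: float = 0.3,
):
    """Read and validate a cohort (and optionally its events).

    Returns ``(cohort_df, histories, excluded_ids)``.  ``histories`` is a
    dict ``patient_id -> EventHistory`` (empty dict if no events file).
    When ``exclude_short_followup`` is set, patients with follow-up below
    ``min_followup`` years are dropped from the returned frame and their ids
    reported (and logged) so the caller can compare their predicted-risk
    distribution with the retained patients'.
    """
    try:
        df = pd.read_csv(cohort_path)
    except ValueError as exc:
        raise DataValidationError(f"malformed cohort CSV: {exc}") from exc
    if "patient_id" not in df.columns:
        raise DataValidationError("cohort CSV must have a patient_id column")
    known = set(COHORT_COLUMNS) | {"no_prior", "outcome_followup", "excluded"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"unknown cohort columns ignored: {unknown}", UserWarning, stacklevel=2)
    for c in df.columns:
        if c == "patient_id":
            continue
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df[c][pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
            lines = [str(i + 2) for i in bad.index[:5]]
            raise DataValidationError(
                f"malformed numeric cell(s) in column {c!r} at line(s) {', '.join(lines)}"
            )
    _validate_cohort_rows(df)

    histories: dict = {}
    if events_path is not None and Path(events_path).exists():
        ev = pd.read_csv(events_path)
        fu_by_id = dict(zip(df["patient_id"], df.get("followup", np.nan)))
        grouped = {pid: g for pid, g in ev.groupby("patient_id")}
        for pid in df["patient_id"]:
            fu = fu_by_id.get(pid)
            if fu is None or np.isnan(fu):
                continue
            g = grouped.get(pid)
            events = (
                sorted(zip(g["time"].astype(float), g["severe"].astype(int)))
                if g is not None
                else []
            )
            histories[pid] = EventHistory(followup=float(fu), events=events)

    excluded_ids: list = []
    if exclude_short_followup and "followup" in df.columns:
        short = df["followup"] < min_followup
        excluded_ids = list(df.loc[short, "patient_id"])
        if excluded_ids:
            logger.info(
                "excluding %d patients with follow-up < %.2f y: %s",
                len(excluded_ids), min_followup, excluded_ids[:20],
            )
        df = df.loc[~short].reset_index(drop=True)
    return df, histories, excluded_ids


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    command: str
    cohort_path: str | None = None
    events_path: str | None = None
    coefficients_path: str | None = None
    recalibration_all_path: str | None = None
    recalibration_severe_path: str | None = None
    horizon: float = 1.0
    outcome: str = "primary"
    thresholds: list[float] = field(default_factory=lambda: list(np.arange(0.05, 0.951, 0.01)))
    bootstrap_b: int = 200
    imputations: int = 10
    seed: int = 0
    out_dir: str = "."
    profile: str = "eclipse_like"
    n: int = 2000
    exclude_short_followup: bool = True

    COMMANDS = ("simulate", "predict", "recalibrate", "validate", "dca")

    def __post_init__(self) -> None:
        if self.command not in self.COMMANDS:
            raise ConfigurationError(f"unknown command {self.command!r}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(**payload)


def _manifest(config: RunConfig, outputs: list[str]) -> dict:
    cfg = asdict(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {
        "version": __version__,
        "config": cfg,
        "config_hash": digest,
        "seed": config.seed,
        "outputs": outputs,
    }


def _write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def run_pipeline(config: RunConfig) -> dict:
    """Execute one pipeline stage; returns the manifest.

    Stages: ``simulate`` (write a synthetic cohort), ``predict`` (score a
    cohort, multiply imputing any partially missing predictors),
    ``recalibrate`` (fit the all/severe spline maps against observed
    events), ``validate`` (calibration + discrimination report), ``dca``
    (decision curves).  Every random draw descends from ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    try:
        if config.command == "simulate":
            outputs = _stage_simulate(config, out)
        elif config.command == "predict":
            outputs = _stage_predict(config, out)
        elif config.command == "recalibrate":
            outputs = _stage_recalibrate(config, out)
        elif config.command == "validate":
            outputs = _stage_validate(config, out)
        elif config.command == "dca":
            outputs = _stage_dca(config, out)
    except Exception as exc:
        raise type(exc)(f"stage {config.command!r} failed: {exc}") from exc
    manifest = _manifest(config, outputs)
    _write_json(manifest, out / "manifest.json")
    return manifest


def _stage_simulate(config: RunConfig, out: Path) -> list[str]:
    from . import synthetic

    factory = {"eclipse_like": synthetic.eclipse_like, "torch_like": synthetic.torch_like}
    if config.profile not in factory:
        raise ConfigurationError(f"unknown profile {config.profile!r}")
    profile = factory[config.profile](n=config.n, seed=config.seed)
    cov = synthetic.generate_covariates(profile)
    hist = synthetic.simulate_exacerbations(
        cov.fillna({"lama": 0.0, "sgrq": 50.0}), profile.true_coefficients, profile
    )
    prior, outcome_hist = synthetic.split_predictor_outcome_windows(hist)
    df = cov.copy()
    df["n_moderate_prior"] = prior["n_moderate_prior"].to_numpy()
    df["n_severe_prior"] = prior["n_severe_prior"].to_numpy()
    df["no_prior"] = (
        (df["n_moderate_prior"] == 0) & (df["n_severe_prior"] == 0)
    ).astype(float)
    df["followup"] = prior["outcome_followup"].to_numpy()
    keep = df["followup"] > 0
    df = df.loc[keep].reset_index(drop=True)
    kept_hist = [h for h, k in zip(outcome_hist, keep) if k]
    write_cohort(df, kept_hist, out / "cohort.csv", out / "events.csv")
    profile.true_coefficients.to_json(out / "true_coefficients.json")
    return ["cohort.csv", "events.csv", "true_coefficients.json"]


def _load_predictions(config: RunConfig, out: Path) -> pd.DataFrame:
    pred_path = out / "predictions.csv"
    if pred_path.exists():
        return pd.read_csv(pred_path, index_col="patient_id")
    _stage_predict(config, out)
    return pd.read_csv(pred_path, index_col="patient_id")


def _stage_predict(config: RunConfig, out: Path) -> list[str]:
    from . import imputation, model_core, recalibration
    from .validation import risk_distribution_summary

    coef = CoefficientSet.from_json(config.coefficients_path)
    df_all, _, _ = read_cohort(config.cohort_path, config.events_path, False)
    df, _, excluded = read_cohort(
        config.cohort_path,
        config.events_path,
        config.exclude_short_followup,
    )
    df = df.set_index("patient_id")

    needed = list(coef.predictors)
    missing_cols = [c for c in needed if df[c].isna().any()]
    if missing_cols:
        completed = _impute_cohort(df, needed, missing_cols, config)
        per_imp = [
            model_core.predict_cohort(d, coef, config.horizon) for d in completed
        ]
        preds = imputation.pooled_prediction(per_imp)
    else:
        preds = model_core.predict_cohort(df, coef, config.horizon)

    if config.recalibration_all_path and config.recalibration_severe_path:
        map_all = recalibration.RecalibrationMap.from_json(config.recalibration_all_path)
        map_sev = recalibration.RecalibrationMap.from_json(config.recalibration_severe_path)
        rate_all = recalibration.apply_recalibration(map_all, preds["rate_all"].to_numpy())
        rate_sev = np.minimum(
            recalibration.apply_recalibration(map_sev, preds["rate_severe"].to_numpy()),
            rate_all,
        )
        p_sev = np.where(rate_all > 0, rate_sev / np.maximum(rate_all, 1e-300), 0.0)
        eta_rate = np.log(np.maximum(rate_all, 1e-300)) - 0.5 * coef.sigma1**2
        eta_sev = np.array(
            [model_core.solve_eta_sev_for_severity(p, coef.sigma2) for p in p_sev]
        )
        pat = model_core.pattern_probabilities(
            eta_rate, eta_sev, coef.sigma1, coef.sigma2, coef.rho, config.horizon
        )
        for k in ("p_any", "p_any_severe", "p_primary", "p_severity"):
            preds[k] = np.asarray(pat[k])
        preds["rate_all"] = rate_all
        preds["rate_severe"] = rate_sev

    preds.round(6).to_csv(out / "predictions.csv", index_label="patient_id")
    if excluded:
        # compare predicted risk of excluded vs included patients
        full = df_all.set_index("patient_id")
        cols_ok = [c for c in needed if not full[c].isna().any()]
        reduced_coef = CoefficientSet(
            beta_rate={k: v for k, v in coef.beta_rate.items()
                       if k == "intercept" or k in cols_ok},
            gamma_sev={k: v for k, v in coef.gamma_sev.items()
                       if k == "intercept" or k in cols_ok},
            sigma1=coef.sigma1, sigma2=coef.sigma2, rho=coef.rho, variant="custom",
        )
        p_full = model_core.predict_cohort(full, reduced_coef, config.horizon)
        summary = risk_distribution_summary(
            p_full.loc[p_full.index.isin(excluded), "p_primary"],
            p_full.loc[~p_full.index.isin(excluded), "p_primary"],
        )
        summary["n_excluded"] = len(excluded)
        _write_json(summary, out / "excluded_risk_summary.json")
    return ["predictions.csv"]


def _impute_cohort(df, needed, missing_cols, config: RunConfig):
    from . import imputation

    models = []
    for col in missing_cols:
        if df[col].isna().all():
            raise ConfigurationError(
                f"predictor {col!r} is wholly missing; an external training "
                "cohort is required to impute it"
            )
        predictors = [c for c in needed if c != col and not df[c].isna().any()]
        if col in BINARY_FIELDS:
            model = imputation.fit_binary_imputer(df, col, predictors)
        else:
            model = imputation.fit_continuous_imputer(df, col, predictors)
        models.append(model)
    completed = [df.copy() for _ in range(config.imputations)]
    for j, model in enumerate(models):
        drawn = imputation.multiply_impute(
            df, model, m=config.imputations, seed=(config.seed, 100 + j)
        )
        for m, d in enumerate(drawn):
            completed[m][model.target] = d[model.target]
    return completed


def _stage_recalibrate(config: RunConfig, out: Path) -> list[str]:
    from . import recalibration

    preds = _load_predictions(config, out)
    df, hist, _ = read_cohort(
        config.cohort_path, config.events_path, config.exclude_short_followup
    )
    df = df.set_index("patient_id")
    ids = [pid for pid in preds.index if pid in hist]
    counts_all = np.array([hist[pid].n_total for pid in ids], dtype=float)
    counts_sev = np.array([hist[pid].n_severe for pid in ids], dtype=float)
    fu = np.array([hist[pid].followup for pid in ids], dtype=float)
    sub = preds.loc[ids]
    map_all = recalibration.fit_recalibration_map(
        sub["rate_all"].to_numpy(), counts_all, fu, target="all"
    )
    map_sev = recalibration.fit_recalibration_map(
        sub["rate_severe"].to_numpy(), counts_sev, fu, target="severe"
    )
    map_all.to_json(out / "recalibration_all.json")
    map_sev.to_json(out / "recalibration_severe.json")
    return ["recalibration_all.json", "recalibration_severe.json"]


def _stage_validate(config: RunConfig, out: Path) -> list[str]:
    from . import validation

    preds = _load_predictions(config, out)
    df, hist, _ = read_cohort(
        config.cohort_path, config.events_path, config.exclude_short_followup
    )
    ids = [pid for pid in preds.index if pid in hist]
    sub = preds.loc[ids]
    counts = np.array([hist[pid].n_total for pid in ids], dtype=float)
    fu = np.array([hist[pid].followup for pid in ids], dtype=float)

    table = validation.decile_calibration_table(
        sub["rate_all"].to_numpy(), counts, fu, scale="rate"
    )
    table.to_csv(out / "calibration_deciles.csv", index=False)

    tto = [validation.derive_time_to_outcome(hist[pid], config.outcome) for pid in ids]
    marker_col = {"primary": "p_primary", "any": "p_any", "any_severe": "p_any_severe"}[
        config.outcome
    ]
    marker = sub[marker_col].to_numpy()
    horizon_ok = np.array(
        [t.censor_time >= config.horizon or bool(t.observed) for t in tto], dtype=bool
    )
    y = np.array(
        [1.0 if (t.observed and t.outcome_time <= config.horizon) else 0.0 for t in tto]
    )
    metrics = {
        "calibration_in_the_large": validation.calibration_in_the_large(
            sub["rate_all"].to_numpy(), counts, fu
        ),
        "ici_rate": validation.integrated_calibration_index_rate(
            sub["rate_all"].to_numpy(), counts, fu
        ),
        "auc": validation.time_dependent_auc(
            marker, tto, t_star=config.horizon, B=config.bootstrap_b, seed=config.seed
        ),
        "n": len(ids),
        "outcome": config.outcome,
    }
    if horizon_ok.sum() >= 50:
        metrics["ici_risk"] = validation.integrated_calibration_index(
            marker[horizon_ok], y[horizon_ok]
        )
        metrics["mroc_test"] = validation.mroc_test(
            marker[horizon_ok], y[horizon_ok], B=max(config.bootstrap_b, 500),
            seed=config.seed,
        )
    _write_json(metrics, out / "metrics.json")
    return ["calibration_deciles.csv", "metrics.json"]


def _stage_dca(config: RunConfig, out: Path) -> list[str]:
    from . import decision_analysis, validation

    preds = _load_predictions(config, out)
    df, hist, _ = read_cohort(
        config.cohort_path, config.events_path, config.exclude_short_followup
    )
    df = df.set_index("patient_id")
    # restrict to subjects whose outcome status at the horizon is known
    ids = [
        pid
        for pid in preds.index
        if pid in hist
        and (
            hist[pid].followup >= config.horizon
            or validation.derive_time_to_outcome(hist[pid], config.outcome).observed
        )
    ]
    sub = preds.loc[ids]
    tto = [validation.derive_time_to_outcome(hist[pid], config.outcome) for pid in ids]
    y = np.array(
        [1.0 if (t.observed and t.outcome_time <= config.horizon) else 0.0 for t in tto]
    )
    marker_col = {"primary": "p_primary", "any": "p_any", "any_severe": "p_any_severe"}[
        config.outcome
    ]
    strategies = {"model": sub[marker_col].to_numpy()}
    if {"n_moderate_prior", "n_severe_prior"} <= set(df.columns):
        strategies["history"] = decision_analysis.history_rule(
            df.loc[ids, "n_moderate_prior"], df.loc[ids, "n_severe_prior"]
        )
    curve = decision_analysis.decision_curve(strategies, y, config.thresholds)
    curve.to_csv(out / "decision_curve.csv", index=False)
    return ["decision_curve.csv"]
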