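"""Decision-curve analysis: net benefit of risk-guided treatment.

At a risk threshold p_t the net benefit of a strategy is
``TP/n - (FP/n) * p_t/(1-p_t)``: true positives credited at face value,
false positives debited at the odds of the threshold, which encodes how the
decision maker weighs overtreatment against undertreatment.  Curves compare
a risk model against treat-all, treat-none, and a binary history rule
(the guideline's 'frequent exacerbator' criterion).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "net_benefit",
    "decision_curve",
    "interventions_avoided",
    "history_rule",
]


def _check_threshold(p_t: float) -> None:
    if not 0.0 < p_t < 1.0:
        raise ValueError(f"threshold must lie strictly in (0, 1), got {p_t}")


def net_benefit(pred_risk, outcome, threshold: float) -> float:
    """Net benefit of treating subjects with predicted risk >= threshold."""
    _check_threshold(threshold)
    pred = np.asarray(pred_risk, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(pred) != len(y):
        raise ConfigurationError("pred and outcome must have equal length")
    n = len(y)
    treated = pred >= threshold
    tp = float(np.sum(treated & (y == 1)))
    fp = float(np.sum(treated & (y == 0)))
    return tp / n - (fp / n) * threshold / (1.0 - threshold)


def history_rule(n_moderate_prior, n_severe_prior, rule: str = "frequent") -> np.ndarray:
    """Binary treat/no-treat rule from prior-year exacerbation history.

    ``frequent``: >=2 moderate or >=1 severe prior events (guideline
    escalation criterion); ``any``: >=1 prior event of either kind.
    """
    m = np.asarray(n_moderate_prior, dtype=float)
    s = np.asarray(n_severe_prior, dtype=float)
    if rule == "frequent":
        return ((m >= 2) | (s >= 1)).astype(float)
    if rule == "any":
        return ((m + s) >= 1).astype(float)
    raise ConfigurationError(f"unknown history rule {rule!r}")


def decision_curve(strategies: dict, outcome, thresholds) -> pd.DataFrame:
    """Net benefit per strategy over a threshold grid.

    ``strategies`` maps names to either a predicted-risk vector (treated set
    varies with the threshold) or a binary treat/no-treat vector (treated
    set fixed).  ``treat_all`` and ``treat_none`` comparators are added
    automatically.  Returns a tidy frame (threshold, strategy, net_benefit).
    """
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if thresholds.size == 0:
        raise ConfigurationError("threshold grid must be non-empty")
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    prevalence = y.mean()

    all_strategies = dict(strategies)
    rows = []
    for p_t in thresholds:
        _check_threshold(p_t)
        odds = p_t / (1.0 - p_t)
        for name, vec in all_strategies.items():
            vec = np.asarray(vec, dtype=float)
            if len(vec) != n:
                raise ConfigurationError(f"strategy {name!r} length mismatch")
            is_binary_rule = np.all(np.isin(vec, (0.0, 1.0)))
            # binary rules treat a fixed set; risk vectors are thresholded
            treated = vec == 1.0 if is_binary_rule else vec >= p_t
            tp = float(np.sum(treated & (y == 1)))
            fp = float(np.sum(treated & (y == 0)))
            rows.append(
                {"threshold": p_t, "strategy": name, "net_benefit": tp / n - (fp / n) * odds}
            )
        rows.append(
            {
                "threshold": p_t,
                "strategy": "treat_all",
                "net_benefit": prevalence - (1.0 - prevalence) * odds,
            }
        )
        rows.append({"threshold": p_t, "strategy": "treat_none", "net_benefit": 0.0})
    return pd.DataFrame(rows)


def interventions_avoided(
    nb_model: float, nb_comparator: float, threshold: float, per: int = 100
) -> float:
    """Unnecessary interventions avoided per ``per`` decisions.

    The net-benefit gain divided by the threshold odds converts the gain
    into a net reduction in false positives at equal true-positive benefit.
    """
    _check_threshold(threshold)
    odds = threshold / (1.0 - threshold)
    return (nb_model - nb_comparator) / odds * per
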