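"""Core domain types: patient covariates, model coefficients, event histories,
and prediction results.

The prediction model couples a frailty (random-effect) Poisson process for the
rate of all moderate/severe exacerbations with a per-event logistic model for
the probability that an event is severe.  Random effects (z1, z2) act on the
log-rate and logit-severity scales respectively and are bivariate normal with
standard deviations sigma1, sigma2 and correlation rho.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

from .exceptions import ConfigurationError, DataValidationError, MissingPredictorError

#: All predictor fields recognised by the full model, in canonical order.
PREDICTOR_FIELDS: tuple[str, ...] = (
    "n_moderate_prior",
    "n_severe_prior",
    "age",
    "sex",
    "smoker",
    "fev1_pct_pred",
    "sgrq",
    "bmi",
    "oxygen",
    "statin",
    "lama",
    "laba",
    "ics",
)

#: Fields that may legitimately be missing at prediction time.
OPTIONAL_FIELDS: frozenset[str] = frozenset({"sgrq", "lama"})

BINARY_FIELDS: frozenset[str] = frozenset(
    {"sex", "smoker", "oxygen", "statin", "lama", "laba", "ics"}
)

#: Model variants and the predictors each one drops relative to the full model.
VARIANT_EXCLUDED: dict[str, frozenset[str]] = {
    "full": frozenset(),
    "no_meds": frozenset({"lama", "laba", "ics"}),
    "no_sgrq": frozenset({"sgrq"}),
    "no_meds_no_sgrq": frozenset({"lama", "laba", "ics", "sgrq"}),
}


def variant_predictors(variant: str) -> tuple[str, ...]:
    """Predictor fields admissible under a model variant."""
    try:
        excluded = VARIANT_EXCLUDED[variant]
    except KeyError:
        raise ConfigurationError(
            f"unknown model variant {variant!r}; expected one of {sorted(VARIANT_EXCLUDED)}"
        ) from None
    return tuple(f for f in PREDICTOR_FIELDS if f not in excluded)


@dataclass
class CovariateVector:
    """One patient's predictor values at the prediction origin.

    Optional fields (``sgrq``, ``lama``) may be ``None`` to flag missingness;
    all other fields must be present and within physiological range.
    """

    n_moderate_prior: float
    n_severe_prior: float
    age: float
    sex: int
    smoker: int
    fev1_pct_pred: float
    bmi: float
    oxygen: int
    statin: int
    laba: int
    ics: int
    sgrq: float | None = None
    lama: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_moderate_prior < 0 or self.n_severe_prior < 0:
            raise DataValidationError("prior exacerbation counts must be >= 0")
        if not self.fev1_pct_pred > 0:
            raise DataValidationError("fev1_pct_pred must be > 0")
        if not self.bmi > 0:
            raise DataValidationError("bmi must be > 0")
        if self.sgrq is not None and not (0.0 <= self.sgrq <= 100.0):
            raise DataValidationError("sgrq must lie in [0, 100]")
        for f in BINARY_FIELDS:
            v = getattr(self, f)
            if v is not None and v not in (0, 1):
                raise DataValidationError(f"{f} must be binary (0/1), got {v!r}")

    def get(self, name: str) -> float:
        """Value of a predictor; raises MissingPredictorError if absent/None."""
        try:
            v = getattr(self, name)
        except AttributeError:
            raise MissingPredictorError(name) from None
        if v is None:
            raise MissingPredictorError(name, "flagged missing")
        return float(v)

    def as_dict(self) -> dict[str, float | None]:
        return asdict(self)


@dataclass
class CoefficientSet:
    """Fixed-effect coefficients and random-effect variance components.

    ``beta_rate`` and ``gamma_sev`` map predictor names to coefficients and
    must contain an ``"intercept"`` entry.  ``beta_rate`` is on the log
    annual-rate scale, ``gamma_sev`` on the logit per-event severity scale.
    """

    beta_rate: dict[str, float]
    gamma_sev: dict[str, float]
    sigma1: float = 0.0
    sigma2: float = 0.0
    rho: float = 0.0
    variant: str = "full"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        # "custom" admits arbitrary predictor names (e.g. refits on synthetic
        # covariates); named variants are restricted to the tool's predictors.
        allowed = None if self.variant == "custom" else (
            set(variant_predictors(self.variant)) | {"intercept"}
        )
        for name, coef_map in (("beta_rate", self.beta_rate), ("gamma_sev", self.gamma_sev)):
            if "intercept" not in coef_map:
                raise ConfigurationError(f"{name} must contain an 'intercept' entry")
            if allowed is not None:
                unknown = set(coef_map) - allowed
                if unknown:
                    raise ConfigurationError(
                        f"{name} has predictors not allowed under variant "
                        f"{self.variant!r}: {sorted(unknown)}"
                    )
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ConfigurationError("random-effect SDs must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigurationError("rho must lie in [-1, 1]")
        # 2x2 covariance [[s1^2, r s1 s2], [r s1 s2, s2^2]] is PSD iff |rho|<=1
        # (or a sigma is 0); the checks above cover it.

    @property
    def predictors(self) -> tuple[str, ...]:
        """Union of non-intercept predictors used by either component."""
        keys = (set(self.beta_rate) | set(self.gamma_sev)) - {"intercept"}
        return tuple(f for f in PREDICTOR_FIELDS if f in keys)

    def to_json(self, path=None) -> str:
        payload = {
            "variant": self.variant,
            "beta_rate": self.beta_rate,
            "gamma_sev": self.gamma_sev,
            "sigma1": self.sigma1,
            "sigma2": self.sigma2,
            "rho": self.rho,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CoefficientSet":
        """Load from a JSON string, dict, or file path."""
        if isinstance(source, Mapping):
            payload = dict(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                payload = json.load(fh)
        known = {"variant", "beta_rate", "gamma_sev", "sigma1", "sigma2", "rho"}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown keys in coefficient config: {sorted(unknown)}")
        return cls(
            beta_rate=dict(payload["beta_rate"]),
            gamma_sev=dict(payload["gamma_sev"]),
            sigma1=float(payload.get("sigma1", 0.0)),
            sigma2=float(payload.get("sigma2", 0.0)),
            rho=float(payload.get("rho", 0.0)),
            variant=payload.get("variant", "full"),
        )


@dataclass
class EventHistory:
    """Exacerbation records for one patient over one observation window.

    ``events`` is a sequence of ``(time, severe)`` pairs with times in years,
    strictly inside ``(0, followup]``, sorted ascending.  ``severe`` is 1 for
    a severe event (ED visit / hospitalisation) and 0 for a moderate one.
    """

    followup: float
    events: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.followup > 0:
            raise DataValidationError("followup must be > 0")
        self.events = [(float(t), int(s)) for t, s in self.events]
        prev = 0.0
        for t, s in self.events:
            if not (0.0 < t <= self.followup):
                raise DataValidationError(
                    f"event time {t} outside (0, {self.followup}]"
                )
            if t < prev:
                raise DataValidationError("event times must be sorted ascending")
            if s not in (0, 1):
                raise DataValidationError("event severity must be 0/1")
            prev = t

    @property
    def n_total(self) -> int:
        return len(self.events)

    @property
    def n_severe(self) -> int:
        return sum(s for _, s in self.events)

    @property
    def n_moderate(self) -> int:
        return self.n_total - self.n_severe


@dataclass
class PredictionResult:
    """Marginal (frailty-averaged) predictions over a horizon.

    Rates are expected events per year; ``p_severity`` is the marginal
    probability that an event is severe; ``p_any``/``p_any_severe`` are the
    probabilities of at least one (severe) event within the horizon; and
    ``p_primary`` is the probability of the guideline pattern of >=2 moderate
    or >=1 severe events.
    """

    rate_all: float
    rate_severe: float
    p_severity: float
    p_any: float
    p_any_severe: float
    p_primary: float
    horizon: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        for name in ("p_severity", "p_any", "p_any_severe", "p_primary"):
            v = getattr(self, name)
            if not (-atol <= v <= 1.0 + atol):
                raise DataValidationError(f"{name}={v} outside [0, 1]")
        if self.rate_severe > self.rate_all + atol:
            raise DataValidationError("rate_severe must not exceed rate_all")
        if self.p_any_severe > self.p_any + atol:
            raise DataValidationError("p_any_severe must not exceed p_any")
        if self.p_primary > self.p_any + atol:
            raise DataValidationError("p_primary must not exceed p_any")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)
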