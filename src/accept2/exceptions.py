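"""Exception hierarchy for the accept2 package."""


class Accept2Error(Exception):
    """Base class for all package-specific errors."""


class MissingPredictorError(Accept2Error, KeyError):
    """A coefficient references a predictor absent (or flagged missing) in the data."""

    def __init__(self, field: str, context: str = ""):
        self.field = field
        msg = f"missing predictor: {field!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class ConfigurationError(Accept2Error, ValueError):
    """Inconsistent or invalid model / run configuration."""


class InsufficientDataError(Accept2Error, ValueError):
    """Too few observations for the requested fit."""


class ConvergenceError(Accept2Error, RuntimeError):
    """Numerical optimization failed to converge; carries the optimizer status."""

    def __init__(self, message: str, status: object = None):
        super().__init__(message)
        self.status = status


class DataValidationError(Accept2Error, ValueError):
    """Row- or field-level validation failure in input data."""
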