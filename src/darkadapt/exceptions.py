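"""Exception hierarchy for darkadapt.

All domain-level failures derive from :class:`DarkAdaptError` so callers can
catch pipeline problems without masking programming errors.
"""


class DarkAdaptError(Exception):
    """Base class for all darkadapt errors."""


class InvalidInputError(DarkAdaptError, ValueError):
    """Non-finite or out-of-contract numeric input."""


class DomainError(DarkAdaptError, ValueError):
    """A quantity is requested outside its mathematical domain
    (e.g. an RIT criterion at or above the cone plateau)."""


class RangeError(DarkAdaptError, ValueError):
    """A value lies outside the instrument's physical range."""


class InsufficientDataError(DarkAdaptError, ValueError):
    """Too few observations to attempt an estimate."""


class FitFailureError(DarkAdaptError, RuntimeError):
    """Optimizer or sampler failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateDesignError(DarkAdaptError, ValueError):
    """Regression design without enough variation to identify the model."""


class CollinearityError(DarkAdaptError, ValueError):
    """Rank-deficient regression design; names the aliased columns."""

    def __init__(self, message: str, aliased: list[str] | None = None):
        super().__init__(message)
        self.aliased = aliased or []


class SchemaError(DarkAdaptError, ValueError):
    """An input table does not match the expected column schema."""


class ConfigurationError(DarkAdaptError, ValueError):
    """A pipeline configuration is inconsistent or incomplete."""


class StateError(DarkAdaptError, RuntimeError):
    """An operation was requested on an object in the wrong state
    (e.g. prediction from an unfitted model)."""
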