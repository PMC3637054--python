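"""Exception hierarchy.

Two branches matter for the CLI exit-code contract: ``ValidationError``
(bad inputs or configuration, exit code 2) and ``ComputationError``
(a well-posed computation that failed, exit code 3).
"""


class UriscreenError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(UriscreenError):
    """Invalid input, configuration, or file content."""

    exit_code = 2


class ComputationError(UriscreenError):
    """A computation could not produce a valid result."""

    exit_code = 3


class InvalidModelError(ValidationError):
    """Kinetic model parameters are non-finite or out of range."""


class InvalidGridError(ValidationError):
    """Requested time grid is unusable (e.g. step larger than duration)."""


class ConfigurationError(ValidationError):
    """Missing or inconsistent configuration (e.g. unknown wavelength)."""


class DomainError(ValidationError):
    """Argument outside its physical domain (e.g. negative activity)."""


class SchemaError(ValidationError):
    """Tabular input is missing a required field; message names it."""


class ParseError(ValidationError):
    """Malformed file; message carries the offending line number."""


class CalibrationError(ComputationError):
    """Root search for a model parameter failed; message reports the bracket."""


class SaturatedTraceError(ComputationError):
    """Substrate consumed past the limit before a rate window could open."""


class InsufficientDataError(ComputationError):
    """Too few samples or data points for the requested estimate."""


class NonSaturatingDataError(ComputationError):
    """Double-reciprocal fit has non-positive intercept (no saturation)."""


class PoorFitError(ComputationError):
    """Regression below the acceptance threshold; carries the r2."""

    def __init__(self, message, r2=None):
        super().__init__(message)
        self.r2 = r2


class NormalizationError(ComputationError):
    """Zero-spread reference group; normalized cutoffs undefined."""


class UndefinedStatisticError(ComputationError):
    """Statistic undefined for this input (e.g. CV with zero mean)."""
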