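"""Exception hierarchy shared across the package."""


class ReleaseFitError(Exception):
    """Base class for all package errors."""


class DomainError(ReleaseFitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ParameterArityError(ReleaseFitError, ValueError):
    """A parameter vector does not match the model's parameter count."""


class OrderingError(DomainError):
    """Time values are not strictly increasing."""


class ValidationError(ReleaseFitError, ValueError):
    """A data container violates one of its invariants."""


class InsufficientDataError(ReleaseFitError, ValueError):
    """Too few points remain to perform a fit."""


class UndefinedStatisticError(ReleaseFitError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class SelectionError(ReleaseFitError, RuntimeError):
    """Model selection cannot proceed (e.g. no converged fits)."""


class ConfigurationError(ReleaseFitError, ValueError):
    """A configuration value is unsupported or inconsistent."""


class UnknownGroupError(ReleaseFitError, KeyError):
    """A fragment label is absent from the active group-contribution table."""
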