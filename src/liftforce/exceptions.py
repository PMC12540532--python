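"""Exception hierarchy for liftforce.

All package errors derive from :class:`LiftForceError` so callers can catch
them wholesale; argument-validation errors are also ``ValueError`` subclasses.
"""


class LiftForceError(Exception):
    """Base class for all liftforce errors."""


class InvalidArgumentError(LiftForceError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(LiftForceError):
    """A data file does not conform to the documented schema."""


class InsufficientDataError(LiftForceError):
    """Too few observations to compute the requested statistic."""


class UndefinedStatisticError(LiftForceError):
    """The statistic is undefined for this input (e.g. zero total variance)."""


class MissingCellError(LiftForceError):
    """A participant has no retained trials in a required design cell."""
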