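"""Named exceptions raised across the package.

Every precondition violation raises a subclass of :class:`RsvpScreenError`
so callers (and the analysis drivers) can distinguish contract failures
from programming errors.
"""


class RsvpScreenError(Exception):
    """Base class for all package errors."""


class InvalidSeparationError(RsvpScreenError):
    """Separation is not one of the task's seven conditions."""


class StreamLengthError(RsvpScreenError):
    """Requested stream is too short to hold both targets plus padding."""


class EmptyOutcomesError(RsvpScreenError):
    """A performance curve was requested from zero trials."""


class UndefinedMetricError(RsvpScreenError):
    """A conditional metric needed for a summary is undefined (zero denominator)."""


class InvalidGroupError(RsvpScreenError):
    """Group label is not CI or HC."""


class EmptySampleError(RsvpScreenError):
    """A statistical comparison received an empty sample."""


class InvalidUError(RsvpScreenError):
    """A U statistic lies outside [0, n1*n2]."""


class SingleClassError(RsvpScreenError):
    """A classifier was fitted on data containing only one class."""


class ConvergenceError(RsvpScreenError):
    """An iterative fit did not reach tolerance within the iteration budget."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(message)
        self.n_iter = n_iter


class LabelError(RsvpScreenError):
    """Prediction/label sequences mismatch in length or contain foreign labels."""


class MissingInputError(RsvpScreenError):
    """A report was requested from a cohort file missing required columns."""


class ConfigError(RsvpScreenError):
    """A configuration value violates its contract."""
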