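"""Exception hierarchy for solegait.

All library errors derive from :class:`SoleGaitError` so callers can catch
one base class; subclasses distinguish user-facing failure modes (bad files,
bad parameters, signals that cannot be analysed).
"""


class SoleGaitError(Exception):
    """Base class for all solegait errors."""


class FormatError(SoleGaitError):
    """A recording file is malformed or misses a mandatory channel."""


class TimingError(SoleGaitError):
    """Timestamps are non-uniform beyond tolerance or inconsistent with the rate."""


class ParameterError(SoleGaitError):
    """An operation was called with invalid parameters."""


class ConfigError(SoleGaitError):
    """Unknown or invalid configuration keys/values."""


class SegmentationError(SoleGaitError):
    """A TUG trial could not be segmented (no load plateau, no steps...)."""


class InsufficientStepsError(SegmentationError):
    """Fewer steps were detected than the requested computation needs."""


class InsufficientBaselineError(SoleGaitError):
    """Fewer baseline trials than required to establish preferred cadence."""


class FitError(SoleGaitError):
    """Soil model fitting preconditions violated (classes/samples)."""


class ModelStateError(SoleGaitError):
    """A soil model was used before fitting/scaling was established."""


class UndefinedResultError(SoleGaitError):
    """The requested quantity is undefined for this input (zero spectrum, zero mean...)."""
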