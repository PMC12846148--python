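"""Exception hierarchy.

All errors raised by this package derive from :class:`SwbLabError` so callers
can catch package failures with a single ``except`` clause while still
distinguishing validation problems from numerical degeneracies.
"""


class SwbLabError(Exception):
    """Base class for all package errors."""


class FormatError(SwbLabError, ValueError):
    """A file does not follow the expected on-disk layout."""


class ValidationError(SwbLabError, ValueError):
    """Input data violate a documented invariant (range, ordering, ...)."""


class ConfigError(SwbLabError, ValueError):
    """Unknown configuration key or ill-typed / out-of-range value."""


class DimensionError(SwbLabError, ValueError):
    """Array shapes are inconsistent with each other."""


class ParameterError(SwbLabError, ValueError):
    """A numeric parameter is outside its admissible range."""


class DegenerateSignalError(SwbLabError, ValueError):
    """A signal carries no usable power (all-zero channel, zero variance)."""


class DegenerateDesignError(SwbLabError, ValueError):
    """A statistical design cannot be fit (constant regressor, zero variance)."""


class EmptyDatasetError(SwbLabError, ValueError):
    """No usable instances remain after filtering."""


class FeatureMismatchError(SwbLabError, KeyError):
    """A requested feature (band/channel) is absent from the data."""
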