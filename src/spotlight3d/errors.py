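"""Exception hierarchy for spotlight3d.

All errors derive from :class:`SpotlightError`; validation problems are also
``ValueError`` subclasses so callers can catch them generically.
"""

__all__ = [
    "SpotlightError",
    "ValidationError",
    "DegenerateHistogramError",
    "EmptyForegroundError",
    "InvalidParameterError",
    "UndefinedDistanceError",
]


class SpotlightError(Exception):
    """Base class for all spotlight3d errors."""


class ValidationError(SpotlightError, ValueError):
    """Input does not satisfy an operation's preconditions (shape, finiteness)."""


class DegenerateHistogramError(SpotlightError, ValueError):
    """Histogram thresholding is undefined (e.g. constant volume)."""


class EmptyForegroundError(SpotlightError, ValueError):
    """A foreground-restricted quantity was requested on an all-zero mask."""


class InvalidParameterError(SpotlightError, ValueError):
    """A tunable parameter is outside its admissible range."""


class UndefinedDistanceError(SpotlightError, ValueError):
    """Profile distance is undefined (zero-norm feature vector)."""
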