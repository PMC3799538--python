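"""Exception hierarchy.

``InfopulseError`` is the base; ``ConfigError`` and ``DataError`` split the
failure modes the pipeline distinguishes in its exit codes.
"""


class InfopulseError(Exception):
    """Base class for all infopulse errors."""


class ConfigError(InfopulseError):
    """Invalid configuration or parameterization."""


class DataError(InfopulseError):
    """Invalid, inconsistent, or insufficient data."""


class PanelValidationError(DataError):
    """A panel violates a structural invariant (ordering, spacing, range)."""


class PanelFormatError(DataError):
    """A panel CSV could not be parsed."""


class AlignmentError(DataError):
    """Two panels that must share a date grid do not."""


class UndefinedRateError(DataError):
    """News rate undefined: zero total stories with nonzero cessation stories."""


class DegenerateSeriesError(DataError):
    """A series with no positive value cannot be max-normalized."""


class WindowError(DataError):
    """Event/reference windows cannot be located within the panel span."""


class UndefinedEffectError(DataError):
    """Pulse effect undefined (zero reference mean or empty window)."""


class RankDeficiencyError(DataError):
    """Regression design matrix is rank deficient (constant regressor)."""
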