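"""Exception hierarchy for the near-fall detection framework.

Exit-code mapping used by the CLI: parse errors (2), configuration
errors (3), computation/calibration errors (4).
"""


class NearFallError(Exception):
    """Base class for all framework errors."""


class InvalidInputError(NearFallError, ValueError):
    """Malformed or inconsistent input data."""


class ParseError(InvalidInputError):
    """A file could not be parsed into the expected structure."""


class ConfigurationError(NearFallError):
    """Missing or inconsistent configuration (e.g. absent thresholds)."""


class ConditioningError(NearFallError):
    """Cluster geometry matrix too ill-conditioned to solve reliably."""


class DegenerateSignalError(NearFallError):
    """Signal carries no usable content (e.g. identically zero)."""


class InsufficientDataError(NearFallError, ValueError):
    """Too few samples or values for the requested operation."""


class InsufficientBinsError(InsufficientDataError):
    """Histogram limit does not accommodate the five monitored bins."""


class MissingExtremaError(NearFallError):
    """An extrema set required for a summary statistic is empty."""


class CalibrationError(NearFallError):
    """Personalised-threshold calibration failed to converge."""


class UndefinedMetricError(NearFallError):
    """A classification metric has a zero denominator."""


class UnclassifiableTypeError(NearFallError):
    """A recovery window contains no extremum to type the perturbation."""
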