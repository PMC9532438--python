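"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to
exit code 3.
"""


class PloidyscopeError(Exception):
    """Base class for all package errors."""


class ConfigError(PloidyscopeError):
    """Invalid configuration (bad probabilities, missing stanzas, ...)."""


class DataError(PloidyscopeError):
    """Input data violates a precondition of an operation."""


class TooFewEventsError(DataError):
    """A calibration or summary population is smaller than required."""


class CalibrationError(DataError):
    """A calibration produced an unusable value (e.g. non-positive mean)."""


class FitError(DataError):
    """A curve fit failed (e.g. non-decaying fluorescence segment)."""
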