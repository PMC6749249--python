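"""Exception hierarchy for mosdetect.

Every error raised by the library derives from :class:`MosDetectError`,
so callers (and the CLI) can distinguish library failures from bugs.
"""


class MosDetectError(Exception):
    """Base class for all mosdetect errors."""


class ParameterError(MosDetectError, ValueError):
    """An argument violates its documented constraints."""


class ConfigurationError(MosDetectError):
    """Invalid run configuration (weights, critical values, thresholds)."""


class FormatError(MosDetectError):
    """A file does not conform to the expected dialect."""


class SignalError(MosDetectError):
    """A signal operation cannot be applied (too short, wrong rate, ...)."""


class DataQualityError(MosDetectError):
    """The data violate a quality premise (e.g. a long run of missing values)."""


class SchedulingError(MosDetectError):
    """A stimulus schedule cannot satisfy its spacing constraints."""


class AlignmentError(MosDetectError):
    """Traces that must share a time base do not."""


class SpatialError(MosDetectError):
    """A spatial operation lacks usable geolocated data."""


class DegenerateFieldError(SpatialError):
    """The cell attribute is constant, so no spatial statistic is defined."""
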