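"""Exception hierarchy shared by all cxrline modules."""


class CxrlineError(Exception):
    """Base class for all cxrline-specific errors."""


class EmptyMaskError(CxrlineError):
    """An operation that requires foreground pixels received an empty mask."""


class GeometryError(CxrlineError):
    """Box/shape arithmetic produced or received an invalid geometry."""


class FormatError(CxrlineError):
    """A file could not be interpreted as a 2-D mask or image."""


class ConfigurationError(CxrlineError):
    """Required configuration (e.g. pixel spacing for PNG input) is missing."""


class ParameterError(CxrlineError):
    """A numeric parameter is out of its documented range."""


class DirectionUndefinedError(CxrlineError):
    """A tangent direction cannot be estimated (single-pixel skeleton)."""


class AggregationError(CxrlineError):
    """A summary was requested over an empty or too-small group."""
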