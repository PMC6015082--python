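"""Exception hierarchy.

All package-specific failures derive from :class:`EndopolarError` so
callers (and the command-line layer) can distinguish validation problems
from genuine bugs.
"""


class EndopolarError(ValueError):
    """Base class for all endopolar errors."""


class ParameterError(EndopolarError):
    """A scene or analysis parameter is out of range or non-finite."""


class CalibrationError(EndopolarError):
    """Physical calibration (pixel size, frame interval) is missing."""


class FormatError(EndopolarError):
    """An input file could not be interpreted."""


class ValidationError(EndopolarError):
    """An input object violates a documented precondition."""


class EmptySampleError(EndopolarError):
    """An operation that needs at least one observation received none."""


class SampleSizeError(EndopolarError):
    """Too few observations for the requested statistic."""


class NormalizationError(EndopolarError):
    """A normalization reference (e.g. control mean) is degenerate."""


class GeometryError(EndopolarError):
    """A geometric input (polyline, point) lies outside the image."""
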