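"""Exception hierarchy.

Everything raised on bad input derives from :class:`PerikitError` so callers
(and the CLI) can distinguish data problems (exit 1) from usage problems.
"""


class PerikitError(Exception):
    """Base class for all perikit errors."""


class ParseError(PerikitError):
    """File does not parse as the documented JSON dialect."""


class SchemaError(PerikitError):
    """Record violates the keypoint/annotation schema."""


class ReferentialError(PerikitError):
    """A record references an image or annotation id that does not exist."""


class ValidationError(PerikitError):
    """A value violates a documented invariant (range, sign, shape)."""


class ConfigurationError(PerikitError):
    """Unknown option name (similarity, ranking source, ...)."""


class CalibrationError(PerikitError):
    """Sigma calibration has no usable pairs."""


class UndefinedOKSError(PerikitError):
    """OKS requested for an implant with no labeled keypoints (0/0)."""


class UndefinedRecallError(PerikitError):
    """Recall requested with zero ground-truth instances."""


class EmptyReportError(PerikitError):
    """No predictions survive the detection-confidence threshold."""


class StatisticsError(PerikitError):
    """Too few observations for the requested test."""


class MeasurementError(PerikitError):
    """Bone-loss measurement requested on unlabeled keypoints."""


class DegenerateImplantError(MeasurementError):
    """Apex and top midpoints coincide: implant has zero length."""


class GeometryError(PerikitError):
    """Raster region out of bounds or degenerate geometry."""


class GenerationError(PerikitError):
    """Synthetic geometry cannot be placed (implant larger than image)."""
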