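"""Exception hierarchy for hippodvh."""


class HippoDVHError(Exception):
    """Base class for all package errors."""


class InvalidContourError(HippoDVHError):
    """A polygon has fewer than 3 vertices or is otherwise degenerate."""


class OutOfExtentError(HippoDVHError):
    """A contour plane lies outside the target grid."""


class EmptyStructureError(HippoDVHError):
    """An operation requiring occupied voxels received an empty mask."""


class TooFewLayersError(HippoDVHError):
    """The structure spans fewer coronal layers than sub-regions requested."""


class OrientationError(HippoDVHError):
    """Grid axis labels do not identify the requested anatomical direction."""


class ParameterError(HippoDVHError):
    """A numeric argument is outside its valid range."""


class DegenerateVarianceError(HippoDVHError):
    """A variance-based test received data with zero spread but unequal means."""


class FormatError(HippoDVHError):
    """An input file is not a valid instance of its expected format."""
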