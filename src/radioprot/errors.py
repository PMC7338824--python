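"""Exception types raised across the pipeline."""


class RadioprotError(Exception):
    """Base class for all package-specific errors."""


class ShapeMismatchError(RadioprotError, ValueError):
    """Intensity and mask grids (or paired inputs) have incompatible shapes."""


class MaskFormatError(RadioprotError, ValueError):
    """A segmentation mask contains non-integer or otherwise invalid labels."""


class EmptyMaskError(RadioprotError, ValueError):
    """A segmentation mask has no foreground voxels."""


class ParameterError(RadioprotError, ValueError):
    """A configuration or function parameter is outside its valid domain."""


class MergeError(RadioprotError, ValueError):
    """Two tables share no keys (genes or patients) along the merge axis."""


class SchemaError(RadioprotError, KeyError):
    """A trait name is not declared in the trait schema."""


class UnresolvedConflictError(RadioprotError, ValueError):
    """Categorical readers disagree and no arbitration value is available."""


class DegenerateDataError(RadioprotError, ValueError):
    """Input data are constant or otherwise degenerate for the requested fit."""
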