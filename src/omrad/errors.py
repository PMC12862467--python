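"""Exception hierarchy shared across the package."""


class OmradError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OmradError):
    """A file could not be read as a supported image format."""


class DimensionalityError(OmradError):
    """An image is not a 3D scalar volume."""


class ParameterError(OmradError, ValueError):
    """An operation parameter is out of its valid range."""


class PairingError(OmradError):
    """Two grids that must share geometry do not."""


class InputError(OmradError):
    """Input data violates an operation precondition (e.g. empty mask)."""


class DegenerateShapeError(OmradError):
    """A mask is too flat (coplanar/collinear voxels) for shape analysis."""


class RegistryError(OmradError, KeyError):
    """An unknown feature name was requested."""


class FoldingError(OmradError):
    """Cross-validation folds cannot be stratified with the given labels."""


class SearchError(OmradError):
    """The region/method grid search had no evaluable configuration."""
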