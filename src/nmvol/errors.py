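"""Exception hierarchy for the nmvol pipeline."""


class NmvolError(Exception):
    """Base class for all nmvol errors."""


class GridMismatchError(NmvolError):
    """Two volumes expected on the same grid have different shapes or affines."""


class DegenerateReferenceError(NmvolError):
    """Reference region statistics are unusable (too few voxels or zero spread)."""


class DegenerateImageError(NmvolError):
    """An image carries no usable signal for the requested operation."""


class DegenerateDataError(NmvolError):
    """A statistical sample is degenerate (constant, or zero residual variance)."""


class EmptyRegionError(NmvolError):
    """A region of interest is empty where a nonempty one is required."""


class TransformError(NmvolError):
    """A spatial transform is invalid or a chain does not connect two spaces."""


class SpecificationError(NmvolError):
    """A phantom or pipeline specification is internally inconsistent."""
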