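"""Exception types shared across the pipeline."""


class HyphacolocError(Exception):
    """Base class for all package-specific errors."""


class SceneGenerationError(HyphacolocError):
    """Raised when a synthetic scene cannot be realized (e.g. the volume is
    too crowded to place all requested vesicles without overlap)."""


class DegenerateInputError(HyphacolocError, ValueError):
    """Raised when a volume has too few distinct intensities to threshold."""


class ShapeMismatchError(HyphacolocError, ValueError):
    """Raised when two volumes or masks that must align do not."""


class EmptyRegionError(HyphacolocError, ValueError):
    """Raised when a correlation region contains no voxels.

    Distinct from the zero-variance case, which yields NaN with a QC flag.
    """
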