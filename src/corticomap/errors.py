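"""Named exceptions raised across the package.

Every precondition violation maps to a distinct class so callers (and the
CLI) can tell a configuration mistake from a data problem.
"""


class CorticomapError(Exception):
    """Base class for all package errors."""


class MissingFileError(CorticomapError):
    """A referenced input file does not exist."""


class NotNiftiError(CorticomapError):
    """The file exists but is not a readable NIfTI image."""


class DimensionalityError(CorticomapError):
    """An image has a dimensionality other than the one required (3 or 4)."""


class SurfaceFormatError(CorticomapError):
    """A surface file lacks the required coordinate or triangle arrays."""


class VertexCountMismatchError(CorticomapError):
    """White and pial coordinate arrays disagree in vertex count."""


class FaceIndexError(CorticomapError):
    """A face references a vertex index outside the vertex array."""


class GridMismatchError(CorticomapError):
    """Two volumes do not share shape, voxel size and affine.

    Registration is an upstream responsibility; comparisons between images
    on different grids are refused rather than silently resampled.
    """


class ParentMismatchError(CorticomapError):
    """Set algebra was attempted between masks with different parents."""


class MaskBoundsError(CorticomapError):
    """Mask indices fall outside the parent surface or volume."""


class EmptyMaskError(CorticomapError):
    """An operation that needs a non-empty mask received an empty one."""


class SamplingBoundsError(CorticomapError):
    """Surface sampling requested coordinates outside the volume grid."""


class AllInvalidError(CorticomapError):
    """Every vertex or voxel entering a statistic was flagged invalid."""


class SeedNotInMaskError(CorticomapError):
    """The seed vertex for a contiguous-region query is not in the mask."""


class NoClusterError(CorticomapError):
    """No cluster survived thresholding where at least one is required."""


class FrequencyBinError(CorticomapError):
    """The stimulus period does not land on a DFT bin of the run.

    Choose a run length that is an integer number of stimulus cycles
    (n_frames * frame_interval must be a multiple of the period).
    """


class ProfileError(CorticomapError):
    """An intensity profile is too short or exits the image."""


class DegenerateInputError(CorticomapError):
    """Input is degenerate for the requested statistic (e.g. zero variance)."""


class ConfigError(CorticomapError):
    """Invalid run configuration."""
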