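"""Exception hierarchy.

Each error category maps to a distinct nonzero exit status in the CLI so that
callers (and shell pipelines) can distinguish bad parameters from bad data.
"""


class FodfbiasError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(FodfbiasError):
    """Invalid parameter value (out of range, wrong shape, ...)."""

    exit_code = 2


class CardinalityError(FodfbiasError):
    """Too few subjects / streamlines / voxels for the requested operation."""

    exit_code = 3


class GridMismatchError(FodfbiasError):
    """Volumes that must share a grid and affine do not."""

    exit_code = 4


class MaskError(FodfbiasError):
    """Empty, overlapping, or otherwise unusable mask input."""

    exit_code = 5


class DegenerateVoxelError(FodfbiasError):
    """An fODF voxel with no positive density where one is required."""

    exit_code = 6


class DivisionGuardError(FodfbiasError):
    """Reweighting would divide by an exactly-zero standard deviation."""

    exit_code = 7
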