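"""Exception hierarchy shared across the package."""


class SegtbmError(Exception):
    """Base class for all package errors."""


class GeometryError(SegtbmError):
    """Volumes do not share a grid/affine with the mask."""


class DataError(SegtbmError):
    """Non-finite or otherwise invalid voxel data."""


class DegenerateVoxelError(SegtbmError):
    """A voxel column has zero variance across subjects."""


class SplitFailureError(SegtbmError):
    """A binary split could not produce two nonempty clusters."""


class CollinearityError(SegtbmError):
    """A design matrix is rank deficient."""

    def __init__(self, message, aliased=()):
        super().__init__(message)
        self.aliased = tuple(aliased)


class NotComputableError(SegtbmError):
    """A statistic is undefined for the given input."""
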