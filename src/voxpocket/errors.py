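"""Exception hierarchy shared across the pipeline stages."""


class VoxpocketError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(VoxpocketError):
    """The input file could not be read as a PDB structure (e.g. no ATOM records)."""


class ChainNotFoundError(VoxpocketError):
    """A requested chain id does not occur in the structure's ATOM records."""


class EmptyStructureError(VoxpocketError):
    """An operation that requires at least one atom received none."""


class GridPaddingError(VoxpocketError):
    """A virtual sphere around a surface voxel would leave the grid bounding box."""


class NotSurfaceVoxelError(VoxpocketError):
    """A voxel expected to be on the surface is not."""


class NotEmptyVoxelError(VoxpocketError):
    """A voxel expected to be empty (exterior) is occupied."""


class NoRankableRegionError(VoxpocketError):
    """No cluster has positive depth and volume; no concave cavity was found."""
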