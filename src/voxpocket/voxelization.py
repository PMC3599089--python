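"""Discretisation of an atom set into a labelled occupancy grid.

Conventions (pinned so that tests are exact):

* voxel index ``(i, j, k)`` has its center at ``origin + spacing * (i, j, k)``;
* a voxel is *occupied* iff its center lies within the van der Waals sphere of
  at least one atom (``|center - atom| <= r``, inclusive);
* an occupied voxel is SURFACE iff at least one of its 6 face neighbours is
  empty, where out-of-bounds counts as empty; otherwise it is INTERIOR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyStructureError
from .structure_io import Structure

EXTERIOR = 0
INTERIOR = 1
SURFACE = 2

#: Default edge length of a voxel (Angstrom).
DEFAULT_SPACING = 1.0
#: Default padding beyond the atom spheres; must cover the largest virtual
#: sphere used downstream (10 A cavity-volume probe).
DEFAULT_PADDING = 10.0


@dataclass
class VoxelGrid:
    """A labelled voxel lattice.

    ``labels`` is a ``(nx, ny, nz)`` uint8 array over
    {EXTERIOR, INTERIOR, SURFACE}.
    """

    origin: np.ndarray  # (3,) center of voxel (0, 0, 0), Angstrom
    spacing: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a non-empty 3-D array")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask of occupied (INTERIOR or SURFACE) voxels."""
        return self.labels != EXTERIOR

    def surface_indices(self) -> np.ndarray:
        """(N, 3) int array of SURFACE voxel indices in lexicographic order."""
        return np.argwhere(self.labels == SURFACE)

    def centers(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian centers (Angstrom) of the given (N, 3) voxel indices."""
        return self.origin + self.spacing * np.asarray(indices, dtype=float)

    def in_bounds(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices))
        dims = np.array(self.dims)
        return np.all((idx >= 0) & (idx < dims), axis=-1)


def _classify(occ: np.ndarray) -> np.ndarray:
    """Label an occupancy mask: occupied voxels with an empty face neighbour
    (out-of-bounds counts as empty) are SURFACE, the rest INTERIOR."""
    padded = np.pad(occ, 1, mode="constant", constant_values=False)
    empty = ~padded
    near_empty = np.zeros_like(occ)
    core = (slice(1, -1),) * 3
    for axis in range(3):
        for shift in (-1, 1):
            near_empty |= np.roll(empty, shift, axis=axis)[core]
    labels = np.zeros(occ.shape, dtype=np.uint8)
    labels[occ & near_empty] = SURFACE
    labels[occ & ~near_empty] = INTERIOR
    return labels


def grid_from_occupancy(occ: np.ndarray, origin=(0.0, 0.0, 0.0), spacing: float = 1.0) -> VoxelGrid:
    """Build a classified grid directly from a boolean occupancy mask."""
    return VoxelGrid(origin=np.asarray(origin, dtype=float), spacing=spacing, labels=_classify(occ))


def build_grid(
    structure: Structure,
    spacing: float = DEFAULT_SPACING,
    padding: float = DEFAULT_PADDING,
) -> VoxelGrid:
    """Voxelise a structure into a classified occupancy grid.

    The grid bounding box covers every atom sphere plus ``padding`` on all
    sides, which guarantees downstream virtual spheres (solid angle, cavity
    volume) never leave the grid when centred on genuine surface voxels.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if len(structure.atoms) == 0:
        raise EmptyStructureError("cannot voxelise an empty structure")

    pos = structure.positions
    radii = structure.radii
    # snap the origin to the spacing lattice so that translating the input by
    # a multiple of the spacing translates the occupied set exactly
    lo = np.floor(((pos - radii[:, None]).min(axis=0) - padding) / spacing) * spacing
    hi = (pos + radii[:, None]).max(axis=0) + padding
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1

    occ = np.zeros(tuple(dims), dtype=bool)
    for p, r in zip(pos, radii):
        i0 = np.maximum(np.ceil((p - r - lo) / spacing).astype(int), 0)
        i1 = np.minimum(np.floor((p + r - lo) / spacing).astype(int), dims - 1)
        if np.any(i0 > i1):
            continue
        axes = [np.arange(i0[d], i1[d] + 1) for d in range(3)]
        coords = [lo[d] + spacing * axes[d] - p[d] for d in range(3)]
        d2 = (
            coords[0][:, None, None] ** 2
            + coords[1][None, :, None] ** 2
            + coords[2][None, None, :] ** 2
        )
        occ[i0[0] : i1[0] + 1, i0[1] : i1[1] + 1, i0[2] : i1[2] + 1] |= d2 <= r * r

    return VoxelGrid(origin=lo, spacing=spacing, labels=_classify(occ))


def classify_surface(grid: VoxelGrid) -> set[tuple[int, int, int]]:
    """Return the SURFACE voxel indices as a set of tuples."""
    return {tuple(int(v) for v in row) for row in grid.surface_indices()}
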