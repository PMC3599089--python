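"""Per-surface-voxel solid angles from virtual-sphere voxel counting.

The solid angle at a surface voxel is ``4 * pi * V_in / V_sphere`` where
``V_sphere`` is the number of lattice voxels whose center lies within the
virtual-sphere radius of the voxel's center (inclusive) and ``V_in`` is the
number of those that are occupied.  Values near ``2*pi`` indicate locally
flat surface, smaller values convex regions, larger values concave pockets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import GridPaddingError, NotSurfaceVoxelError
from .structure_io import Structure, write_pdb
from .voxelization import SURFACE, VoxelGrid

FOUR_PI = 4.0 * math.pi

#: Recommended virtual-sphere radius (Angstrom).
DEFAULT_SA_RADIUS = 6.0


def sphere_offsets(radius: float, spacing: float) -> np.ndarray:
    """Integer index offsets whose centers lie within ``radius`` (inclusive).

    The zero offset (the probed voxel itself) is included.
    """
    if radius <= spacing:
        raise ValueError("sphere radius must exceed the grid spacing")
    m = int(math.floor(radius / spacing))
    rng = np.arange(-m, m + 1)
    di, dj, dk = np.meshgrid(rng, rng, rng, indexing="ij")
    offs = np.stack([di.ravel(), dj.ravel(), dk.ravel()], axis=1)
    d2 = (offs.astype(float) ** 2).sum(axis=1) * spacing * spacing
    return offs[d2 <= radius * radius]


@dataclass
class SolidAngleMap:
    """Solid angle (steradians) for every surface voxel of one grid."""

    indices: np.ndarray  # (N, 3) surface voxel indices
    values: np.ndarray  # (N,) steradians in [0, 4*pi]
    sphere_radius: float
    _lookup: dict[tuple[int, int, int], float] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.values):
            raise ValueError("indices and values must have equal length")
        if len(self.values) and (self.values.min() < 0 or self.values.max() > FOUR_PI + 1e-12):
            raise ValueError("solid angles must lie in [0, 4*pi]")
        self._lookup = {
            tuple(int(x) for x in idx): float(v) for idx, v in zip(self.indices, self.values)
        }

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, voxel) -> bool:
        return tuple(voxel) in self._lookup

    def __getitem__(self, voxel) -> float:
        return self._lookup[tuple(voxel)]

    def items(self):
        return self._lookup.items()

    def as_dict(self) -> dict[tuple[int, int, int], float]:
        return dict(self._lookup)


def _check_margin(grid: VoxelGrid, indices: np.ndarray, reach: int) -> None:
    dims = np.array(grid.dims)
    if len(indices) == 0:
        return
    if (indices.min(axis=0) < reach).any() or (indices.max(axis=0) > dims - 1 - reach).any():
        raise GridPaddingError(
            "virtual sphere would leave the grid; rebuild the grid with "
            f"padding >= {reach * grid.spacing:g} A"
        )


def solid_angle_at(
    grid: VoxelGrid,
    voxel,
    radius: float = DEFAULT_SA_RADIUS,
    require_surface: bool = True,
) -> float:
    """Solid angle (steradians) at one voxel via direct voxel counting.

    ``require_surface=False`` allows probing the occupied fraction at an
    arbitrary voxel center, which is what complementarity checks between a
    solid and its complement need (the coincident point is a surface voxel of
    only one of the two grids).
    """
    voxel = tuple(int(v) for v in voxel)
    if require_surface and grid.labels[voxel] != SURFACE:
        raise NotSurfaceVoxelError(f"voxel {voxel} is not a surface voxel")
    offs = sphere_offsets(radius, grid.spacing)
    reach = int(math.floor(radius / grid.spacing))
    _check_margin(grid, np.array([voxel]), reach)
    pts = np.asarray(voxel) + offs
    v_sphere = len(offs)
    v_in = int(grid.occupied[pts[:, 0], pts[:, 1], pts[:, 2]].sum())
    return (v_in / v_sphere) * FOUR_PI


def solid_angle_all(grid: VoxelGrid, radius: float = DEFAULT_SA_RADIUS) -> SolidAngleMap:
    """Solid angles for every surface voxel.

    The computation is a pure map: it is vectorised over sphere offsets but
    produces bit-identical results to calling :func:`solid_angle_at` on each
    surface voxel individually.
    """
    surf = grid.surface_indices()
    offs = sphere_offsets(radius, grid.spacing)
    reach = int(math.floor(radius / grid.spacing))
    _check_margin(grid, surf, reach)

    occ = grid.occupied
    v_in = np.zeros(len(surf), dtype=np.int64)
    for off in offs:
        idx = surf + off
        v_in += occ[idx[:, 0], idx[:, 1], idx[:, 2]]
    values = (v_in / len(offs)) * FOUR_PI
    return SolidAngleMap(indices=surf, values=values, sphere_radius=radius)


def export_bfactor_pdb(
    structure: Structure,
    grid: VoxelGrid,
    sa_map: SolidAngleMap,
    path: str | Path,
) -> None:
    """Write a PDB copy with per-atom B-factors set to the mean solid angle
    of the surface voxels nearest to each atom (visualisation aid).

    Each surface voxel is assigned to its nearest atom; atoms owning no
    surface voxel get B-factor 0.
    """
    tree = cKDTree(structure.positions)
    centers = grid.centers(sa_map.indices)
    _, nearest = tree.query(centers)
    sums = np.zeros(len(structure.atoms))
    counts = np.zeros(len(structure.atoms))
    np.add.at(sums, nearest, sa_map.values)
    np.add.at(counts, nearest, 1.0)
    b = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)
    write_pdb(structure, path, b_factors=b)
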