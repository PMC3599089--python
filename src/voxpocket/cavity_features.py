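"""Depth and volume indicators for clustered pocket regions.

Depth maps each member's solid angle to an integer bin::

     5  if sa > 0.9 * 4*pi
     4  if 0.8 * 4*pi < sa <= 0.9 * 4*pi
     3  if 0.7 * 4*pi < sa <= 0.8 * 4*pi
     2  if 0.6 * 4*pi < sa <= 0.7 * 4*pi
     1  if 0.5 * 4*pi < sa <= 0.6 * 4*pi
    -1  otherwise

and a cluster's depth indicator is the plain mean over its members
(negative bins included).

Volume counts the empty voxels near the anchor that behave like cavity
interior: an empty voxel belongs to the cavity when at least
``interior_direction_min`` of 7 bi-directional lines through it (3 axes plus
4 body diagonals) hit occupied voxels in *both* directions before leaving
the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NotEmptyVoxelError, NotSurfaceVoxelError
from .pocket_clustering import PocketCluster, Voxel
from .solid_angle import FOUR_PI, SolidAngleMap, sphere_offsets
from .voxelization import EXTERIOR, SURFACE, VoxelGrid

#: Radius of the cavity-volume probe sphere around the anchor (Angstrom).
DEFAULT_VOLUME_RADIUS = 10.0
#: Minimum number of interior bi-directional lines for a cavity voxel.
DEFAULT_INTERIOR_DIRECTION_MIN = 4

#: The 7 bi-directional lines: 3 axes + 4 body diagonals.
DIRECTIONS = np.array(
    [
        (1, 0, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 1, 1),
        (1, 1, -1),
        (1, -1, 1),
        (-1, 1, 1),
    ],
    dtype=int,
)

_DEPTH_BINS = ((0.9, 5), (0.8, 4), (0.7, 3), (0.6, 2), (0.5, 1))


@dataclass(frozen=True)
class DepthIndicator:
    """Integer depth per member voxel and the cluster mean."""

    per_voxel: dict[Voxel, int]
    average: float


@dataclass(frozen=True)
class VolumeIndicator:
    """Count of cavity-interior empty voxels near one anchor."""

    voxel_count: int
    probe_radius: float = DEFAULT_VOLUME_RADIUS
    interior_direction_min: int = DEFAULT_INTERIOR_DIRECTION_MIN


def depth_of(sa: float) -> int:
    """Map a solid angle (steradians) to its depth bin.

    Bin boundaries belong to the lower bin (``sa = 0.9 * 4*pi`` maps to 4);
    anything at or below ``0.5 * 4*pi`` maps to -1.
    """
    if not 0.0 <= sa <= FOUR_PI * (1 + 1e-12):
        raise ValueError(f"solid angle {sa} outside [0, 4*pi]")
    for frac, value in _DEPTH_BINS:
        if sa > frac * FOUR_PI:
            return value
    return -1


def average_depth(cluster: PocketCluster, sa_map: SolidAngleMap) -> DepthIndicator:
    """Depth bins for each member plus their arithmetic mean (-1s included)."""
    per_voxel = {m: depth_of(sa_map[m]) for m in cluster.members}
    return DepthIndicator(per_voxel=per_voxel, average=float(np.mean(list(per_voxel.values()))))


def _march_blocked(occ: np.ndarray, start: np.ndarray, step: np.ndarray) -> bool:
    """Walk voxel-by-voxel from ``start`` along ``step``; True if an occupied
    voxel is hit before leaving the grid."""
    dims = occ.shape
    pos = np.array(start, dtype=int)
    while True:
        pos = pos + step
        if (pos < 0).any() or (pos >= dims).any():
            return False
        if occ[pos[0], pos[1], pos[2]]:
            return True


def interior_direction_count(grid: VoxelGrid, voxel) -> int:
    """Number of the 7 bi-directional lines through an empty voxel that hit
    occupancy in both directions (0..7)."""
    voxel = tuple(int(v) for v in voxel)
    if grid.labels[voxel] != EXTERIOR:
        raise NotEmptyVoxelError(f"voxel {voxel} is occupied")
    occ = grid.occupied
    start = np.array(voxel)
    count = 0
    for step in DIRECTIONS:
        if _march_blocked(occ, start, step) and _march_blocked(occ, start, -step):
            count += 1
    return count


def _blocked_bulk(occ: np.ndarray, starts: np.ndarray, step: np.ndarray) -> np.ndarray:
    """Vectorised ray march: for each start voxel, does stepping along
    ``step`` hit occupancy before leaving the grid?"""
    dims = np.array(occ.shape)
    pos = starts.copy()
    blocked = np.zeros(len(starts), dtype=bool)
    active = np.ones(len(starts), dtype=bool)
    while active.any():
        pos[active] += step
        act_idx = np.flatnonzero(active)
        p = pos[act_idx]
        inb = np.all((p >= 0) & (p < dims), axis=1)
        active[act_idx[~inb]] = False
        inside_idx = act_idx[inb]
        p = pos[inside_idx]
        hit = occ[p[:, 0], p[:, 1], p[:, 2]]
        blocked[inside_idx[hit]] = True
        active[inside_idx[hit]] = False
    return blocked


def interior_direction_counts_bulk(grid: VoxelGrid, voxels: np.ndarray) -> np.ndarray:
    """Vectorised :func:`interior_direction_count` over an (N, 3) index array."""
    voxels = np.asarray(voxels, dtype=int)
    if len(voxels) == 0:
        return np.zeros(0, dtype=int)
    occ = grid.occupied
    counts = np.zeros(len(voxels), dtype=int)
    for step in DIRECTIONS:
        fwd = _blocked_bulk(occ, voxels, step)
        back = _blocked_bulk(occ, voxels, -step)
        counts += fwd & back
    return counts


def cavity_volume(
    grid: VoxelGrid,
    anchor,
    probe_radius: float = DEFAULT_VOLUME_RADIUS,
    interior_direction_min: int = DEFAULT_INTERIOR_DIRECTION_MIN,
) -> VolumeIndicator:
    """Count cavity-interior empty voxels within ``probe_radius`` of the anchor.

    An empty voxel inside the probe ball counts iff its interior-direction
    count is at least ``interior_direction_min``.  ``probe_radius`` below the
    grid spacing yields an empty ball and a zero count.
    """
    anchor = tuple(int(v) for v in anchor)
    if grid.labels[anchor] != SURFACE:
        raise NotSurfaceVoxelError(f"anchor {anchor} is not a surface voxel")
    if probe_radius <= grid.spacing:
        return VolumeIndicator(0, probe_radius, interior_direction_min)

    offs = sphere_offsets(probe_radius, grid.spacing)
    pts = np.asarray(anchor) + offs
    inb = grid.in_bounds(pts)
    pts = pts[inb]
    empty = grid.labels[pts[:, 0], pts[:, 1], pts[:, 2]] == EXTERIOR
    pts = pts[empty]
    counts = interior_direction_counts_bulk(grid, pts)
    return VolumeIndicator(
        voxel_count=int((counts >= interior_direction_min).sum()),
        probe_radius=probe_radius,
        interior_direction_min=interior_direction_min,
    )
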