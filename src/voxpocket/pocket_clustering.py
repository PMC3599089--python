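"""Selection and single-linkage clustering of highly concave surface voxels.

Only the surface voxels whose solid angles fall in the configured top
fraction are clustered.  Two candidates are linked when their centers are
within the distance threshold *and* their solid angles agree within a band;
connected components of this relation become pocket clusters, each
represented by the member with the largest solid angle (its *anchor*).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .solid_angle import FOUR_PI, SolidAngleMap
from .voxelization import VoxelGrid

#: Fraction of surface voxels (by solid angle) kept as pocket candidates.
DEFAULT_CANDIDATE_FRACTION = 0.20
#: Single-linkage distance threshold between candidate voxels (Angstrom).
DEFAULT_CLUSTER_DISTANCE = 20.0
#: Maximum solid-angle difference for two candidates to be linked
#: (one depth-bin width, 0.1 * 4*pi steradians).
DEFAULT_SA_BAND = 0.1 * FOUR_PI

Voxel = tuple[int, int, int]


@dataclass(frozen=True)
class PocketCluster:
    """A connected group of concave candidate voxels."""

    members: tuple[Voxel, ...]  # sorted lexicographically
    anchor: Voxel
    anchor_sa: float
    mean_sa: float

    def __post_init__(self) -> None:
        if self.anchor not in self.members:
            raise ValueError("anchor must be a cluster member")

    def __len__(self) -> int:
        return len(self.members)


def select_candidates(
    sa_map: SolidAngleMap, fraction: float = DEFAULT_CANDIDATE_FRACTION
) -> set[Voxel]:
    """The ``ceil(fraction * N)`` surface voxels with the largest solid angles.

    Ties at the cutoff value are all included, so the result is independent
    of input ordering.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if len(sa_map) == 0:
        raise ValueError("solid-angle map is empty")
    n = math.ceil(fraction * len(sa_map))
    cutoff = np.sort(sa_map.values)[::-1][n - 1]
    keep = sa_map.values >= cutoff
    return {tuple(int(x) for x in idx) for idx in sa_map.indices[keep]}


def pick_anchor(members, sa_map: SolidAngleMap) -> Voxel:
    """The member with maximal solid angle; ties go to the lexicographically
    smallest voxel index."""
    members = list(members)
    if not members:
        raise ValueError("cannot pick an anchor from an empty member set")
    return min(members, key=lambda v: (-sa_map[v], tuple(v)))


def cluster_voxels(
    candidates,
    sa_map: SolidAngleMap,
    grid: VoxelGrid,
    distance_threshold: float = DEFAULT_CLUSTER_DISTANCE,
    sa_band: float = DEFAULT_SA_BAND,
) -> list[PocketCluster]:
    """Single-linkage clusters over the candidate voxels.

    Two candidates are linked iff their Cartesian center distance is at most
    ``distance_threshold`` (Angstrom) and their solid angles differ by at
    most ``sa_band`` (steradians).  Clusters are returned sorted by anchor
    solid angle, descending (anchor index breaks exact ties), so the output
    is independent of candidate iteration order.
    """
    cand = sorted(tuple(int(x) for x in v) for v in candidates)
    if not cand:
        return []
    missing = [v for v in cand if v not in sa_map]
    if missing:
        raise ValueError(f"candidates outside the solid-angle map: {missing[:3]}")

    idx = np.array(cand, dtype=int)
    centers = grid.centers(idx)
    sa = np.array([sa_map[v] for v in cand])

    tree = cKDTree(centers)
    pairs = tree.query_pairs(r=distance_threshold, output_type="ndarray")
    if len(pairs):
        ok = np.abs(sa[pairs[:, 0]] - sa[pairs[:, 1]]) <= sa_band
        pairs = pairs[ok]
    n = len(cand)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])) if len(pairs) else ([], ([], [])),
        shape=(n, n),
    )
    n_comp, labels = connected_components(adj, directed=False)

    clusters: list[PocketCluster] = []
    for comp in range(n_comp):
        members = tuple(cand[i] for i in np.flatnonzero(labels == comp))
        anchor = pick_anchor(members, sa_map)
        clusters.append(
            PocketCluster(
                members=members,
                anchor=anchor,
                anchor_sa=sa_map[anchor],
                mean_sa=float(np.mean([sa_map[m] for m in members])),
            )
        )
    clusters.sort(key=lambda c: (-c.anchor_sa, c.anchor))
    return clusters


def cluster_report_rows(clusters, grid: VoxelGrid) -> list[dict]:
    """Tabular summary used by the CLI's TSV export."""
    rows = []
    for i, cl in enumerate(clusters):
        x, y, z = grid.centers(np.array(cl.anchor))
        rows.append(
            {
                "cluster_id": i,
                "size": len(cl),
                "anchor_index": "{} {} {}".format(*cl.anchor),
                "anchor_x": round(float(x), 3),
                "anchor_y": round(float(y), 3),
                "anchor_z": round(float(z), 3),
                "anchor_sa": float(cl.anchor_sa),
                "mean_sa": float(cl.mean_sa),
            }
        )
    return rows
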