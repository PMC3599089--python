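"""Combine depth and volume indicators into a ranked score.

Each candidate region's ranked value is::

    rv = (depth_avg / depth_max) * w1 + (volume / volume_max) * w2

with the maxima taken over the candidate regions of the same query protein
and ``w1 + w2 = 1``.  Regions are ordered by rv descending; exact ties are
broken by larger volume, then smaller cluster id.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cavity_features import DepthIndicator, VolumeIndicator
from .errors import NoRankableRegionError
from .pocket_clustering import PocketCluster


@dataclass(frozen=True)
class Weights:
    """Linear weighting coefficients for depth (w1) and volume (w2)."""

    w1: float = 0.5
    w2: float = 0.5

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class RankedRegion:
    cluster: PocketCluster
    depth: DepthIndicator
    volume: VolumeIndicator
    rv: float
    rank: int  # 1-based
    cluster_id: int  # position in the input feature list


def rank_regions(
    features: list[tuple[PocketCluster, DepthIndicator, VolumeIndicator]],
    weights: Weights = Weights(),
) -> list[RankedRegion]:
    """Score and order candidate regions for one query protein.

    Raises :class:`~voxpocket.errors.NoRankableRegionError` when the maximal
    average depth is not positive or the maximal volume count is zero, i.e.
    no concave cavity was found.
    """
    if not features:
        raise NoRankableRegionError("no candidate regions to rank")
    cd_max = max(d.average for _, d, _ in features)
    cv_max = max(v.voxel_count for _, _, v in features)
    if cd_max <= 0:
        raise NoRankableRegionError(f"maximal average depth {cd_max:g} is not positive")
    if cv_max == 0:
        raise NoRankableRegionError("maximal cavity volume is zero")

    scored = []
    for cid, (cluster, depth, volume) in enumerate(features):
        rv = (depth.average / cd_max) * weights.w1 + (volume.voxel_count / cv_max) * weights.w2
        scored.append((rv, volume.voxel_count, cid, cluster, depth, volume))
    # anchor index precedes the positional id so that exact ties resolve
    # independently of input order
    scored.sort(key=lambda t: (-t[0], -t[1], t[3].anchor, t[2]))
    return [
        RankedRegion(cluster=c, depth=d, volume=v, rv=rv, rank=i + 1, cluster_id=cid)
        for i, (rv, _, cid, c, d, v) in enumerate(scored)
    ]


def top_k(regions: list[RankedRegion], k: int) -> list[RankedRegion]:
    """First ``min(k, n)`` regions of a ranked list."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return regions[:k]
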