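"""End-to-end orchestration: structure -> grid -> solid angles -> clusters ->
features -> ranked regions."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

from .cavity_features import average_depth, cavity_volume
from .config import RunConfig
from .errors import NoRankableRegionError
from .pocket_clustering import cluster_voxels, select_candidates
from .ranking import RankedRegion, Weights, rank_regions
from .solid_angle import SolidAngleMap, solid_angle_all
from .structure_io import Structure
from .voxelization import VoxelGrid, build_grid

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    structure: Structure
    grid: VoxelGrid
    sa_map: SolidAngleMap
    regions: list[RankedRegion]  # empty when no rankable region exists
    failure: str | None = None  # reason when regions is empty


def run_pipeline(structure: Structure, config: RunConfig = RunConfig()) -> PipelineResult:
    """Run every stage on one structure; deterministic for a given config."""
    stages: list[tuple[str, float]] = []

    def tick(name: str, t0: float) -> None:
        stages.append((name, time.perf_counter() - t0))
        logger.info("stage %-12s %.2fs", name, stages[-1][1])

    t0 = time.perf_counter()
    grid = build_grid(structure, spacing=config.spacing, padding=config.padding)
    tick("voxelize", t0)

    t0 = time.perf_counter()
    sa_map = solid_angle_all(grid, radius=config.sa_radius)
    tick("solid_angle", t0)

    t0 = time.perf_counter()
    candidates = select_candidates(sa_map, fraction=config.candidate_fraction)
    clusters = cluster_voxels(
        candidates,
        sa_map,
        grid,
        distance_threshold=config.cluster_distance,
        sa_band=config.sa_band,
    )
    tick("cluster", t0)

    t0 = time.perf_counter()
    features = [
        (
            cl,
            average_depth(cl, sa_map),
            cavity_volume(
                grid,
                cl.anchor,
                probe_radius=config.volume_radius,
                interior_direction_min=config.interior_direction_min,
            ),
        )
        for cl in clusters
    ]
    tick("features", t0)

    t0 = time.perf_counter()
    try:
        regions = rank_regions(features, Weights(config.w1, config.w2))
        failure = None
    except NoRankableRegionError as exc:
        regions = []
        failure = str(exc)
    tick("rank", t0)

    return PipelineResult(structure=structure, grid=grid, sa_map=sa_map, regions=regions, failure=failure)
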