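import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import direction_count_bruteforce, random_blob_occupancy
from voxpocket.cavity_features import (
    average_depth,
    cavity_volume,
    depth_of,
    interior_direction_count,
    interior_direction_counts_bulk,
)
from voxpocket.errors import NotEmptyVoxelError, NotSurfaceVoxelError
from voxpocket.pocket_clustering import PocketCluster
from voxpocket.solid_angle import FOUR_PI, SolidAngleMap
from voxpocket.synthetic_shapes import ShapeSpec, generate_grid
from voxpocket.voxelization import EXTERIOR, SURFACE, grid_from_occupancy


class TestDepthOf:
    @pytest.mark.parametrize(
        "frac,expected",
        [
            (0.95, 5),
            (0.91, 5),
            (0.90, 4),  # boundary belongs to the lower bin
            (0.85, 4),
            (0.80, 3),
            (0.75, 3),
            (0.70, 2),
            (0.65, 2),
            (0.60, 1),
            (0.55, 1),
            (0.50, -1),  # at the bottom boundary: else branch
            (0.30, -1),
            (0.0, -1),
            (1.0, 5),
        ],
    )
    def test_branch_table(self, frac, expected):
        assert depth_of(frac * FOUR_PI) == expected

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            depth_of(-0.1)
        with pytest.raises(ValueError):
            depth_of(4.1 * math.pi)

    @given(
        a=st.floats(min_value=0.0, max_value=FOUR_PI),
        b=st.floats(min_value=0.0, max_value=FOUR_PI),
    )
    @settings(max_examples=200)
    def test_monotone_step_function(self, a, b):
        lo, hi = sorted((a, b))
        assert depth_of(lo) <= depth_of(hi)


class TestAverageDepth:
    def test_mixed_members_mean(self):
        fracs = [0.95, 0.92, 0.85, 0.75, 0.55, 0.30]  # depths 5,5,4,3,1,-1
        idx = [(i, 0, 0) for i in range(6)]
        sa_map = SolidAngleMap(
            indices=np.array(idx), values=np.array([f * FOUR_PI for f in fracs]), sphere_radius=6.0
        )
        cluster = PocketCluster(tuple(idx), idx[0], fracs[0] * FOUR_PI, 0.0)
        ind = average_depth(cluster, sa_map)
        assert sorted(ind.per_voxel.values(), reverse=True) == [5, 5, 4, 3, 1, -1]
        assert ind.average == pytest.approx(17 / 6)

    def test_all_five(self):
        idx = [(i, 0, 0) for i in range(3)]
        sa_map = SolidAngleMap(np.array(idx), np.full(3, 0.95 * FOUR_PI), 6.0)
        cluster = PocketCluster(tuple(idx), idx[0], 0.95 * FOUR_PI, 0.0)
        assert average_depth(cluster, sa_map).average == pytest.approx(5.0)

    def test_singleton_negative(self):
        idx = [(0, 0, 0)]
        sa_map = SolidAngleMap(np.array(idx), np.array([0.4 * FOUR_PI]), 6.0)
        cluster = PocketCluster(tuple(idx), idx[0], 0.4 * FOUR_PI, 0.0)
        assert average_depth(cluster, sa_map).average == pytest.approx(-1.0)


def enclosed_void_grid():
    return generate_grid(ShapeSpec("enclosed_void", radius=8.0, void_radius=3.0))


class TestInteriorDirectionCount:
    def test_enclosed_void_centre_is_seven(self):
        grid = enclosed_void_grid()
        centre = np.round((np.zeros(3) - grid.origin) / grid.spacing).astype(int)
        assert grid.labels[tuple(centre)] == EXTERIOR
        assert interior_direction_count(grid, centre) == 7

    def test_open_sky_above_slab(self, slab_grid):
        top = np.argwhere(slab_grid.labels == SURFACE)
        centers = slab_grid.centers(top)
        mid = top[np.argmax(centers[:, 2] - 0.001 * (abs(centers[:, 0]) + abs(centers[:, 1])))]
        above = mid + np.array([0, 0, 3])
        count = interior_direction_count(slab_grid, above)
        assert count <= 3
        assert count == direction_count_bruteforce(slab_grid.occupied, above)

    def test_occupied_voxel_errors(self, slab_grid):
        occ_voxel = np.argwhere(slab_grid.labels != EXTERIOR)[0]
        with pytest.raises(NotEmptyVoxelError):
            interior_direction_count(slab_grid, occ_voxel)

    def test_bruteforce_equivalence_random_grid(self):
        rng = np.random.default_rng(5)
        occ = random_blob_occupancy(rng, 22, margin=4)
        grid = grid_from_occupancy(occ)
        empties = np.argwhere(grid.labels == EXTERIOR)[::37]
        bulk = interior_direction_counts_bulk(grid, empties)
        for voxel, got in zip(empties, bulk):
            expected = direction_count_bruteforce(occ, voxel)
            assert got == expected
            assert interior_direction_count(grid, voxel) == expected


class TestCavityVolume:
    def test_enclosed_void_counts_all_void_voxels(self):
        grid = enclosed_void_grid()
        # anchor: inner-wall surface voxel right above the void centre
        centre = np.round((np.zeros(3) - grid.origin) / grid.spacing).astype(int)
        anchor = centre.copy()
        while grid.labels[tuple(anchor)] == EXTERIOR:
            anchor[2] += 1
        assert grid.labels[tuple(anchor)] == SURFACE
        # oracle: empty voxels within 10 A of the anchor with >= 4 blocked lines
        offs = np.argwhere(np.ones((21, 21, 21))) - 10
        offs = offs[(offs**2).sum(axis=1) <= 100]
        pts = anchor + offs
        expected = 0
        for p in pts:
            if grid.labels[tuple(p)] == EXTERIOR and direction_count_bruteforce(grid.occupied, p) >= 4:
                expected += 1
        vol = cavity_volume(grid, anchor, probe_radius=10.0)
        assert vol.voxel_count == expected
        # the fully-enclosed void's own voxels all count (7/7 directions)
        void = [
            p
            for p in np.argwhere(grid.labels == EXTERIOR)
            if np.linalg.norm(grid.centers(p)) <= 2.0
        ]
        assert vol.voxel_count >= len(void) > 0

    def test_convex_sphere_volume_zero(self, sphere_grid):
        surf = sphere_grid.surface_indices()
        assert cavity_volume(sphere_grid, surf[0], probe_radius=10.0).voxel_count == 0

    def test_zero_probe_radius(self, sphere_grid):
        surf = sphere_grid.surface_indices()
        assert cavity_volume(sphere_grid, surf[0], probe_radius=0.0).voxel_count == 0

    def test_non_surface_anchor_errors(self, sphere_grid):
        interior = np.argwhere(sphere_grid.labels == 1)[0]
        with pytest.raises(NotSurfaceVoxelError):
            cavity_volume(sphere_grid, interior)

    def test_deeper_pocket_never_smaller(self):
        volumes = []
        for rp in (2.5, 3.0, 3.5, 4.0):
            grid = generate_grid(
                ShapeSpec("sphere_with_cap_pocket", radius=10.0, pocket_radius=rp, pocket_offset=7.0)
            )
            # anchor: surface voxel closest to the pocket bottom
            surf = grid.surface_indices()
            centers = grid.centers(surf)
            bottom = np.array([0.0, 0.0, 7.0 - rp])
            anchor = surf[np.argmin(np.linalg.norm(centers - bottom, axis=1))]
            volumes.append(cavity_volume(grid, anchor, probe_radius=10.0).voxel_count)
        assert volumes == sorted(volumes)
        assert volumes[-1] > 0
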