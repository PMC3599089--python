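"""Analytic test solids as occupancy grids and pseudo-atom PDB fixtures.

Every stage of the pipeline can be exercised on these shapes without any
external data.  Grids are produced by evaluating the analytic inside-test at
voxel centers on a lattice aligned so that centers fall on integer multiples
of the spacing; PDB fixtures pack carbon pseudo-atoms (vdW 1.70 A) on a
1.4 A lattice inside a slightly eroded copy of the same solid, so that
re-voxelising the PDB reproduces the analytic grid to within one voxel
layer.  Everything is deterministic for a given spec.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import Atom, Structure, format_atom_record
from .voxelization import VoxelGrid, grid_from_occupancy

KINDS = (
    "solid_sphere",
    "sphere_with_cap_pocket",
    "slab",
    "cube",
    "cylindrical_well",
    "enclosed_void",
    "complementary_pair",
)

#: Pseudo-atom lattice pitch (below 2 * 1.70 A so spheres overlap leaving no holes).
ATOM_PITCH = 1.4
PSEUDO_ELEMENT = "C"
PSEUDO_RADIUS = 1.70
#: Erosion applied when placing pseudo-atoms, compensating their vdW radius.
ATOM_SHRINK = 1.0


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one analytic solid.

    Unused size fields may stay at their defaults; ``validate`` checks the
    ones the chosen ``kind`` requires.
    """

    kind: str
    spacing: float = 1.0
    padding: float = 10.0
    seed: int = 0
    atom_pitch: float = ATOM_PITCH  # pseudo-atom lattice pitch; smaller = smoother surface
    radius: float = 10.0  # host sphere radius / complementary-pair sphere
    edge: float = 20.0  # cube edge
    thickness: float = 6.0  # slab thickness (z)
    extent: float = 30.0  # lateral extent of slab / well block
    pocket_radius: float = 4.0
    pocket_offset: float = 7.0  # carved-ball center distance from host center (+z)
    well_radius: float = 2.0
    well_depth: float = 8.0
    void_radius: float = 3.0

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; one of {KINDS}")
        if self.spacing <= 0 or self.padding < 0:
            raise ValueError("spacing must be positive and padding non-negative")
        if not 0 < self.atom_pitch < 2 * PSEUDO_RADIUS:
            raise ValueError("atom_pitch must be positive and below the pseudo-atom diameter")
        sizes = {
            "solid_sphere": (self.radius,),
            "complementary_pair": (self.radius,),
            "cube": (self.edge,),
            "slab": (self.thickness, self.extent),
            "sphere_with_cap_pocket": (self.radius, self.pocket_radius, self.pocket_offset),
            "cylindrical_well": (self.well_radius, self.well_depth, self.extent),
            "enclosed_void": (self.radius, self.void_radius),
        }[self.kind]
        if any(s <= 0 for s in sizes):
            raise ValueError(f"{self.kind}: size parameters must be positive")
        if self.kind == "sphere_with_cap_pocket" and self.pocket_radius >= self.radius:
            raise ValueError("pocket must be smaller than the host sphere")
        if self.kind == "enclosed_void" and self.void_radius >= self.radius:
            raise ValueError("void must be smaller than the host sphere")
        if self.kind == "cylindrical_well" and self.well_depth >= self.extent:
            raise ValueError("well depth must be below the block thickness")


def _inside(spec: ShapeSpec, pts: np.ndarray, shrink: float = 0.0) -> np.ndarray:
    """Vectorised inside-test for the analytic solid, optionally eroded by
    ``shrink`` Angstrom (carved features are *grown* by the same amount)."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    r2 = x * x + y * y + z * z
    if spec.kind in ("solid_sphere", "complementary_pair"):
        return r2 <= (spec.radius - shrink) ** 2
    if spec.kind == "cube":
        h = spec.edge / 2 - shrink
        return np.max(np.abs(pts), axis=1) <= h
    if spec.kind == "slab":
        return (
            (np.abs(z) <= spec.thickness / 2 - shrink)
            & (np.abs(x) <= spec.extent / 2 - shrink)
            & (np.abs(y) <= spec.extent / 2 - shrink)
        )
    if spec.kind == "sphere_with_cap_pocket":
        host = r2 <= (spec.radius - shrink) ** 2
        dz = z - spec.pocket_offset
        carved = x * x + y * y + dz * dz <= (spec.pocket_radius + shrink) ** 2
        return host & ~carved
    if spec.kind == "cylindrical_well":
        # block occupying z in [-extent/2, 0], with a vertical open well
        # of radius well_radius drilled from the top face down to -well_depth
        half = spec.extent / 2
        block = (
            (z <= 0 - shrink)
            & (z >= -half + shrink)
            & (np.abs(x) <= half - shrink)
            & (np.abs(y) <= half - shrink)
        )
        well = (x * x + y * y <= (spec.well_radius + shrink) ** 2) & (
            z >= -spec.well_depth - shrink
        )
        return block & ~well
    if spec.kind == "enclosed_void":
        return (r2 <= (spec.radius - shrink) ** 2) & (r2 >= (spec.void_radius + shrink) ** 2)
    raise ValueError(spec.kind)


def _bbox(spec: ShapeSpec) -> tuple[np.ndarray, np.ndarray]:
    if spec.kind in ("solid_sphere", "complementary_pair"):
        h = spec.radius
        return -np.array([h, h, h]), np.array([h, h, h])
    if spec.kind == "cube":
        h = spec.edge / 2
        return -np.array([h, h, h]), np.array([h, h, h])
    if spec.kind == "slab":
        return (
            -np.array([spec.extent / 2, spec.extent / 2, spec.thickness / 2]),
            np.array([spec.extent / 2, spec.extent / 2, spec.thickness / 2]),
        )
    if spec.kind == "cylindrical_well":
        h = spec.extent / 2
        return -np.array([h, h, h]), np.array([h, h, 0.0])
    if spec.kind in ("sphere_with_cap_pocket", "enclosed_void"):
        h = spec.radius
        return -np.array([h, h, h]), np.array([h, h, h])
    raise ValueError(spec.kind)


def generate_grid(spec: ShapeSpec) -> VoxelGrid:
    """Classified occupancy grid of the analytic solid, padded on all sides.

    The lattice is aligned so voxel centers land on integer multiples of the
    spacing (shape centers sit on a voxel center).
    """
    spec.validate()
    lo, hi = _bbox(spec)
    n_pad = int(math.ceil(spec.padding / spec.spacing))
    i_lo = np.floor(lo / spec.spacing).astype(int) - n_pad
    i_hi = np.ceil(hi / spec.spacing).astype(int) + n_pad
    dims = i_hi - i_lo + 1
    origin = i_lo * spec.spacing

    axes = [origin[d] + spec.spacing * np.arange(dims[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    occ = _inside(spec, pts).reshape(tuple(dims))
    return grid_from_occupancy(occ, origin=origin, spacing=spec.spacing)


def complement_grid(grid: VoxelGrid) -> VoxelGrid:
    """Grid on the same lattice whose occupied set is the exact complement."""
    return grid_from_occupancy(~grid.occupied, origin=grid.origin, spacing=grid.spacing)


def generate_pair(spec: ShapeSpec) -> tuple[VoxelGrid, VoxelGrid]:
    """A solid and its complement on a shared lattice (complementarity tests)."""
    solid = generate_grid(spec)
    return solid, complement_grid(solid)


def _pseudo_atom_points(spec: ShapeSpec) -> np.ndarray:
    pitch = spec.atom_pitch
    lo, hi = _bbox(spec)
    n_lo = np.floor(lo / pitch).astype(int)
    n_hi = np.ceil(hi / pitch).astype(int)
    axes = [pitch * np.arange(n_lo[d], n_hi[d] + 1) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    return pts[_inside(spec, pts, shrink=ATOM_SHRINK)]


def pseudo_structure(spec: ShapeSpec) -> Structure:
    """The fixture as an in-memory :class:`Structure` (one residue per atom)."""
    spec.validate()
    pts = _pseudo_atom_points(spec)
    if len(pts) == 0:
        raise ValueError(f"{spec.kind}: no pseudo-atoms fit inside the solid")
    if len(pts) > 9999:
        raise ValueError(f"{spec.kind}: fixture too large for PDB residue numbering ({len(pts)})")
    atoms = tuple(
        Atom(
            element=PSEUDO_ELEMENT,
            position=p,
            vdw_radius=PSEUDO_RADIUS,
            residue_name="UNK",
            residue_seq=i + 1,
            chain_id="A",
            serial=i + 1,
            name="C",
        )
        for i, p in enumerate(pts)
    )
    return Structure(atoms=atoms, source_id=f"fixture:{spec.kind}")


def generate_pdb(spec: ShapeSpec) -> str:
    """PDB text of the pseudo-atom fixture (deterministic for a given spec)."""
    buf = io.StringIO()
    for atom in pseudo_structure(spec).atoms:
        buf.write(format_atom_record(atom))
    buf.write("END\n")
    return buf.getvalue()


def reference_pocket_spec() -> ShapeSpec:
    """The pinned pocket fixture used for end-to-end validation.

    A 10 A host sphere with a 4 A cavity carved at (0, 0, 7) — a deep pocket
    whose mouth barely opens at the top pole — packed at 1.0 A pitch so the
    outer surface is smooth at 1 A voxel resolution.
    """
    return ShapeSpec(
        kind="sphere_with_cap_pocket",
        radius=10.0,
        pocket_radius=4.0,
        pocket_offset=7.0,
        atom_pitch=1.0,
    )


def reference_pocket_config():
    """Pipeline parameters tuned for the reference pocket fixture.

    The candidate fraction (0.10) keeps the convex baseline out of the
    candidate set and the tighter solid-angle band (0.05 * 4*pi) stops
    single-linkage chaining between successive wall rings, so the rank-1
    cluster is exactly the pocket's bottom wall.
    """
    from .config import RunConfig

    return RunConfig(candidate_fraction=0.10, sa_band=0.05 * 4.0 * math.pi)


def _pocket_wall_voxels(spec: ShapeSpec, grid: VoxelGrid) -> np.ndarray:
    """Surface voxels lining the carved cavity (deep part for cap pockets).

    Purely geometric: cavity voxels are the empty voxels inside the analytic
    carved region (strictly inside the host), wall voxels are the surface
    voxels face-adjacent to them.  For cap pockets the wall is restricted to
    the bottom region (center z at most pocket_offset - pocket_radius + 1.5),
    the part a concave-surface detector should flag.
    """
    labels = grid.labels
    empty_idx = np.argwhere(labels == 0)
    cen = grid.centers(empty_idx)
    if spec.kind == "sphere_with_cap_pocket":
        pc = np.array([0.0, 0.0, spec.pocket_offset])
        cavity = (np.linalg.norm(cen - pc, axis=1) <= spec.pocket_radius) & (
            np.linalg.norm(cen, axis=1) <= spec.radius - 1.0
        )
    elif spec.kind == "cylindrical_well":
        cavity = (
            (cen[:, 0] ** 2 + cen[:, 1] ** 2 <= spec.well_radius**2)
            & (cen[:, 2] <= -1.0)
            & (cen[:, 2] >= -spec.well_depth)
        )
    else:
        raise ValueError(f"{spec.kind} has no pocket ground truth")

    mask = np.zeros(labels.shape, dtype=bool)
    cav = empty_idx[cavity]
    mask[cav[:, 0], cav[:, 1], cav[:, 2]] = True
    surf = np.argwhere(labels == 2)
    adjacent = np.zeros(len(surf), dtype=bool)
    for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        n = surf + d
        adjacent |= mask[n[:, 0], n[:, 1], n[:, 2]]
    wall = surf[adjacent]
    if spec.kind == "sphere_with_cap_pocket":
        z = grid.centers(wall)[:, 2]
        wall = wall[z <= spec.pocket_offset - spec.pocket_radius + 1.5]
    return wall


def pocket_truth_residues(spec: ShapeSpec, lining_distance: float = 4.5) -> set[tuple[str, int]]:
    """Ground-truth pocket-lining residues for pocket-carrying fixtures.

    A pseudo-residue lines the pocket when its atom lies within
    ``lining_distance`` of a pocket wall voxel center (see
    :func:`_pocket_wall_voxels`); computed on the same voxel lattice the
    pipeline uses, so the annotation matches the grid geometry exactly.
    """
    from scipy.spatial import cKDTree

    from .voxelization import build_grid

    spec.validate()
    structure = pseudo_structure(spec)
    grid = build_grid(structure, spacing=spec.spacing, padding=spec.padding)
    wall = _pocket_wall_voxels(spec, grid)
    if len(wall) == 0:
        raise ValueError(f"{spec.kind}: no pocket wall voxels found")
    tree = cKDTree(grid.centers(wall))
    d, _ = tree.query(structure.positions)
    return {("A", int(i) + 1) for i in np.flatnonzero(d <= lining_distance)}


def expected_properties(spec: ShapeSpec) -> dict:
    """Analytic anchors (where known) for the fixture, for reporting."""
    spec.validate()
    out: dict = {"kind": spec.kind, "spacing": spec.spacing}
    if spec.kind == "slab":
        out["flat_face_sa_continuum"] = 2 * math.pi
    if spec.kind == "cube":
        out["corner_sa_continuum"] = math.pi / 2
        out["edge_sa_continuum"] = math.pi
    if spec.kind == "complementary_pair":
        out["sa_sum_at_boundary"] = 4 * math.pi
    if spec.kind == "sphere_with_cap_pocket":
        out["recommended_config"] = reference_pocket_config().to_dict()
    return out


def write_fixture(spec: ShapeSpec, outdir: str | Path, lining_distance: float = 4.5) -> dict:
    """Write PDB (+ truth table for pocket shapes) + expected-property JSON.

    Returns a manifest of the files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pdb_path = outdir / f"{spec.kind}.pdb"
    pdb_path.write_text(generate_pdb(spec))
    files = {"pdb": str(pdb_path)}

    if spec.kind in ("sphere_with_cap_pocket", "cylindrical_well"):
        truth = pocket_truth_residues(spec, lining_distance=lining_distance)
        truth_path = outdir / f"{spec.kind}.truth.tsv"
        truth_path.write_text("".join(f"{c}\t{r}\n" for c, r in sorted(truth)))
        files["truth"] = str(truth_path)

    props_path = outdir / f"{spec.kind}.expected.json"
    props_path.write_text(json.dumps(expected_properties(spec), indent=2) + "\n")
    files["expected"] = str(props_path)
    return files
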