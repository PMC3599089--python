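"""Scoring predicted regions against annotated binding residues.

A predicted region *matches* the annotation when any of its member voxel
centers lies within ``match_distance`` of any atom of an annotated residue.
A trial is successful when one of the top-k regions matches.  Confusion
counts are accumulated at residue level: a residue is predicted positive iff
any of its atoms lies within ``match_distance`` of a matching top-k region's
member voxels; positives are scored against the annotated residue set over
all residues of the structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .ranking import RankedRegion, top_k
from .structure_io import Structure, is_water
from .voxelization import VoxelGrid

#: Residue/voxel contact cutoff (Angstrom).
DEFAULT_MATCH_DISTANCE = 4.5

Residue = tuple[str, int]  # (chain_id, residue_seq)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    mcc: float
    #: names of metrics whose denominator was zero and were reported as 0
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "mcc": self.mcc,
            "degenerate": list(self.degenerate),
        }


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, accuracy, PPV and MCC from raw counts.

    A metric whose denominator is zero is reported as 0 and flagged in
    ``degenerate``.
    """
    if counts.total == 0:
        raise ValueError("confusion counts are all zero")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    degenerate: list[str] = []

    def ratio(name: str, num: float, den: float) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sensitivity = ratio("sensitivity", tp, tp + fn)
    specificity = ratio("specificity", tn, tn + fp)
    accuracy = (tp + tn) / counts.total
    ppv = ratio("ppv", tp, tp + fp)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ratio("mcc", tp * tn - fp * fn, mcc_den)
    return Metrics(sensitivity, specificity, accuracy, ppv, mcc, tuple(degenerate))


def _region_member_centers(region: RankedRegion, grid: VoxelGrid) -> np.ndarray:
    return grid.centers(np.array(region.cluster.members, dtype=int))


def match_member_centers(
    member_centers: list[np.ndarray],
    truth: set[Residue] | list[Residue],
    structure: Structure,
    k: int = 3,
    match_distance: float = DEFAULT_MATCH_DISTANCE,
) -> tuple[bool, ConfusionCounts]:
    """Core matcher over per-region member voxel centers, in rank order.

    ``member_centers[i]`` is the (Mi, 3) array of the rank-(i+1) region's
    member voxel centers in Angstrom.
    """
    truth_set = {(str(c), int(r)) for c, r in truth}
    if not truth_set:
        raise ValueError("truth annotation is empty")

    residues = structure.residues()
    unknown = truth_set - set(residues)
    if unknown:
        raise ValueError(f"annotated residues absent from structure: {sorted(unknown)[:3]}")

    truth_atoms = np.array(
        [a.position for res in truth_set for a in residues[res]], dtype=float
    )
    truth_tree = cKDTree(truth_atoms)

    matching: list[np.ndarray] = []
    for centers in member_centers[:k]:
        hits = truth_tree.query_ball_point(centers, r=match_distance, return_length=True)
        if np.any(hits > 0):
            matching.append(centers)
    success = bool(matching)

    predicted_pos: set[Residue] = set()
    if matching:
        member_tree = cKDTree(np.vstack(matching))
        for res, atoms in residues.items():
            pos = np.array([a.position for a in atoms], dtype=float)
            hits = member_tree.query_ball_point(pos, r=match_distance, return_length=True)
            if np.any(hits > 0):
                predicted_pos.add(res)

    universe = set(residues)
    tp = len(predicted_pos & truth_set)
    fp = len(predicted_pos - truth_set)
    fn = len(truth_set - predicted_pos)
    tn = len(universe) - tp - fp - fn
    return success, ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def match_regions(
    predictions: list[RankedRegion],
    truth: set[Residue] | list[Residue],
    structure: Structure,
    grid: VoxelGrid,
    k: int = 3,
    match_distance: float = DEFAULT_MATCH_DISTANCE,
) -> tuple[bool, ConfusionCounts]:
    """Success flag and residue-level confusion counts for the top-k regions.

    A region matches when any member voxel center lies within
    ``match_distance`` of any atom of an annotated residue; ``truth`` is a
    non-empty collection of (chain_id, residue_seq) pairs and the residue
    universe is every residue of the protein body.
    """
    centers = [_region_member_centers(r, grid) for r in top_k(predictions, k)]
    return match_member_centers(centers, truth, structure, k=k, match_distance=match_distance)


def truth_from_ligand(
    structure: Structure,
    cutoff: float = DEFAULT_MATCH_DISTANCE,
    exclude_water: bool = True,
) -> set[Residue]:
    """Binding residues derived from HETATM proximity: any residue with an
    atom within ``cutoff`` of a ligand atom."""
    ligand = [a for a in structure.het_atoms if not (exclude_water and is_water(a))]
    if not ligand:
        raise ValueError("structure has no (non-water) HETATM ligand atoms")
    tree = cKDTree(np.array([a.position for a in ligand], dtype=float))
    out: set[Residue] = set()
    for res, atoms in structure.residues().items():
        pos = np.array([a.position for a in atoms], dtype=float)
        if np.any(tree.query_ball_point(pos, r=cutoff, return_length=True) > 0):
            out.add(res)
    return out


def read_truth(path: str | Path) -> set[Residue]:
    """Read a two-column (chain, resseq) whitespace/tab table; '#' comments."""
    out: set[Residue] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed truth line: {line!r}")
        out.add((parts[0], int(parts[1])))
    return out


def write_truth(residues, path: str | Path) -> None:
    lines = [f"{c}\t{r}\n" for c, r in sorted({(str(c), int(r)) for c, r in residues})]
    Path(path).write_text("".join(lines))
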