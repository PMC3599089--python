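"""Reading and writing protein structures.

The protein body is built from ``ATOM`` records only; ``HETATM`` records
(ligands, ions, waters) are parsed but kept in a separate collection so that
evaluation code can derive binding-site annotations from ligand proximity.
Multi-model files contribute model 1 only and only the first alternate
location of each disordered atom is kept, so the atom set is deterministic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from biotite.structure.io.pdb import PDBFile

from .errors import ChainNotFoundError, EmptyStructureError, PDBParseError

logger = logging.getLogger(__name__)

#: Radius assigned to elements missing from the radius table (Angstrom).
FALLBACK_RADIUS = 1.5

_WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


def default_radius_table() -> dict[str, float]:
    """Load the van der Waals radius table shipped with the package.

    Returns a mapping from upper-case element symbol to radius in Angstrom.
    """
    text = resources.files("voxpocket.data").joinpath("vdw_radii.json").read_text()
    raw = json.loads(text)
    return {k.upper(): float(v) for k, v in raw.items() if not k.startswith("_")}


@dataclass(frozen=True, eq=False)
class Atom:
    """A single atom with coordinates and a hard-sphere radius."""

    element: str
    position: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float
    residue_name: str
    residue_seq: int
    chain_id: str
    serial: int
    name: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")


@dataclass(frozen=True)
class Structure:
    """An ordered atom set from one PDB file, after chain selection.

    ``atoms`` holds the protein body (ATOM records); ``het_atoms`` holds the
    HETATM records of the same chains, kept for ligand-derived annotations.
    """

    atoms: tuple[Atom, ...]
    source_id: str
    selected_chains: frozenset[str] = frozenset()
    het_atoms: tuple[Atom, ...] = ()

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(f"{self.source_id}: no atoms after chain selection")
        if self.selected_chains:
            bad = {a.chain_id for a in self.atoms} - self.selected_chains
            if bad:
                raise ValueError(f"atoms outside selected chains: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of atom coordinates in file order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        """(N,) array of van der Waals radii in file order."""
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def residues(self) -> dict[tuple[str, int], list[Atom]]:
        """Group protein atoms by (chain_id, residue_seq), preserving order."""
        out: dict[tuple[str, int], list[Atom]] = {}
        for atom in self.atoms:
            out.setdefault((atom.chain_id, atom.residue_seq), []).append(atom)
        return out


def _element_of(element_field: str, atom_name: str) -> str:
    elem = element_field.strip().upper()
    if elem:
        return elem
    # Fall back to the leading letters of the atom-name field.
    letters = "".join(c for c in atom_name if c.isalpha())
    return letters[:2].upper() if len(letters) >= 2 else letters.upper()


def _atoms_from_array(arr, table: Mapping[str, float], start_serial: int = 1) -> list[Atom]:
    atoms: list[Atom] = []
    for i in range(arr.array_length()):
        elem = _element_of(str(arr.element[i]), str(arr.atom_name[i]))
        radius = table.get(elem)
        if radius is None:
            logger.warning("unknown element %r: using fallback radius %.2f A", elem, FALLBACK_RADIUS)
            radius = FALLBACK_RADIUS
        atoms.append(
            Atom(
                element=elem,
                position=np.array(arr.coord[i], dtype=float),
                vdw_radius=radius,
                residue_name=str(arr.res_name[i]),
                residue_seq=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                serial=int(arr.atom_id[i]) if "atom_id" in arr.get_annotation_categories() else start_serial + i,
                name=str(arr.atom_name[i]),
            )
        )
    return atoms


def parse_pdb(
    path: str | Path,
    chains: Iterable[str] | None = None,
    table: Mapping[str, float] | None = None,
) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path:
        PDB file with at least one ATOM record.
    chains:
        Optional chain ids to keep; ``None`` or empty keeps all chains.
        Requesting a chain with no ATOM records raises
        :class:`~voxpocket.errors.ChainNotFoundError`.
    table:
        Element -> radius mapping; defaults to the packaged table.

    Model 1 is used for multi-model files and only the first alternate
    location of each atom is retained.
    """
    path = Path(path)
    if table is None:
        table = default_radius_table()
    try:
        pdb_file = PDBFile.read(str(path))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arr = pdb_file.get_structure(model=1, altloc="first", extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises various error types
        raise PDBParseError(f"{path}: cannot parse PDB file: {exc}") from exc

    protein = arr[~arr.hetero]
    het = arr[arr.hetero]
    if protein.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM records")

    selection = frozenset(str(c) for c in chains) if chains else frozenset()
    if selection:
        present = {str(c) for c in np.unique(protein.chain_id)}
        missing = selection - present
        if missing:
            raise ChainNotFoundError(f"{path}: chain(s) not found: {sorted(missing)}")
        protein = protein[np.isin(protein.chain_id, sorted(selection))]
        het = het[np.isin(het.chain_id, sorted(selection))]

    return Structure(
        atoms=tuple(_atoms_from_array(protein, table)),
        source_id=path.name,
        selected_chains=selection,
        het_atoms=tuple(_atoms_from_array(het, table)),
    )


def assign_radii(structure: Structure, table: Mapping[str, float]) -> Structure:
    """Return a copy of ``structure`` with radii reassigned from ``table``.

    Unknown elements receive :data:`FALLBACK_RADIUS` (a warning is logged).
    """
    upper = {k.upper(): float(v) for k, v in table.items()}

    def reassign(atom: Atom) -> Atom:
        radius = upper.get(atom.element.upper())
        if radius is None:
            logger.warning(
                "unknown element %r: using fallback radius %.2f A", atom.element, FALLBACK_RADIUS
            )
            radius = FALLBACK_RADIUS
        return replace(atom, vdw_radius=radius)

    return Structure(
        atoms=tuple(reassign(a) for a in structure.atoms),
        source_id=structure.source_id,
        selected_chains=structure.selected_chains,
        het_atoms=tuple(reassign(a) for a in structure.het_atoms),
    )


def format_atom_record(
    atom: Atom, serial: int | None = None, b_factor: float = 0.0, record: str = "ATOM"
) -> str:
    """Format one fixed-width PDB ATOM/HETATM line (wwPDB columns)."""
    serial = atom.serial if serial is None else serial
    name = atom.name or atom.element
    # Standard alignment: element symbols of one letter start in column 14.
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    x, y, z = atom.position
    return (
        f"{record:<6s}{serial:>5d} {name:<4s} {atom.residue_name:>3s} "
        f"{atom.chain_id:1s}{atom.residue_seq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b_factor:6.2f}          "
        f"{atom.element:>2s}\n"
    )


def write_pdb(
    structure: Structure,
    path: str | Path,
    b_factors: Sequence[float] | None = None,
) -> None:
    """Write the structure back out as a PDB file.

    ``b_factors`` optionally overrides the B-factor column of the protein
    atoms (used for solid-angle visualisation exports).
    """
    lines: list[str] = []
    for i, atom in enumerate(structure.atoms):
        b = float(b_factors[i]) if b_factors is not None else 0.0
        lines.append(format_atom_record(atom, b_factor=b))
    for atom in structure.het_atoms:
        lines.append(format_atom_record(atom, record="HETATM"))
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def is_water(atom: Atom) -> bool:
    return atom.residue_name.upper() in _WATER_RESNAMES
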