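"""Protein structure I/O and the residue/element tables the geometry stages use.

Structures are read from fixed-width PDB files (wwPDB v3.3 ATOM/HETATM
records) via :mod:`gemmi` and held as a flat, ordered list of
:class:`AtomRecord`.  Only the first model is read; alternate locations are
resolved to the highest-occupancy conformer (ties broken by file order).
Coordinates stay in the file's frame — no re-centering happens at parse time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

from .errors import EmptyStructureError, ValidationError

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "read_structure",
    "write_structure",
    "residue_is_polar",
    "vdw_radius",
    "POLAR_RESIDUES",
    "STANDARD_RESIDUES",
    "VDW_RADII",
]

#: The 20 standard amino acids.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Residues counted as polar when scoring pocket lining composition:
#: charged (ARG, LYS, HIS, ASP, GLU), polar-uncharged (SER, THR, ASN, GLN),
#: plus TYR, CYS and TRP whose side chains carry hydrogen-bonding heteroatoms.
POLAR_RESIDUES = frozenset(
    "ARG LYS HIS ASP GLU SER THR ASN GLN TYR CYS TRP".split()
)

#: Bondi van der Waals radii (A) for the elements that occur in protein
#: structures and common ligands.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "FE": 1.52,
    "MG": 1.73,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
}

DEFAULT_VDW_RADIUS = 1.70

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

# PDB backbone atom names (used elsewhere for side-chain centroids).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record of a structure."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    x: float
    y: float
    z: float
    element: str
    occupancy: float = 1.0
    b_factor: float = 0.0
    hetatm: bool = False

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_seq)


@dataclass
class ProteinStructure:
    """An ordered collection of atom records with a structure id."""

    atoms: list[AtomRecord] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.id!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    def coords(self) -> np.ndarray:
        """(n, 3) array of atom coordinates in file order."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def residues(self) -> dict[tuple[str, int], list[AtomRecord]]:
        """Group atoms into residues keyed by (chain_id, residue_seq).

        Every atom belongs to exactly one residue, so the groups partition
        the atom list.
        """
        out: dict[tuple[str, int], list[AtomRecord]] = {}
        for atom in self.atoms:
            out.setdefault(atom.residue_key, []).append(atom)
        return out


def _infer_element(atom_name: str) -> str:
    """Guess an element symbol from a PDB atom name.

    Handles the common protein cases ("CA" -> C, "OG1" -> O, "1HB" -> H).
    Two-letter elements in HETATM groups should come from columns 77-78;
    this fallback only fires when those are blank.
    """
    name = atom_name.strip()
    # leading digits (e.g. 1HB) mean hydrogen naming
    while name and name[0].isdigit():
        name = name[1:]
    if not name:
        return ""
    return name[0].upper()


def residue_is_polar(residue_name: str, *, strict: bool = False) -> bool:
    """Whether a standard residue counts as polar for pocket composition.

    Parameters
    ----------
    residue_name:
        Three-letter residue code (case-insensitive).
    strict:
        If true, a non-standard residue raises :class:`ValidationError`;
        otherwise it warns and returns False.
    """
    name = residue_name.strip().upper()
    if name not in STANDARD_RESIDUES:
        if strict:
            raise ValidationError(f"non-standard residue name: {residue_name!r}")
        warnings.warn(
            f"non-standard residue {residue_name!r} treated as apolar",
            stacklevel=2,
        )
        return False
    return name in POLAR_RESIDUES


def vdw_radius(element: str, *, default: float = DEFAULT_VDW_RADIUS) -> float:
    """Bondi van der Waals radius in A; unknown elements warn and default."""
    key = element.strip().upper()
    radius = VDW_RADII.get(key)
    if radius is None:
        warnings.warn(
            f"unknown element {element!r}; using default radius {default} A",
            stacklevel=2,
        )
        return default
    return radius


def read_structure(
    path: str | Path,
    *,
    include_hetatm: bool = False,
    structure_id: str | None = None,
) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Only the first model is used.  HETATM records and waters are excluded
    unless ``include_hetatm`` is set (waters are always excluded).  Alternate
    locations are resolved to the highest-occupancy conformer, ties broken
    by the first record encountered.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi parse failure
        raise OSError(f"could not parse PDB file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    model = st[0]

    # altloc resolution: best record per (chain, seq, atom_name)
    best: dict[tuple[str, int, str], AtomRecord] = {}
    order: list[tuple[str, int, str]] = []
    for chain in model:
        for residue in chain:
            is_het = residue.het_flag == "H"
            if residue.name.strip().upper() in _WATER_NAMES:
                continue
            if is_het and not include_hetatm:
                continue
            for atom in residue:
                element = atom.element.name.upper() if not atom.element.is_metal else atom.element.name.upper()
                if not element or element == "X":
                    element = _infer_element(atom.name)
                key = (chain.name, residue.seqid.num, atom.name)
                rec = AtomRecord(
                    serial=atom.serial,
                    atom_name=atom.name,
                    residue_name=residue.name,
                    chain_id=chain.name,
                    residue_seq=residue.seqid.num,
                    x=atom.pos.x,
                    y=atom.pos.y,
                    z=atom.pos.z,
                    element=element,
                    occupancy=atom.occ,
                    b_factor=atom.b_iso,
                    hetatm=is_het,
                )
                if key not in best:
                    best[key] = rec
                    order.append(key)
                elif rec.occupancy > best[key].occupancy:
                    best[key] = rec
    atoms = [best[k] for k in order]
    if not atoms:
        raise EmptyStructureError(f"{path} contains no ATOM records after filtering")
    return ProteinStructure(atoms=atoms, id=structure_id or path.stem)


def write_structure(structure: ProteinStructure, path: str | Path) -> None:
    """Write a structure back to fixed-width PDB via gemmi."""
    st = gemmi.Structure()
    st.name = structure.id or "pocketscreen"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    current: dict[str, tuple[int, gemmi.Residue] | None] = {}
    for rec in structure.atoms:
        chain = chains.get(rec.chain_id)
        if chain is None:
            chain = gemmi.Chain(rec.chain_id)
            chains[rec.chain_id] = chain
            model.add_chain(chain)
            chain = model[rec.chain_id]
            chains[rec.chain_id] = chain
            current[rec.chain_id] = None
        res_state = current[rec.chain_id]
        if res_state is None or res_state[0] != rec.residue_seq:
            residue = gemmi.Residue()
            residue.name = rec.residue_name
            residue.seqid = gemmi.SeqId(rec.residue_seq, " ")
            residue.het_flag = "H" if rec.hetatm else "A"
            chain.add_residue(residue)
            residue = chain[len(chain) - 1]
            current[rec.chain_id] = (rec.residue_seq, residue)
        residue = current[rec.chain_id][1]
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.serial = rec.serial
        atom.pos = gemmi.Position(rec.x, rec.y, rec.z)
        atom.occ = rec.occupancy
        atom.b_iso = rec.b_factor
        atom.element = gemmi.Element(rec.element)
        residue.add_atom(atom)
    st.add_model(model)
    st.write_pdb(str(path))


def structure_from_arrays(
    coords: np.ndarray,
    elements: Iterable[str],
    residue_names: Iterable[str],
    *,
    chain_id: str = "A",
    structure_id: str = "synthetic",
) -> ProteinStructure:
    """Build a one-atom-per-residue structure from raw arrays.

    Convenience constructor used by the synthetic-fixture generators; atom
    *i* becomes residue ``(chain_id, i + 1)``.
    """
    coords = np.asarray(coords, dtype=float)
    atoms = []
    for i, (xyz, element, resname) in enumerate(
        zip(coords, elements, residue_names, strict=True)
    ):
        atoms.append(
            AtomRecord(
                serial=i + 1,
                atom_name=element.upper()[:2],
                residue_name=resname,
                chain_id=chain_id,
                residue_seq=i + 1,
                x=float(xyz[0]),
                y=float(xyz[1]),
                z=float(xyz[2]),
                element=element.upper(),
            )
        )
    return ProteinStructure(atoms=atoms, id=structure_id)
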