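"""Protein structure input and per-atom solvent accessibility.

Structures are read from PDB files into a flat, typed atom model holding
only the heavy atoms of the 20 standard amino acids (first model, altlocs
resolved by occupancy).  Solvent-accessible surface area (SASA) is computed
with the Shrake-Rupley sphere-sampling algorithm as implemented in biotite,
with element-wise van-der-Waals radii and a 1.4 A water probe.  Downstream
surface definitions are percentile-based and therefore robust to the exact
radius table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, NamedTuple

import gemmi
import numpy as np
import biotite.structure as _bst

__all__ = [
    "AtomRecord",
    "AtomType",
    "StructureModel",
    "EmptyStructureError",
    "DegenerateGeometryError",
    "STANDARD_RESIDUES",
    "read_pdb",
    "write_pdb",
    "compute_sasa",
]

#: Three-letter codes of the 20 standard amino acids; everything else is
#: discarded at parse time.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class EmptyStructureError(ValueError):
    """Raised when a file yields no standard amino-acid heavy atoms."""


class DegenerateGeometryError(ValueError):
    """Raised when two atoms share identical coordinates."""


class AtomType(NamedTuple):
    """Chemical context of an atom: residue and PDB atom name.

    The pair uniquely identifies a chemical type, e.g. alanine C-beta is
    ``AtomType("ALA", "CB")`` and is distinct from valine C-beta.
    """

    residue_name: str
    atom_name: str

    def __str__(self) -> str:  # used in serialized tables
        return f"{self.residue_name}:{self.atom_name}"

    @classmethod
    def parse(cls, text: str) -> "AtomType":
        res, _, name = text.partition(":")
        return cls(res, name)


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a standard residue.

    ``insertion_code`` participates in residue identity so that inserted
    residues never collide with their neighbours.
    """

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0
    insertion_code: str = ""

    @property
    def atom_type(self) -> AtomType:
        return AtomType(self.residue_name, self.atom_name)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclasses.dataclass
class StructureModel:
    """An ordered collection of atoms from a single structure/domain."""

    identifier: str
    atoms: list[AtomRecord]

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in file order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, identifier: str | None = None) -> "StructureModel":
        """Copy with replaced coordinates (e.g. after a rigid transform)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            dataclasses.replace(a, coords=tuple(float(x) for x in c))
            for a, c in zip(self.atoms, coords)
        ]
        return StructureModel(identifier or self.identifier, atoms)


# SasaAnnotation is simply a float array aligned 1:1 with StructureModel.atoms;
# a dedicated wrapper type would add nothing over the ndarray contract.
SasaAnnotation = np.ndarray


def read_pdb(path: str | Path) -> StructureModel:
    """Read the first model of a PDB file into a :class:`StructureModel`.

    Keeps heavy atoms of the 20 standard residues only; hydrogens, waters
    and hetero-compounds are dropped.  Alternate locations are resolved to
    the highest-occupancy conformer (ties: first in file).

    Raises
    ------
    EmptyStructureError
        If no standard amino-acid heavy atom survives filtering.
    """
    path = Path(path)
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = structure[0]

    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            if residue.name not in STANDARD_RESIDUES:
                continue
            if residue.het_flag == "H":  # HETATM records (e.g. MSE kept out by name filter anyway)
                continue
            # altloc resolution: highest occupancy wins, first-in-file on ties
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ + 1e-12:
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        altloc=atom.altloc if atom.altloc != "\x00" else "",
                        occupancy=atom.occ,
                        insertion_code=(residue.seqid.icode or "").strip(),
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"{path}: no standard amino-acid ATOM records")
    return StructureModel(path.stem, atoms)


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a minimal standard-conforming PDB file (ATOM records only)."""
    path = Path(path)
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        name = a.atom_name
        # PDB v3.3 alignment: 1-3 char names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = a.coords
        lines.append(
            f"ATOM  {i:5d} {name_field}{'':1s}{a.residue_name:>3s} {a.chain_id:1s}"
            f"{a.residue_number:4d}{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _to_atom_array(structure: StructureModel) -> _bst.AtomArray:
    n = len(structure.atoms)
    arr = _bst.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id = np.array([a.chain_id for a in structure.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_number for a in structure.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in structure.atoms], dtype="U5")
    arr.atom_name = np.array([a.atom_name for a in structure.atoms], dtype="U6")
    arr.element = np.array([a.element for a in structure.atoms], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def compute_sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> SasaAnnotation:
    """Per-atom solvent-accessible surface area in A^2 (Shrake-Rupley).

    Deterministic for a fixed ``n_sphere_points`` (Fibonacci point
    distribution); element-wise van-der-Waals radii.

    Raises
    ------
    DegenerateGeometryError
        If two atoms sit on identical coordinates.
    """
    if len(structure) == 0:
        raise EmptyStructureError("cannot compute SASA of an empty structure")
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_sphere_points < 100:
        raise ValueError("n_sphere_points must be >= 100")

    coords = structure.coords
    # identical coordinates break sphere occlusion logic
    rounded = np.round(coords, 6)
    uniq = np.unique(rounded, axis=0)
    if uniq.shape[0] != coords.shape[0]:
        raise DegenerateGeometryError("two atoms share identical coordinates")

    arr = _to_atom_array(structure)
    sasa = _bst.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=n_sphere_points,
        vdw_radii="Single",
    )
    sasa = np.asarray(sasa, dtype=float)
    if np.any(np.isnan(sasa)):
        raise ValueError("SASA undefined for some atom (unknown element radius)")
    return np.maximum(sasa, 0.0)
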