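"""Surface-atom selection and patch extraction.

An atom of type t (residue + atom name, e.g. ALA:CB) is a *surface* atom
when its SASA is at least ``alpha * access_surf_t``, where ``access_surf_t``
is the 99th percentile of the SASA distribution of type t over a training
corpus and ``alpha`` defaults to 0.9.  A *patch* is the set of surface atoms
within a fixed radius (default 7 A) of a solvent-exposed beta-carbon pivot,
pivot included.  Patches overlap and jointly cover the protein surface.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, AtomType, SasaAnnotation, StructureModel

__all__ = [
    "SurfaceThresholdTable",
    "Patch",
    "fit_thresholds",
    "select_surface_atoms",
    "extract_patches",
    "compute_inner_sphere",
    "radius_of_gyration",
    "build_patch",
]

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILE = 99.0
DEFAULT_ALPHA = 0.9
DEFAULT_RADIUS = 7.0
INNER_MIN, INNER_MAX = 4, 9
INNER_SCAN_STEP = 0.25


@dataclasses.dataclass
class SurfaceThresholdTable:
    """Per-atom-type surface-area thresholds (``access_surf_t``)."""

    thresholds: dict[AtomType, float]
    alpha: float = DEFAULT_ALPHA
    percentile: float = DEFAULT_PERCENTILE
    corpus_size: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if any(v < 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be non-negative")

    def cutoff(self, atom_type: AtomType) -> float | None:
        """alpha-scaled surface cutoff for a type, or None if unobserved."""
        t = self.thresholds.get(atom_type)
        return None if t is None else self.alpha * t


@dataclasses.dataclass
class Patch:
    """A pivot beta-carbon plus the surface atoms within ``radius`` of it."""

    source_id: str
    pivot: AtomRecord
    atoms: list[AtomRecord]
    radius: float
    composition: dict[AtomType, int]
    rg: float
    inner_indices: list[int]
    inner_radius: float
    small: bool = False  # fewer than INNER_MIN atoms in the whole patch

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def types(self) -> list[AtomType]:
        return [a.atom_type for a in self.atoms]

    @property
    def inner_atoms(self) -> list[AtomRecord]:
        return [self.atoms[i] for i in self.inner_indices]

    @property
    def patch_id(self) -> str:
        p = self.pivot
        return f"{self.source_id}/{p.chain_id}{p.residue_number}{p.insertion_code}"

    def with_coords(self, coords: np.ndarray) -> "Patch":
        """Copy with replaced atom coordinates (rigid-transform support)."""
        coords = np.asarray(coords, dtype=float)
        atoms = [
            dataclasses.replace(a, coords=tuple(float(x) for x in c))
            for a, c in zip(self.atoms, coords)
        ]
        pivot_pos = list(self.atoms).index(self.pivot)
        patch = dataclasses.replace(self, atoms=atoms, pivot=atoms[pivot_pos])
        patch.rg = radius_of_gyration(atoms)
        return patch


def radius_of_gyration(atoms: Sequence[AtomRecord] | np.ndarray) -> float:
    """Unweighted rg: RMS distance of the atoms from their centroid."""
    if isinstance(atoms, np.ndarray):
        coords = np.asarray(atoms, dtype=float)
    else:
        coords = np.array([a.coords for a in atoms], dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("radius of gyration of an empty set")
    centroid = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))


def fit_thresholds(
    corpus: Iterable[tuple[StructureModel, SasaAnnotation]],
    percentile: float = DEFAULT_PERCENTILE,
    alpha: float = DEFAULT_ALPHA,
) -> SurfaceThresholdTable:
    """Fit ``access_surf_t`` as a SASA percentile per atom type over a corpus.

    The percentile uses the sorted-values linear-interpolation convention
    (numpy's default); a type observed once gets its single value.
    """
    pooled: dict[AtomType, list[float]] = {}
    n_structures = 0
    for structure, sasa in corpus:
        sasa = np.asarray(sasa, dtype=float)
        if len(sasa) != len(structure):
            raise ValueError("SASA annotation does not align with structure")
        n_structures += 1
        for atom, area in zip(structure.atoms, sasa):
            pooled.setdefault(atom.atom_type, []).append(float(area))
    if n_structures == 0:
        raise ValueError("empty corpus")
    thresholds = {
        t: float(np.percentile(np.asarray(v), percentile)) for t, v in pooled.items()
    }
    return SurfaceThresholdTable(
        thresholds=thresholds,
        alpha=alpha,
        percentile=percentile,
        corpus_size=n_structures,
    )


def select_surface_atoms(
    structure: StructureModel,
    sasa: SasaAnnotation,
    table: SurfaceThresholdTable,
) -> set[int]:
    """Indices of atoms with SASA >= alpha * access_surf_t (inclusive).

    Atom types not present in the threshold table are never surface;
    each unseen type is logged once per call.
    """
    sasa = np.asarray(sasa, dtype=float)
    if len(sasa) != len(structure):
        raise ValueError("SASA annotation does not align with structure")
    surface: set[int] = set()
    unseen: set[AtomType] = set()
    for i, atom in enumerate(structure.atoms):
        cutoff = table.cutoff(atom.atom_type)
        if cutoff is None:
            unseen.add(atom.atom_type)
            continue
        if sasa[i] >= cutoff - 1e-12:
            surface.add(i)
    for t in sorted(unseen):
        logger.warning("atom type %s absent from threshold table; never surface", t)
    return surface


def build_patch(
    source_id: str,
    pivot: AtomRecord,
    atoms: Sequence[AtomRecord],
    radius: float = DEFAULT_RADIUS,
) -> Patch:
    """Assemble a Patch from its atoms: composition, rg and inner sphere."""
    atoms = list(atoms)
    if pivot not in atoms:
        raise ValueError("pivot must be among the patch atoms")
    composition = dict(Counter(a.atom_type for a in atoms))
    patch = Patch(
        source_id=source_id,
        pivot=pivot,
        atoms=atoms,
        radius=radius,
        composition=composition,
        rg=radius_of_gyration(atoms),
        inner_indices=[],
        inner_radius=radius,
    )
    return compute_inner_sphere(patch)


def compute_inner_sphere(patch: Patch) -> Patch:
    """Fix the pivot-centred inner sphere to hold 4-9 atoms.

    Scans the sphere radius downward from the patch radius in 0.25 A steps
    and stops at the first radius whose atom count falls in [4, 9].  If two
    shells are so close that the count jumps from above 9 to below 4 in one
    step, the 9 atoms nearest the pivot are used instead.  Patches with
    fewer than 4 atoms are their own inner sphere and flagged ``small``.
    """
    if len(patch.atoms) == 0:
        raise ValueError("patch has no atoms")
    coords = patch.coords
    d = np.linalg.norm(coords - patch.pivot.xyz, axis=1)
    n = len(patch.atoms)

    if n < INNER_MIN:
        patch.inner_indices = list(range(n))
        patch.inner_radius = patch.radius
        patch.small = True
        return patch

    r = patch.radius
    chosen: list[int] | None = None
    while r > 0:
        inside = np.nonzero(d <= r + 1e-9)[0]
        if len(inside) <= INNER_MAX:
            if len(inside) >= INNER_MIN:
                chosen = list(inside)
                patch.inner_radius = r
            break
        r -= INNER_SCAN_STEP
    if chosen is None:
        # count jumped past [4, 9]: take the 9 nearest atoms (stable order)
        order = np.argsort(d, kind="stable")[:INNER_MAX]
        chosen = sorted(int(i) for i in order)
        patch.inner_radius = float(d[order].max())
    patch.inner_indices = chosen
    patch.small = False
    return patch


def extract_patches(
    structure: StructureModel,
    surface: set[int],
    radius: float = DEFAULT_RADIUS,
) -> list[Patch]:
    """One patch per solvent-exposed CB pivot.

    Each patch holds exactly the surface atoms within ``radius`` of the
    pivot (Euclidean, inclusive) plus the pivot itself.  Deterministic and
    independent of atom input order (patches sorted by pivot residue).
    """
    if not surface:
        return []
    surface_idx = sorted(surface)
    for i in surface_idx:
        if not 0 <= i < len(structure):
            raise IndexError(f"surface index {i} out of range")
    surf_atoms = [structure.atoms[i] for i in surface_idx]
    surf_coords = np.array([a.coords for a in surf_atoms], dtype=float)
    tree = cKDTree(surf_coords)

    pivots = [
        (j, a) for j, a in enumerate(surf_atoms) if a.atom_name == "CB"
    ]
    # order-independence: sort pivots by residue identity
    pivots.sort(key=lambda ja: (ja[1].chain_id, ja[1].residue_number, ja[1].insertion_code))

    patches: list[Patch] = []
    for j, pivot in pivots:
        near = tree.query_ball_point(surf_coords[j], r=radius + 1e-9)
        atoms = sorted(
            (surf_atoms[i] for i in near),
            key=lambda a: (a.chain_id, a.residue_number, a.insertion_code, a.atom_name),
        )
        patches.append(build_patch(structure.identifier, pivot, atoms, radius=radius))
    return patches
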