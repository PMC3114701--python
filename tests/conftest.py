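"""Shared fixtures: tiny PDB files, synthetic corpora, and the
session-scoped demonstration library (expensive to build)."""

from __future__ import annotations

import numpy as np
import pytest

from surfpatch.evaluation import DemoLibrary, build_demo_library
from surfpatch.structure_io import AtomRecord, StructureModel
from surfpatch.synthetic_fixtures import FixtureSpec, make_structure

ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
END
"""

HETATM_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
HETATM    3  C1  LIG A   3       6.000   0.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB AALA A   1       1.988  -0.773  -1.199  0.60  0.00           C
ATOM      6  CB BALA A   1       2.100  -0.800  -1.300  0.40  0.00           C
END
"""


@pytest.fixture
def ala_pdb(tmp_path):
    path = tmp_path / "ala.pdb"
    path.write_text(ALA_PDB)
    return path


@pytest.fixture
def hetatm_only_pdb(tmp_path):
    path = tmp_path / "het.pdb"
    path.write_text(HETATM_ONLY_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture
def helix():
    return make_structure(FixtureSpec(rng_seed=0, n_residues=12, geometry="helix"))


@pytest.fixture(scope="session")
def demo() -> DemoLibrary:
    """Library built from 20 native-like synthetic structures (k = 12)."""
    return build_demo_library(rng_seed=1)


def make_atom(
    name: str = "CA",
    res: str = "ALA",
    xyz: tuple[float, float, float] = (0.0, 0.0, 0.0),
    num: int = 1,
    element: str | None = None,
) -> AtomRecord:
    return AtomRecord(
        chain_id="A",
        residue_number=num,
        residue_name=res,
        atom_name=name,
        element=element or name[0],
        coords=xyz,
    )


def grid_structure(coords: np.ndarray, name: str = "CA", res: str = "ALA") -> StructureModel:
    """One-type structure from a raw coordinate array (test scaffolding)."""
    atoms = [
        make_atom(name=name, res=res, xyz=tuple(float(x) for x in c), num=i + 1)
        for i, c in enumerate(np.asarray(coords, dtype=float))
    ]
    return StructureModel("grid", atoms)
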