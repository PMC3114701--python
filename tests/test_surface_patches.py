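"""Surface thresholds, surface-atom selection and patch extraction."""

import random

import numpy as np
import pytest

from surfpatch.structure_io import AtomType, StructureModel, compute_sasa
from surfpatch.surface_patches import (
    Patch,
    SurfaceThresholdTable,
    build_patch,
    compute_inner_sphere,
    extract_patches,
    fit_thresholds,
    radius_of_gyration,
    select_surface_atoms,
)
from surfpatch.synthetic_fixtures import FixtureSpec, make_structure

from conftest import grid_structure, make_atom

CA_ALA = AtomType("ALA", "CA")


def corpus_of(values):
    """A one-type corpus whose pooled SASA values are exactly ``values``."""
    coords = np.column_stack(
        [np.arange(len(values)) * 5.0, np.zeros(len(values)), np.zeros(len(values))]
    )
    return [(grid_structure(coords), np.asarray(values, dtype=float))]


class TestFitThresholds:
    def test_percentile_linear_interpolation(self):
        table = fit_thresholds(corpus_of(np.arange(101)))
        assert table.thresholds[CA_ALA] == pytest.approx(99.0)

    def test_single_observation_is_its_own_threshold(self):
        table = fit_thresholds(corpus_of([7.25]))
        assert table.thresholds[CA_ALA] == pytest.approx(7.25)

    def test_all_zero_type_has_zero_threshold_and_is_surface(self):
        structure, sasa = corpus_of([0.0, 0.0, 0.0])[0]
        table = fit_thresholds([(structure, sasa)])
        assert table.thresholds[CA_ALA] == 0.0
        surface = select_surface_atoms(structure, sasa, table)
        assert surface == {0, 1, 2}

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_thresholds([])


class TestSelectSurfaceAtoms:
    def table(self, threshold=10.0):
        return SurfaceThresholdTable({CA_ALA: threshold}, alpha=0.9)

    def test_boundary_is_inclusive(self):
        structure, _ = corpus_of([0.0])[0]
        surface = select_surface_atoms(structure, np.array([9.0]), self.table())
        assert surface == {0}  # 9.0 == 0.9 * 10.0 exactly

    def test_below_boundary_excluded(self):
        structure, _ = corpus_of([0.0])[0]
        assert select_surface_atoms(structure, np.array([0.0]), self.table()) == set()

    def test_unknown_type_never_surface(self):
        structure = StructureModel("x", [make_atom(name="CB", res="SER")])
        table = self.table()
        assert select_surface_atoms(structure, np.array([99.0]), table) == set()

    def test_rigid_rotation_preserves_surface_set(self):
        from scipy.spatial.transform import Rotation

        structure = make_structure(FixtureSpec(rng_seed=3, n_residues=10))
        annotated = [(structure, compute_sasa(structure))]
        table = fit_thresholds(annotated, percentile=50, alpha=0.9)
        surface = select_surface_atoms(structure, annotated[0][1], table)

        R = Rotation.from_euler("zyx", [1.0, 0.4, -0.7]).as_matrix()
        moved = structure.with_coords(structure.coords @ R.T + 7.0)
        surface_moved = select_surface_atoms(moved, compute_sasa(moved), table)
        # quadrature jitter may flip atoms sitting exactly at the cutoff
        assert len(surface ^ surface_moved) <= max(2, len(surface) // 20)


class TestExtractPatches:
    def planted_structure(self):
        """Pivot CB + 10 atoms inside 7 A + 3 outside, all same residue."""
        rng = np.random.default_rng(5)
        inside = rng.uniform(-3.9, 3.9, (10, 3))  # max norm < 7
        outside = np.array([[8.0, 0, 0], [0, 9.0, 0], [0, 0, 10.0]])
        atoms = [make_atom(name="CB", res="ALA", xyz=(0, 0, 0), num=1)]
        for i, c in enumerate(np.vstack([inside, outside])):
            atoms.append(
                make_atom(name="CA", res="ALA", xyz=tuple(map(float, c)), num=i + 2)
            )
        return StructureModel("planted", atoms)

    def test_patch_membership_matches_brute_force(self):
        structure = self.planted_structure()
        surface = set(range(len(structure)))
        patches = extract_patches(structure, surface, radius=7.0)
        assert len(patches) == 1
        patch = patches[0]
        assert len(patch) == 11
        pivot_xyz = np.asarray(structure.atoms[0].coords)
        for atom in patch.atoms:
            assert np.linalg.norm(atom.xyz - pivot_xyz) <= 7.0 + 1e-9

    def test_glycine_only_structure_has_no_pivots(self):
        structure = make_structure(
            FixtureSpec(rng_seed=1, n_residues=8, composition_palette=("GLY",))
        )
        patches = extract_patches(structure, set(range(len(structure))))
        assert patches == []

    def test_composition_counts_sum_to_patch_size(self):
        structure = self.planted_structure()
        (patch,) = extract_patches(structure, set(range(len(structure))))
        assert sum(patch.composition.values()) == len(patch)

    def test_atom_input_order_is_irrelevant(self):
        structure = self.planted_structure()
        shuffled_atoms = list(structure.atoms)
        random.Random(0).shuffle(shuffled_atoms)
        shuffled = StructureModel("planted", shuffled_atoms)
        (p1,) = extract_patches(structure, set(range(len(structure))))
        (p2,) = extract_patches(shuffled, set(range(len(shuffled))))
        key = lambda a: (a.residue_number, a.atom_name)
        assert sorted(p1.atoms, key=key) == sorted(p2.atoms, key=key)

    def test_every_covered_surface_atom_appears_in_some_patch(self):
        structure = make_structure(FixtureSpec(rng_seed=9, n_residues=14))
        surface = set(range(len(structure)))
        patches = extract_patches(structure, surface, radius=7.0)
        pivots = [p.pivot.xyz for p in patches]
        in_patches = {
            (a.residue_number, a.atom_name) for p in patches for a in p.atoms
        }
        for i in surface:
            atom = structure.atoms[i]
            if any(np.linalg.norm(atom.xyz - pv) <= 7.0 for pv in pivots):
                assert (atom.residue_number, atom.atom_name) in in_patches

    def test_mean_patch_size_on_demo_corpus_is_realistic(self, demo):
        base = demo.bases[0]
        sasa = compute_sasa(base)
        surface = select_surface_atoms(base, sasa, demo.thresholds)
        patches = extract_patches(base, surface)
        mean_size = np.mean([len(p) for p in patches])
        assert 10 <= mean_size <= 45


class TestInnerSphere:
    def patch_with(self, coords):
        atoms = [make_atom(name="CB", res="ALA", xyz=(0, 0, 0), num=1)]
        for i, c in enumerate(coords):
            atoms.append(make_atom(name="CA", res="ALA", xyz=tuple(c), num=i + 2))
        return build_patch("t", atoms[0], atoms, radius=7.0)

    def test_small_cluster_is_its_own_inner_sphere(self):
        patch = self.patch_with([(1.5, 0, 0), (0, 1.6, 0), (0, 0, 1.7), (1.1, 1.1, 0), (2.0, 0.5, 0.5)])
        assert len(patch.inner_indices) == 6
        assert not patch.small

    def test_large_patch_inner_count_in_range(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(-4.0, 4.0, (24, 3))
        patch = self.patch_with([tuple(c) for c in coords])
        assert 4 <= len(patch.inner_indices) <= 9

    def test_tiny_patch_flagged_small(self):
        patch = self.patch_with([(2.0, 0, 0), (0, 2.0, 0)])
        assert patch.small
        assert len(patch.inner_indices) == 3


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration([make_atom()]) == 0.0

    def test_two_atoms_two_angstrom_apart(self):
        atoms = [make_atom(xyz=(0, 0, 0)), make_atom(xyz=(2.0, 0, 0), num=2)]
        assert radius_of_gyration(atoms) == pytest.approx(1.0)

    def test_rotation_invariant(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(0)
        coords = rng.normal(size=(12, 3)) * 3.0
        R = Rotation.from_euler("xyz", [0.5, 1.0, -0.3]).as_matrix()
        assert radius_of_gyration(coords) == pytest.approx(
            radius_of_gyration(coords @ R.T + 4.0), abs=1e-9
        )
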