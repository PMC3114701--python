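"""Compatibility screens, Kabsch superposition, exact and heuristic
patch distances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from surfpatch.structure_io import AtomType
from surfpatch.surface_patches import build_patch
from surfpatch.patch_distance import (
    compatible,
    exact_distance,
    heuristic_distance,
    kabsch_superpose,
    pairwise_distances,
)
from surfpatch.synthetic_fixtures import (
    PLANTED_TYPE_POOL,
    make_patch_pair,
    make_planted_patches,
)

from conftest import make_atom


def patch_of(coords, types=None, res="ALA", name="CB"):
    """Patch from raw coordinates; first atom is the pivot."""
    coords = np.asarray(coords, dtype=float)
    atoms = []
    for i, c in enumerate(coords):
        if types is not None:
            r, n = types[i]
        else:
            r, n = res, name
        atoms.append(make_atom(name=n, res=r, xyz=tuple(map(float, c)), num=i + 1))
    return build_patch("t", atoms[0], atoms, radius=7.0)


class TestCompatible:
    def test_identical_patch_is_self_compatible(self):
        a, _ = make_patch_pair(0, noise=0.0)
        assert compatible(a, a)

    def test_rg_gap_beyond_phi3_rejected(self):
        # collinear spreads scaled to rg = 2 and rg = 8, same composition
        base = np.linspace(-1.0, 1.0, 6)
        rg0 = math.sqrt(np.mean(base**2))
        a = patch_of([[x * 2.0 / rg0, 0, 0] for x in base])
        b = patch_of([[x * 8.0 / rg0, 0, 0] for x in base])
        assert a.rg == pytest.approx(2.0) and b.rg == pytest.approx(8.0)
        assert not compatible(a, b)

    def test_size_ratio_just_over_phi1_rejected(self):
        a = patch_of([[2.0 * i, 0, 0] for i in range(10)])
        b = patch_of([[2.0 * i, 0, 0] for i in range(13)])
        # |10-13| / 13 = 0.231 > 0.2
        assert not compatible(a, b)

    def test_disjoint_composition_rejected(self):
        a, _ = make_patch_pair(1, noise=0.0, type_pool=PLANTED_TYPE_POOL[:4])
        b, _ = make_patch_pair(2, noise=0.0, type_pool=PLANTED_TYPE_POOL[4:])
        assert not compatible(a, b)


class TestKabsch:
    def test_identical_sets_superpose_exactly(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        rmsd, tf = kabsch_superpose(pts, pts)
        assert rmsd < 1e-12
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rigid_copies_superpose_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3)) * 4.0
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(axis * rng.uniform(0, math.pi)).as_matrix()
        moved = pts @ R.T + rng.uniform(-10, 10, 3)
        rmsd, tf = kabsch_superpose(pts, moved)
        assert rmsd < 1e-9
        assert np.allclose(tf.apply(moved), pts, atol=1e-8)

    def test_two_point_worked_case(self):
        rmsd, _ = kabsch_superpose(
            np.array([[0.0, 0, 0], [1.0, 0, 0]]), np.array([[0.0, 0, 0], [3.0, 0, 0]])
        )
        assert rmsd == pytest.approx(1.0, abs=1e-12)

    def test_proper_rotation_only(self):
        # a mirrored tetrahedron must NOT superpose to zero
        pts = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]], dtype=float)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        rmsd, tf = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1


class TestExactDistance:
    def test_self_distance_zero(self):
        a, _ = make_patch_pair(3, noise=0.2)
        assert exact_distance(a, a).value < 1e-6

    def test_incompatible_pair_is_infinite(self):
        a, _ = make_patch_pair(1, noise=0.0, type_pool=PLANTED_TYPE_POOL[:4])
        b, _ = make_patch_pair(2, noise=0.0, type_pool=PLANTED_TYPE_POOL[4:])
        assert exact_distance(a, b).is_infinite

    def test_permuted_rigid_copy_recovered(self):
        # 3 same-type atoms in permuted order under a rigid motion
        pts = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 4.0, 0]])
        R = Rotation.from_euler("xyz", [0.4, -0.2, 1.3]).as_matrix()
        permuted = pts[[2, 0, 1]] @ R.T + np.array([1.0, 2.0, 3.0])
        a = patch_of(pts)
        b = patch_of(permuted)
        result = exact_distance(a, b)
        assert result.value < 1e-9
        assert len(result.mapping) == 3

    def test_oracle_guard_refuses_large_patches(self):
        rng = np.random.default_rng(0)
        big = patch_of(np.vstack([[0, 0, 0], rng.uniform(-4, 4, (11, 3))]))
        with pytest.raises(ValueError):
            exact_distance(big, big)


class TestHeuristicDistance:
    def test_self_distance_zero_with_identity_mapping(self):
        a, _ = make_patch_pair(4, noise=0.3)
        result = heuristic_distance(a, a)
        assert result.value < 1e-6
        assert all(i == j for i, j in result.mapping.pairs)

    def test_no_seed_below_two_angstrom_means_infinite(self):
        # same composition, rg within phi3, but every mapping above 2 A RMSD:
        # a compact cluster against a 2.2x scaled copy of itself
        rng = np.random.default_rng(42)
        pts = np.vstack([[0.0, 0.0, 0.0], rng.uniform(-2.2, 2.2, (5, 3))])
        a = patch_of(pts)
        b = patch_of(pts * 2.2)
        assert compatible(a, b)
        assert exact_distance(a, b).value > 2.0  # no sub-2 A superposition exists
        assert heuristic_distance(a, b).is_infinite

    def test_heuristic_never_undercuts_exact(self):
        for i in range(40):
            a, b = make_patch_pair(7000 + i, noise=(0.1, 0.3, 0.5)[i % 3])
            ex = exact_distance(a, b).value
            he = heuristic_distance(a, b).value
            if math.isfinite(ex) and math.isfinite(he):
                assert he >= ex - 1e-6

    def test_rigid_motion_of_one_patch_changes_nothing(self):
        a, b = make_patch_pair(11, noise=0.3)
        d0 = heuristic_distance(a, b).value
        R = Rotation.from_euler("zxz", [0.7, 0.2, -1.9]).as_matrix()
        b_moved = b.with_coords(b.coords @ R.T + np.array([4.0, -6.0, 2.0]))
        d1 = heuristic_distance(a, b_moved).value
        assert d1 == pytest.approx(d0, abs=1e-6)


class TestPairwiseDistances:
    def test_identical_pair_gives_zero_matrix(self):
        a, _ = make_patch_pair(5, noise=0.0)
        m = pairwise_distances([a, a])
        assert np.allclose(m, 0.0, atol=1e-6)

    def test_matrix_is_symmetric_with_zero_diagonal(self):
        patches, _ = make_planted_patches(2, 4, 0.2, rng_seed=6)
        m = pairwise_distances(patches)
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 0.0)

    def test_composition_disjoint_outsider_is_infinitely_far(self):
        patches, _ = make_planted_patches(
            2, 3, 0.1, rng_seed=8, type_pool=PLANTED_TYPE_POOL[:5]
        )
        outsider, _ = make_patch_pair(9, noise=0.0, type_pool=PLANTED_TYPE_POOL[5:])
        m = pairwise_distances(patches + [outsider])
        assert np.all(np.isinf(m[-1, :-1]))
        assert np.isfinite(m[0, 1])  # in-group distances stay finite

    def test_requires_two_patches(self):
        a, _ = make_patch_pair(10, noise=0.0)
        with pytest.raises(ValueError):
            pairwise_distances([a])
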