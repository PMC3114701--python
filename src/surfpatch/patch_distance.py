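"""Chemically-constrained minimum-RMSD distance between surface patches.

Two patches are first screened for *compatibility*: their sizes, chemical
compositions and radii of gyration must agree within thresholds
(phi1 = phi2 = 0.2 relative, phi3 = 5 A absolute).  Incompatible patches
are infinitely distant.  For compatible patches the distance is the
minimum RMSD over *proper mappings* -- one-to-one, type-preserving
correspondences between the atoms -- after optimal rigid superposition.

Exact minimisation enumerates every maximal proper mapping and is
factorial per atom type; it is exposed as a small-patch oracle.  The
production path is a seeded heuristic: all proper mappings between the two
pivot-centred inner spheres (4-9 atoms each) are enumerated, superpositions
with RMSD below 2 A seed a transform, the full patches are matched greedily
by proximity within each seed's frame, and the best re-superposed RMSD over
all seeds is returned.  No seed below 2 A means infinite distance.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import AtomType
from .surface_patches import Patch

__all__ = [
    "RigidTransform",
    "ProperMapping",
    "PatchDistanceResult",
    "compatible",
    "kabsch_superpose",
    "exact_distance",
    "heuristic_distance",
    "pairwise_distances",
]

PHI1 = 0.2  # max relative size difference
PHI2 = 0.2  # max relative chemical-composition difference
PHI3 = 5.0  # max |rg(A) - rg(B)| in Angstrom
SEED_RMSD_MAX = 2.0
MATCH_CUTOFF = 3.0
MIN_MATCH_FRAC = 0.5
MAX_SEED_MAPPINGS = 4096  # enumeration cap for inner-sphere mappings
MAX_SEEDS = 32  # best seeds (by inner RMSD) carried to full-patch matching
ORACLE_MAX_ATOMS = 8


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping B-frame points into A's frame."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclasses.dataclass(frozen=True)
class ProperMapping:
    """Type-preserving one-to-one pairs (index in A, index in B)."""

    pairs: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclasses.dataclass
class PatchDistanceResult:
    """Distance outcome: a finite RMSD with its mapping, or infinity."""

    value: float
    mapping: ProperMapping | None = None
    transform: RigidTransform | None = None
    seed_count: int = 0

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.value)

    @classmethod
    def infinite(cls, seed_count: int = 0) -> "PatchDistanceResult":
        return cls(value=math.inf, mapping=None, transform=None, seed_count=seed_count)


def compatible(
    a: Patch,
    b: Patch,
    phi1: float = PHI1,
    phi2: float = PHI2,
    phi3: float = PHI3,
) -> bool:
    """Size, composition and rg screens; failing any makes dist infinite."""
    n, m = len(a), len(b)
    big = max(n, m)
    if big == 0:
        return False
    if abs(n - m) / big > phi1 + 1e-12:
        return False
    types = set(a.composition) | set(b.composition)
    chem = sum(abs(a.composition.get(t, 0) - b.composition.get(t, 0)) for t in types)
    if chem / big > phi2 + 1e-12:
        return False
    if abs(a.rg - b.rg) > phi3 + 1e-12:
        return False
    return True


def kabsch_superpose(
    points_a: np.ndarray, points_b: np.ndarray
) -> tuple[float, RigidTransform]:
    """Least-squares rigid superposition of ``points_b`` onto ``points_a``.

    Proper rotations only (no reflection).  Returns the minimised RMSD and
    the transform such that ``transform.apply(points_b) ~ points_a``.
    Degenerate sets (single point, collinear) still yield a valid minimum.
    """
    pa = np.asarray(points_a, dtype=float).reshape(-1, 3)
    pb = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if pa.shape != pb.shape or pa.shape[0] == 0:
        raise ValueError("point sets must be equal-length and non-empty")
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    if pa.shape[0] == 1:
        return 0.0, RigidTransform(np.eye(3), ca - cb)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate sets warn but solve fine
        rot, _ = Rotation.align_vectors(pa - ca, pb - cb)
    R = rot.as_matrix()
    transform = RigidTransform(R, ca - R @ cb)
    # residual-based RMSD: numerically exact near zero, unlike the
    # singular-value form which cancels catastrophically
    residuals = pa - transform.apply(pb)
    rmsd = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return rmsd, transform


def _type_groups(
    types_a: Sequence[AtomType], types_b: Sequence[AtomType]
) -> list[tuple[list[int], list[int]]]:
    """Per shared type: (indices in A, indices in B), deterministic order."""
    by_a: dict[AtomType, list[int]] = {}
    by_b: dict[AtomType, list[int]] = {}
    for i, t in enumerate(types_a):
        by_a.setdefault(t, []).append(i)
    for j, t in enumerate(types_b):
        by_b.setdefault(t, []).append(j)
    shared = sorted(set(by_a) & set(by_b))
    return [(by_a[t], by_b[t]) for t in shared]


def count_maximal_mappings(
    types_a: Sequence[AtomType], types_b: Sequence[AtomType]
) -> int:
    """Number of maximal proper mappings between two typed atom sets."""
    total = 1
    for ia, ib in _type_groups(types_a, types_b):
        small, large = sorted((len(ia), len(ib)))
        total *= math.perm(large, small)
    return total


def enumerate_maximal_mappings(
    types_a: Sequence[AtomType],
    types_b: Sequence[AtomType],
    cap: int | None = None,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (idx_a, idx_b) index arrays for every maximal proper mapping.

    Maximal: within each shared type the smaller side is fully mapped.
    All mappings therefore have the same length sum_t min(|A_t|, |B_t|).
    Enumeration order is deterministic; ``cap`` truncates it.
    """
    groups = _type_groups(types_a, types_b)
    if not groups:
        return

    def per_group(ia: list[int], ib: list[int]):
        if len(ia) <= len(ib):
            return [(ia, list(p)) for p in itertools.permutations(ib, len(ia))]
        return [(list(p), ib) for p in itertools.permutations(ia, len(ib))]

    choices = [per_group(ia, ib) for ia, ib in groups]
    it = itertools.product(*choices)
    if cap is not None:
        it = itertools.islice(it, cap)
    for combo in it:
        idx_a = np.concatenate([np.asarray(c[0], dtype=int) for c in combo])
        idx_b = np.concatenate([np.asarray(c[1], dtype=int) for c in combo])
        yield idx_a, idx_b


def _batch_rmsd(sets_a: np.ndarray, sets_b: np.ndarray) -> np.ndarray:
    """Minimal superposition RMSD for M paired point sets, (M, s, 3) each."""
    s = sets_a.shape[1]
    A = sets_a - sets_a.mean(axis=1, keepdims=True)
    B = sets_b - sets_b.mean(axis=1, keepdims=True)
    C = np.einsum("msi,msj->mij", B, A)
    U, S, Vt = np.linalg.svd(C)
    sign = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    sign[sign == 0] = 1.0
    S = S.copy()
    S[:, -1] *= sign
    sq = (A**2).sum(axis=(1, 2)) + (B**2).sum(axis=(1, 2)) - 2.0 * S.sum(axis=1)
    return np.sqrt(np.maximum(sq, 0.0) / s)


def exact_distance(
    a: Patch,
    b: Patch,
    phi1: float = PHI1,
    phi2: float = PHI2,
    phi3: float = PHI3,
    max_atoms: int = ORACLE_MAX_ATOMS,
) -> PatchDistanceResult:
    """Brute-force minimum RMSD over every maximal proper mapping.

    Oracle-only: factorial per atom type, refuses patches larger than
    ``max_atoms``.
    """
    if len(a) > max_atoms or len(b) > max_atoms:
        raise ValueError(
            f"exact_distance is an oracle for patches of <= {max_atoms} atoms"
        )
    if not compatible(a, b, phi1, phi2, phi3):
        return PatchDistanceResult.infinite()

    types_a, types_b = a.types, b.types
    coords_a, coords_b = a.coords, b.coords
    batch_idx: list[tuple[np.ndarray, np.ndarray]] = list(
        enumerate_maximal_mappings(types_a, types_b)
    )
    if not batch_idx:
        return PatchDistanceResult.infinite()
    sets_a = np.stack([coords_a[ia] for ia, _ in batch_idx])
    sets_b = np.stack([coords_b[ib] for _, ib in batch_idx])
    rmsds = _batch_rmsd(sets_a, sets_b)
    w = int(np.argmin(rmsds))
    ia, ib = batch_idx[w]
    rmsd, transform = kabsch_superpose(coords_a[ia], coords_b[ib])
    mapping = ProperMapping(tuple(zip(map(int, ia), map(int, ib))))
    return PatchDistanceResult(
        value=float(rmsds[w]), mapping=mapping, transform=transform
    )


def _greedy_match(
    coords_a: np.ndarray,
    types_a_codes: np.ndarray,
    coords_b_transformed: np.ndarray,
    types_b_codes: np.ndarray,
    cutoff: float,
) -> tuple[list[tuple[int, int]], int]:
    """Greedy maximal matching of A's atoms to transformed B atoms.

    Candidate same-type pairs are accepted in ascending distance order,
    each atom used at most once; the matching runs to type-capacity
    maximality so the result is a maximal proper mapping (final RMSDs can
    then never fall below the exact minimum over maximal mappings).
    Returns the pairs and the count of pairs within ``cutoff``, which the
    caller uses as a seed-quality gate.
    """
    diff = coords_a[:, None, :] - coords_b_transformed[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    same = types_a_codes[:, None] == types_b_codes[None, :]
    cand_i, cand_j = np.nonzero(same)
    order = np.argsort(dist[cand_i, cand_j], kind="stable")
    used_a = np.zeros(coords_a.shape[0], dtype=bool)
    used_b = np.zeros(coords_b_transformed.shape[0], dtype=bool)
    pairs: list[tuple[int, int]] = []
    n_close = 0
    for k in order:
        i, j = int(cand_i[k]), int(cand_j[k])
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            pairs.append((i, j))
            if dist[i, j] <= cutoff:
                n_close += 1
    return pairs, n_close


def heuristic_distance(
    a: Patch,
    b: Patch,
    seed_rmsd_max: float = SEED_RMSD_MAX,
    match_cutoff: float = MATCH_CUTOFF,
    min_match_frac: float = MIN_MATCH_FRAC,
    phi1: float = PHI1,
    phi2: float = PHI2,
    phi3: float = PHI3,
    max_seed_mappings: int = MAX_SEED_MAPPINGS,
    max_seeds: int = MAX_SEEDS,
) -> PatchDistanceResult:
    """Inner-sphere-seeded approximation of the minimum proper-mapping RMSD.

    Every maximal proper mapping between the two inner spheres is superposed;
    those below ``seed_rmsd_max`` become seed transforms.  Each seed's
    transform is applied to the whole of B, atoms are greedily matched by
    proximity among equal types within ``match_cutoff``, the matched pairs
    are re-superposed, and the best final RMSD wins.  With no seed, or no
    seed matching at least ``min_match_frac`` of the smaller patch (and at
    least 3 atoms), the distance is infinite.
    """
    if not compatible(a, b, phi1, phi2, phi3):
        return PatchDistanceResult.infinite()

    inner_a, inner_b = a.inner_atoms, b.inner_atoms
    types_ia = [at.atom_type for at in inner_a]
    types_ib = [at.atom_type for at in inner_b]
    coords_ia = np.array([at.coords for at in inner_a], dtype=float)
    coords_ib = np.array([at.coords for at in inner_b], dtype=float)

    idx_pairs = list(
        enumerate_maximal_mappings(types_ia, types_ib, cap=max_seed_mappings)
    )
    idx_pairs = [(ia, ib) for ia, ib in idx_pairs if len(ia) >= 3]
    if not idx_pairs:
        return PatchDistanceResult.infinite()

    sets_a = np.stack([coords_ia[ia] for ia, _ in idx_pairs])
    sets_b = np.stack([coords_ib[ib] for _, ib in idx_pairs])
    inner_rmsds = _batch_rmsd(sets_a, sets_b)
    seed_order = np.argsort(inner_rmsds, kind="stable")
    seeds = [
        k for k in seed_order if inner_rmsds[k] < seed_rmsd_max - 1e-12
    ][:max_seeds]
    if not seeds:
        return PatchDistanceResult.infinite()

    coords_a, coords_b = a.coords, b.coords
    types_a, types_b = a.types, b.types
    code_of: dict[AtomType, int] = {}
    for t in itertools.chain(types_a, types_b):
        code_of.setdefault(t, len(code_of))
    codes_a = np.array([code_of[t] for t in types_a], dtype=int)
    codes_b = np.array([code_of[t] for t in types_b], dtype=int)

    min_close = max(3, math.ceil(min_match_frac * min(len(a), len(b))))
    best: PatchDistanceResult | None = None
    for k in seeds:
        ia, ib = idx_pairs[k]
        _, seed_tf = kabsch_superpose(coords_ia[ia], coords_ib[ib])
        moved_b = seed_tf.apply(coords_b)
        pairs, n_close = _greedy_match(coords_a, codes_a, moved_b, codes_b, match_cutoff)
        if n_close < min_close:
            continue
        pa = coords_a[[i for i, _ in pairs]]
        pb = coords_b[[j for _, j in pairs]]
        rmsd, transform = kabsch_superpose(pa, pb)
        if best is None or rmsd < best.value:
            best = PatchDistanceResult(
                value=rmsd,
                mapping=ProperMapping(tuple(pairs)),
                transform=transform,
                seed_count=len(seeds),
            )
    if best is None:
        return PatchDistanceResult.infinite(seed_count=len(seeds))
    return best


def pairwise_distances(
    patches: Sequence[Patch],
    **dist_kwargs,
) -> np.ndarray:
    """Symmetric all-vs-all heuristic distance matrix (inf = incompatible).

    The diagonal is zero and each unordered pair is computed once.
    """
    n = len(patches)
    if n < 2:
        raise ValueError("need at least 2 patches")
    matrix = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = heuristic_distance(patches[i], patches[j], **dist_kwargs).value
            matrix[i, j] = matrix[j, i] = d
    return matrix
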