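"""Scoring structures against a surface-patch library.

Each query patch gets a DCLE -- distance to the closest library element --
and a cluster assignment.  A structure (or set) is summarised by the
fraction of patches with infinite DCLE, the mean finite DCLE, and the
cluster-preference vector F(Q) whose entries f(Q, C_i) are the fraction of
assigned patches closest to centroid i.  Preference deviations from the
training set, Delta_i = |f(Q0, C_i) - f(Q, C_i)|, and Wilcoxon rank-sum
comparisons of DCLE pools quantify how native-like a set of patches is;
lexicographic (infinite fraction, mean finite DCLE) scores rank candidate
models of the same target, lower being better.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .patch_clustering import PatchLibrary
from .patch_distance import heuristic_distance
from .structure_io import StructureModel, compute_sasa
from .surface_patches import (
    DEFAULT_RADIUS,
    Patch,
    SurfaceThresholdTable,
    extract_patches,
    select_surface_atoms,
)

__all__ = [
    "PatchAssignment",
    "CompatibilityProfile",
    "assign_patch",
    "profile_structure",
    "profile_patches",
    "delta_preferences",
    "wilcoxon_rank_sum",
    "rank_models",
    "bootstrap_rank1_std",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PatchAssignment:
    patch_id: str
    cluster: int | None
    dcle: float


@dataclasses.dataclass
class CompatibilityProfile:
    """Per-patch library assignments and set-level summaries for one source."""

    source_id: str
    assignments: list[PatchAssignment]
    preference: np.ndarray  # F(Q): per-cluster fraction of assigned patches
    mean_finite_dcle: float
    fraction_infinite: float
    empty: bool = False  # no patches could be extracted

    @property
    def dcle_values(self) -> np.ndarray:
        return np.array([a.dcle for a in self.assignments], dtype=float)

    @property
    def score(self) -> tuple[float, float]:
        """Lexicographic model score: lower is more library-compatible."""
        return (self.fraction_infinite, self.mean_finite_dcle)


def assign_patch(
    patch: Patch, library: PatchLibrary, **dist_kwargs
) -> tuple[int | None, float]:
    """Closest library element: (cluster index, DCLE); (None, inf) if the
    patch is incompatible with every centroid.  Ties break to the lowest
    centroid index."""
    if library.k < 1:
        raise ValueError("empty library")
    best_idx: int | None = None
    best = math.inf
    for i, centroid in enumerate(library.centroids):
        d = heuristic_distance(patch, centroid, **dist_kwargs).value
        if d < best:
            best, best_idx = d, i
    if math.isinf(best):
        return None, math.inf
    return best_idx, best


def profile_patches(
    source_id: str,
    patches: Sequence[Patch],
    library: PatchLibrary,
    **dist_kwargs,
) -> CompatibilityProfile:
    """Assign a ready-made patch collection against the library."""
    assignments = []
    for p in patches:
        cluster, dcle = assign_patch(p, library, **dist_kwargs)
        assignments.append(PatchAssignment(p.patch_id, cluster, dcle))
    dcle = np.array([a.dcle for a in assignments], dtype=float)
    finite = dcle[np.isfinite(dcle)]
    counts = np.zeros(library.k, dtype=float)
    for a in assignments:
        if a.cluster is not None:
            counts[a.cluster] += 1
    n_assigned = counts.sum()
    preference = counts / n_assigned if n_assigned > 0 else counts
    return CompatibilityProfile(
        source_id=source_id,
        assignments=assignments,
        preference=preference,
        mean_finite_dcle=float(finite.mean()) if finite.size else math.inf,
        fraction_infinite=(
            float(np.mean(~np.isfinite(dcle))) if dcle.size else 1.0
        ),
        empty=len(assignments) == 0,
    )


def profile_structure(
    structure: StructureModel,
    library: PatchLibrary,
    thresholds: SurfaceThresholdTable,
    radius: float = DEFAULT_RADIUS,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    **dist_kwargs,
) -> CompatibilityProfile:
    """Full pipeline for one structure: SASA, surface, patches, assignment."""
    sasa = compute_sasa(structure, probe_radius=probe_radius, n_sphere_points=n_sphere_points)
    surface = select_surface_atoms(structure, sasa, thresholds)
    patches = extract_patches(structure, surface, radius=radius)
    if not patches:
        logger.warning("structure %s yields no surface patches", structure.identifier)
    return profile_patches(structure.identifier, patches, library, **dist_kwargs)


def delta_preferences(f0: np.ndarray, fq: np.ndarray) -> np.ndarray:
    """Delta_i = |f(Q0, C_i) - f(Q, C_i)| elementwise."""
    f0 = np.asarray(f0, dtype=float)
    fq = np.asarray(fq, dtype=float)
    if f0.shape != fq.shape:
        raise ValueError("preference vectors differ in length")
    return np.abs(f0 - fq)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test, (rank-sum statistic of x, p).

    Uses the tie- and continuity-corrected normal approximation.
    Infinities are legal sample values: they rank above every finite value
    and tie among themselves at mid-ranks.  Two identical constant samples
    give p = 1 by convention.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 values")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # average ranks; handles +-inf ties
    w = float(ranks[: len(x)].sum())
    if np.all(pooled == pooled[0]):
        return w, 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", use_continuity=True, method="asymptotic"
    )
    return w, float(res.pvalue)


def rank_models(
    models: Sequence[StructureModel],
    library: PatchLibrary,
    thresholds: SurfaceThresholdTable,
    **profile_kwargs,
) -> list[tuple[StructureModel, CompatibilityProfile, int]]:
    """Rank candidate models of one target by library compatibility.

    Score = (fraction of infinite-DCLE patches, mean finite DCLE),
    compared lexicographically; lower is better.  Ties keep input order;
    a model with zero patches scores (inf, inf) and ranks last.
    Returns (model, profile, rank) triples, rank 1 = best, in rank order.
    """
    if len(models) < 2:
        raise ValueError("ranking needs at least 2 models")
    profiles = [
        profile_structure(m, library, thresholds, **profile_kwargs) for m in models
    ]
    keyed = []
    for pos, (m, prof) in enumerate(zip(models, profiles)):
        score = (math.inf, math.inf) if prof.empty else prof.score
        if prof.empty:
            logger.warning("model %s has no patches; ranked last", m.identifier)
        keyed.append((score, pos, m, prof))
    keyed.sort(key=lambda t: (t[0], t[1]))  # stable: ties keep input order
    return [(m, prof, rank) for rank, (_, _, m, prof) in enumerate(keyed, start=1)]


def bootstrap_rank1_std(
    rank1_flags: Sequence[bool], n_iter: int = 10_000, rng_seed: int = 0
) -> float:
    """Bootstrap std (percentage points) of the rank-1 fraction over targets."""
    flags = np.asarray(list(rank1_flags), dtype=float)
    if flags.size == 0:
        raise ValueError("no targets")
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, flags.size, size=(n_iter, flags.size))
    means = flags[idx].mean(axis=1)
    return float(means.std(ddof=1) * 100.0)
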