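"""Outlier weeding and k-means++/medoid clustering of surface patches.

Patches far from almost everything (distance above 2.5 A to more than 90%
of the others, infinities included) are weeded out first to avoid
singleton clusters.  The remainder is clustered by Lloyd alternation under
the patch distance with k-means++ seeding; because coordinate averaging of
patches with different compositions is ill-defined, the cluster centre is
the *medoid* -- the member minimising total finite distance to its
co-members -- so every library element is a real patch that can later serve
as a superposition target.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .surface_patches import Patch

__all__ = [
    "PatchLibrary",
    "weed_outliers",
    "kmeanspp_seed",
    "cluster_patches",
    "DEFAULT_K",
    "OUTLIER_DISTANCE",
    "OUTLIER_FRACTION",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 350
OUTLIER_DISTANCE = 2.5  # Angstrom
OUTLIER_FRACTION = 0.9
MAX_ITER = 100
INF_CAP_FACTOR = 2.0  # infinities capped at this multiple of the max finite distance


@dataclasses.dataclass
class PatchLibrary:
    """k centroid patches with cluster sizes and training preferences.

    ``training_fractions[i]`` is f(Q0, C_i): the fraction of the clustered
    training patches assigned to cluster i; the preference vector of the
    training set itself.
    """

    centroids: list[Patch]
    cluster_sizes: np.ndarray
    training_fractions: np.ndarray
    centroid_indices: np.ndarray  # indices into the clustered patch list
    assignments: np.ndarray  # cluster label per clustered patch
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.centroids)
        if k < 1:
            raise ValueError("library must hold at least one centroid")
        self.cluster_sizes = np.asarray(self.cluster_sizes, dtype=int)
        self.training_fractions = np.asarray(self.training_fractions, dtype=float)
        if self.cluster_sizes.shape != (k,) or self.training_fractions.shape != (k,):
            raise ValueError("sizes/fractions must have one entry per centroid")
        if abs(self.training_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("training fractions must sum to 1")

    @property
    def k(self) -> int:
        return len(self.centroids)


def _capped(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Replace infinities by a finite cap preserving 'far' semantics."""
    finite = matrix[np.isfinite(matrix)]
    cap = INF_CAP_FACTOR * float(finite.max()) if finite.size and finite.max() > 0 else 1.0
    out = matrix.copy()
    out[~np.isfinite(out)] = cap
    return out, cap


def outlier_mask(
    dmatrix: np.ndarray,
    d_out: float = OUTLIER_DISTANCE,
    frac: float = OUTLIER_FRACTION,
) -> np.ndarray:
    """Boolean mask: True where a patch is an outlier.

    A patch is an outlier when its distance exceeds ``d_out`` (infinity
    counts as exceeding) to strictly more than ``frac`` of the *other*
    patches.
    """
    dmatrix = np.asarray(dmatrix, dtype=float)
    n = dmatrix.shape[0]
    if n < 2:
        return np.zeros(n, dtype=bool)
    far = (dmatrix > d_out) | ~np.isfinite(dmatrix)
    np.fill_diagonal(far, False)
    return far.sum(axis=1) > frac * (n - 1) + 1e-12


def weed_outliers(
    patches: Sequence[Patch],
    dmatrix: np.ndarray,
    d_out: float = OUTLIER_DISTANCE,
    frac: float = OUTLIER_FRACTION,
) -> tuple[list[Patch], list[Patch]]:
    """Split patches into (kept, removed) by the far-from-most rule.

    Original order is preserved in both outputs; with fewer than 2 patches
    everything is kept.
    """
    patches = list(patches)
    n = len(patches)
    if n < 2:
        return patches, []
    dmatrix = np.asarray(dmatrix, dtype=float)
    if dmatrix.shape != (n, n):
        raise ValueError("distance matrix does not match patches")
    is_outlier = outlier_mask(dmatrix, d_out, frac)
    kept = [p for p, o in zip(patches, is_outlier) if not o]
    removed = [p for p, o in zip(patches, is_outlier) if o]
    return kept, removed


def kmeanspp_seed(
    patches: Sequence[Patch],
    dmatrix: np.ndarray,
    k: int,
    rng_seed: int,
) -> list[int]:
    """k-means++ seeding over a precomputed distance matrix.

    First centre uniform at random; each next centre sampled with
    probability proportional to D(x)^2 where D(x) is the distance to the
    nearest chosen centre (infinities capped).  Deterministic per seed.
    """
    n = len(patches)
    if k > n:
        raise ValueError(f"k={k} exceeds number of patches n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    dm, _ = _capped(np.asarray(dmatrix, dtype=float))
    rng = np.random.default_rng(rng_seed)
    chosen = [int(rng.integers(n))]
    d_near = dm[chosen[0]].copy()
    d_near[chosen[0]] = 0.0
    while len(chosen) < k:
        w = d_near**2
        total = w.sum()
        if total <= 0:
            # all remaining points coincide with a centre: pick lowest unchosen
            remaining = sorted(set(range(n)) - set(chosen))
            chosen.append(remaining[0])
        else:
            nxt = int(rng.choice(n, p=w / total))
            chosen.append(nxt)
        d_near = np.minimum(d_near, dm[chosen[-1]])
        d_near[chosen[-1]] = 0.0
    return chosen


def _assign(dm: np.ndarray, centroid_idx: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels; ties break to the lowest centroid index."""
    sub = dm[:, centroid_idx]  # (n, k)
    return np.argmin(sub, axis=1)  # argmin returns first minimum = lowest index


def _lloyd_once(
    patches: Sequence[Patch],
    raw: np.ndarray,
    dm: np.ndarray,
    k: int,
    max_iter: int,
    init_seed: int,
) -> tuple[np.ndarray, np.ndarray, list[float], int]:
    n = len(patches)
    centroid_idx = np.asarray(kmeanspp_seed(patches, raw, k, init_seed), dtype=int)
    labels = _assign(dm, centroid_idx)
    objective_trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # re-seed empty clusters with the patch of largest current DCLE
        d_near = dm[np.arange(n), centroid_idx[labels]]
        for c in range(k):
            if not np.any(labels == c):
                far_patch = int(np.argmax(d_near))
                centroid_idx[c] = far_patch
                labels[far_patch] = c
                d_near = dm[np.arange(n), centroid_idx[labels]]
                logger.info("re-seeded empty cluster %d with patch %d", c, far_patch)
        # medoid update: member minimising total distance to co-members
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            sub = dm[np.ix_(members, members)]
            centroid_idx[c] = int(members[np.argmin(sub.sum(axis=1))])
        new_labels = _assign(dm, centroid_idx)
        objective_trace.append(
            float(dm[np.arange(n), centroid_idx[new_labels]].sum())
        )
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    return labels, centroid_idx, objective_trace, n_iter


def cluster_patches(
    patches: Sequence[Patch],
    dmatrix: np.ndarray,
    k: int = DEFAULT_K,
    max_iter: int = MAX_ITER,
    rng_seed: int = 0,
    n_init: int = 5,
) -> PatchLibrary:
    """Lloyd alternation with medoid update under the patch distance.

    Assignment uses the capped matrix so patches infinitely far from every
    centroid still join their least-far cluster; the medoid minimises the
    sum of capped distances to co-members.  Empty clusters are re-seeded
    with the patch furthest from its nearest centroid.  Each restart stops
    when the assignment stabilises or after ``max_iter`` rounds;
    ``n_init`` k-means++ restarts are run (seeds derived from
    ``rng_seed``) and the lowest-objective solution wins, the usual guard
    against unlucky seedings.  Deterministic per ``rng_seed``.
    """
    patches = list(patches)
    n = len(patches)
    if k > n:
        raise ValueError(f"k={k} exceeds number of patches n={n}")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    raw = np.asarray(dmatrix, dtype=float)
    if raw.shape != (n, n):
        raise ValueError("distance matrix does not match patches")
    dm, cap = _capped(raw)

    best = None
    for restart in range(n_init):
        init_seed = rng_seed + 100_003 * restart
        labels_r, centroid_r, trace_r, iter_r = _lloyd_once(
            patches, raw, dm, k, max_iter, init_seed
        )
        objective = float(dm[np.arange(n), centroid_r[labels_r]].sum())
        if best is None or objective < best[0] - 1e-12:
            best = (objective, labels_r, centroid_r, trace_r, iter_r)
    _, labels, centroid_idx, objective_trace, n_iter = best

    sizes = np.bincount(labels, minlength=k)
    fractions = sizes / n
    library = PatchLibrary(
        centroids=[patches[i] for i in centroid_idx],
        cluster_sizes=sizes,
        training_fractions=fractions,
        centroid_indices=centroid_idx.copy(),
        assignments=labels.copy(),
        provenance={
            "n_patches": n,
            "k": k,
            "rng_seed": rng_seed,
            "n_iter": n_iter,
            "inf_cap": cap,
            "objective_trace": objective_trace,
        },
    )
    logger.info(
        "clustered %d patches into k=%d (converged in %d iterations)", n, k, n_iter
    )
    return library
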