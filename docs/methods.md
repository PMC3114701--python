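# Methods

This note documents the models, parameters, numerical choices and known
limitations of `surfpatch`. The README describes the pipeline at a high
level; here the emphasis is on *why* each piece is the way it is and what
the synthetic experiments do and do not demonstrate.

## Surface definition

Solvent-accessible surface area is computed per heavy atom with the
Shrake–Rupley sphere-sampling algorithm (biotite backend): a 1.4 Å water
probe, element-wise van-der-Waals radii, and 960 quadrature points on a
deterministic Fibonacci sphere. SASA is quadrature-limited rather than
exact; the package treats any two runs at the same point count as
identical and any comparison across rotations as accurate to roughly the
quadrature error (≈1% of an exposed atom's area). Hydrogens are not
modelled; only the heavy atoms of the 20 standard residues enter, with
alternate locations resolved to the highest-occupancy conformer and only
the first model of a multi-model file used.

An atom of type *t* (residue + atom name) is *surface* iff its SASA is at
least α times `access_surf_t`, where `access_surf_t` is a percentile of
the pooled SASA distribution of type *t* over the training corpus
(sorted-values linear interpolation). The defaults — 99th percentile,
α = 0.9 — are the method's reference calibration for crystallographic
protein corpora, where per-type SASA distributions have a long upper tail
and the rule picks genuinely exposed atoms while damping artifacts such
as superficially exposed backbone from missing side chains.

Both knobs are configuration because the rule is *corpus-relative*. On
the synthetic mini-proteins used for testing, essentially every atom is
solvent-exposed and per-type distributions are tight, so the reference
calibration would label only chain ends as surface. The fixture
experiments therefore fit thresholds at the 10th percentile with α = 0.9,
which places the cutoff below the buried/exposed valley of those corpora
and restores the properties the surface stage is supposed to deliver:
continuous coverage by overlapping patches and mean patch sizes in the
tens of atoms. This is a calibration of the same rule to a different
corpus, not a different rule.

## Patches

A patch is one exposed CB pivot plus all surface atoms within r = 7 Å
(inclusive boundary), stored with its per-type composition counts, its
unweighted radius of gyration about the geometric centroid, and its inner
sphere. Glycine has no CB and contributes no pivots, though its atoms
appear inside neighbouring patches. Patch extraction is order-independent:
pivots are processed in residue order and patch atoms are sorted by
residue and atom name.

The **inner sphere** is fixed by scanning the pivot-centred radius
downward from r in 0.25 Å steps and stopping at the first radius whose
atom count lies in [4, 9]. If coincident shells make the count jump from
above 9 to below 4 within one step, the 9 atoms nearest the pivot are
taken instead, so the 4–9 invariant holds whenever the patch has at least
4 atoms; smaller patches are their own inner sphere and carry a `small`
flag.

## Patch distance

Two patches are compared only if they pass three compatibility screens:
relative size difference ≤ Φ₁, relative composition difference
Σᵢ|T_iA − T_iB| / max(n,m) ≤ Φ₂, and |rg(A) − rg(B)| ≤ Φ₃
(Φ₁ = Φ₂ = 0.2, Φ₃ = 5 Å). Normalising the first two by max(n, m) makes
Φ₁ and Φ₂ dimensionless fractions consistent with ΣᵢT_iA = n; all three
thresholds are configuration. Failing any screen makes the distance
infinite.

For compatible patches the distance is the minimum RMSD over *maximal
proper mappings*: type-preserving one-to-one correspondences in which the
smaller per-type group is fully mapped. Superposition is least-squares
rigid with proper rotations only (reflections are never allowed); the
measure is symmetric and rigid-invariant but does **not** satisfy the
triangle inequality, so it is a dissimilarity, not a metric. RMSD is
evaluated from the actual residuals of the fitted transform rather than
from the singular values, which keeps near-zero distances accurate to
machine precision instead of ~1e-7.

`exact_distance` enumerates every maximal mapping (batched SVD) and is
the oracle; it refuses patches above 8 atoms because the search is
factorial per type. The production path, `heuristic_distance`, follows
the seeded scheme:

1. Enumerate all maximal proper mappings between the two inner spheres
   (deterministic order, capped at 4096; mappings of fewer than 3 pairs
   are discarded because a rigid transform is underdetermined below
   that).
2. Superpose each; mappings with inner RMSD < 2 Å become seeds. No seed
   means infinite distance. At most the 32 best seeds (by inner RMSD) are
   carried forward; both caps bound the cost on repetitive compositions
   and are configuration.
3. For each seed, apply its transform to the whole of B and match atoms
   greedily: all same-type pairs in ascending distance order, each atom
   used once, run to type-capacity maximality. The greedy mapping is
   therefore itself a maximal proper mapping. A seed is accepted only if
   at least 50% of the smaller patch (and at least 3 atoms) matched
   within the 3 Å proximity cutoff — the quality gate that prevents a
   handful of coincidentally close atoms from producing a spurious
   finite score.
4. Re-superpose the matched pairs; the minimum final RMSD over accepted
   seeds is the distance.

Because every scored mapping is maximal, the heuristic can never report a
value below the exact minimum (it searches a subset of the same mapping
space); it errs only upward, typically by < 0.1 Å on oracle-sized
patches. Whether a pivot maps to a pivot is not constrained.

## Outlier weeding and clustering

A patch is an outlier when its distance exceeds 2.5 Å (infinity included)
to strictly more than 90% of the other patches; outliers are removed
before clustering to avoid singleton clusters. On the synthetic ensembles
the weeded patches are overwhelmingly chain-end patches — the analogue of
the domain-boundary and crystal-contact artifacts this rule is meant to
absorb.

Clustering is Lloyd alternation under the patch distance with k-means++
seeding and **medoid** updates: averaging coordinates across patches of
different compositions is ill-defined, and medoids keep every library
element a real patch usable as a superposition target. Details:

- Infinite distances are capped at twice the largest finite distance for
  seeding weights and assignment, preserving "far" semantics while
  keeping D² sampling proper.
- Assignment ties break to the lowest centroid index; every tie-break in
  the pipeline is lowest-index, so runs are bit-reproducible per seed.
- Empty clusters are re-seeded with the patch furthest from its nearest
  centroid.
- Each restart stops on unchanged assignments or after 100 iterations;
  the within-cluster objective is non-increasing across iterations.
- `n_init` = 5 k-means++ restarts are run (seeds derived from the master
  seed) and the lowest final objective wins. A single D²-weighted seeding
  occasionally places two seeds in one tight group, and a medoid update
  cannot migrate a centroid across well-separated groups afterwards;
  restarts are the standard guard.

The library stores the centroid patches, cluster sizes, and the training
preference vector f(Q⁰, Cᵢ) = sizeᵢ / n.

## Scoring and ranking

A query patch's DCLE is its minimum heuristic distance over the
centroids (ties to the lowest index); incompatibility with every centroid
gives an infinite DCLE and no cluster. A structure's profile aggregates
the fraction of infinite-DCLE patches, the mean finite DCLE, and the
preference vector over assigned patches.

Models of one target are ranked by the lexicographic score (infinite
fraction, mean finite DCLE), lower better, ties keeping input order; a
model with no patches ranks last. The aggregation is configuration-level
by design — median DCLE or threshold-exceedance fractions are drop-in
alternatives — because per-patch scores admit several defensible
summaries and the infinite fraction carries most of the signal on heavily
distorted models.

The Wilcoxon rank-sum test uses the tie- and continuity-corrected normal
approximation (appropriate for the thousands-of-patches pools the method
produces); infinities are legal sample values that rank above all finite
values. Two identical constant samples return p = 1 by convention. An
exact-enumeration oracle in the test suite checks the approximation to
within 0.02 at sample size 8+8. Bootstrap standard deviations of the
rank-1 percentage resample targets with replacement, 10,000 iterations,
seeded.

## Synthetic fixtures and what they show

`make_structure` builds mini-proteins with ideal CA spacing (3.8 Å helix /
sheet / self-avoiding coil traces), backbone N, C, O placed on and around
the CA–CA segments with exact bond-scale distances, outward-pointing CBs,
and 0–2 typed side-chain stub atoms per residue. Sequences are random
draws from a palette or periodic repeats of it. `perturb_structure` adds
seeded isotropic Gaussian noise (RMSD ≈ σ√3). All generators are
bit-reproducible from their seeds.

The library experiments use a corpus of 20 native-like structures: 10
noisy copies (σ = 0.1 Å) each of two periodic 24-residue bases (an
ALA/SER helix and a LEU/LYS sheet), clustered at k = 12. Periodic
sequences matter: a homorepeat helix is screw-symmetric, so patches recur
*along the chain* as well as across copies. This recurrence is the
premise a motif library rests on; random-sequence corpora have
essentially no chemically compatible patch pairs under Φ₂ = 0.2 and
cannot support a library at desk scale.

`make_planted_patches` plants k groups of noisy copies of distinct
template point-clouds sharing one composition. For separations below the
2 Å seed limit, templates are calibrated perturbations (0.8 Å spread) of
one base cloud held in a [min_separation, 1.95 Å] exact-distance band, so
between-group distances stay finite and geometry-driven; larger requested
separations use independent templates and may legitimately be infinite. A
construction check requires the minimum inter-template distance to exceed
3× the sampled maximum intra-group distance, retrying with derived seeds.

What passing these experiments shows: every stage behaves per contract on
geometrically clean, chemically typed inputs with known ground truth —
the distance is sound against brute force, clustering recovers planted
structure, the outlier rule and the DCLE/Δ machinery do what they claim,
and heavily perturbed decoys are reliably separated from natives. What it
does **not** show: performance on real crystallographic corpora, whose
patch recurrence, composition diversity, packing and artifact structure
the fixtures only caricature; nor anything about competitive model
quality assessment against modern predictors. Decoys here are Gaussian
perturbations, which destroy surface chemistry far more crudely than a
structure-prediction server does.

## Experiment sizes

The evaluation protocols are sized for a single CPU: 2×10⁶ random-ranking
trials; 200 oracle-equivalence pairs; 100 sanity patches; 10 seeds × {3,5}
planted groups of 20; 10 outlier seeds; 50 ranking trials (native + five
σ = 2 Å decoys each) plus a 25-trial σ-sweep over {0, 0.5, 1, 2} Å. The
full acceptance script runs in about a minute; the test suite in under
two.

## Known limitations

- The distance is not a metric (no triangle inequality) and the heuristic
  is not admissible beyond oracle sizes — it can overestimate when the
  inner spheres are unrepresentative of the full patch.
- Thresholds, Φ screens and the 2 Å seed rule interact: patch populations
  with little recurrence degenerate to mostly-infinite distance matrices,
  in which case weeding removes everything (the CLI reports this rather
  than clustering noise).
- mmCIF input, hydrogens, hetero-groups, multi-model ensembles and
  assembly generation are out of scope; insertion codes are honoured as
  part of residue identity.
- Serialized patch files store coordinates at full precision but PDB
  output rounds to 3 decimals, so a PDB round-trip is only stable to
  5×10⁻⁴ Å.
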