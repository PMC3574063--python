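# Methods

## Problem setting

Input is an all-vs-all pairwise similarity over n protein sequences, either
as BLAST tabular hits (outfmt 6) or as a square score matrix, optionally
with a sequence→species map and true family labels. The goal is an
unsupervised partition of the sequences into families that remains reliable
for remote homologs, multi-domain proteins, and datasets contaminated by
recent paralogs and outliers.

## From scores to Mercer kernels

Raw search scores violate both kernel axioms. The repair chain is:

* **Symmetrization.** `S ← (S + Sᵀ)/2`. Applied before any spectral step.
* **PSD projection.** Eigendecompose the symmetric matrix and replace every
  negative eigenvalue by zero. For symmetric matrices this is exactly the
  nearest PSD matrix in Frobenius norm, and it is idempotent. We use a
  symmetric eigendecomposition rather than an SVD: for a symmetric matrix
  the singular values are the absolute eigenvalues, and clamping (rather
  than taking absolute values) is what discards the non-kernel part of the
  spectrum instead of folding it back in.
* **Normalization.** Unit-sphere, `K'ᵢⱼ = Kᵢⱼ/√(KᵢᵢKⱼⱼ)` (unit diagonal;
  preserves PSD as a congruence with a positive diagonal matrix), or
  min-max into [0, 1]. The affine min-max shift adds a rank-one all-ones
  term that can push the spectrum negative, so min-max re-projects to PSD
  and then restores the exact [0, 1] range with PSD-safe operations only
  (adding a non-negative multiple of the all-ones matrix, dividing by the
  maximum).
* **Diagonal repair.** Self-scores are orders of magnitude above cross
  scores and would dominate every normalization; `repair_diagonal` replaces
  the diagonal by the row maximum (default) or a constant. After PSD
  projection, a sequence left with a (near-)zero row — e.g. isolated by the
  BLASTP score cutoff — gets unit self-similarity and zero similarity to
  everything else; for a PSD matrix a zero diagonal entry forces a zero
  row, so this is PSD-safe.

Kernel recipes: **I** thresholds HSP bit scores at a cutoff (default 50
bits — a conventional reliable-hit scale, deliberately exposed as a
parameter because no benchmark validates it) and then applies the chain
with unit-sphere normalization; **II** applies the chain directly to
profile-search scores; **V**–**VIII** are Hadamard products of the simple
kernels, PSD by the Schur product theorem and re-normalized to the unit
sphere. The order of operations in recipe I (cutoff → symmetrize → project
→ normalize) keeps the cutoff interpretable in raw score units.

## OrthoMCL-style weights and the neighborhood kernels

Edge weights are averaged −log10 E-values (E-values floored at 1e−180 to
stay finite), symmetrized and diagonal-repaired. For every unordered
species pair (s, t) — including s = t, the within-species paralog case —
each weight is divided by the mean positive weight of its species-pair
block. This damps recent-paralog blocks, whose within-species weights are
systematically inflated, and makes the weighting invariant to rescaling any
one species pair. Only this species-pair mean normalization is implemented;
the full OrthoMCL recent-paralog subgraph logic belongs to the upstream
tool whose output this package consumes.

Neighborhoods are `N(x) = {x} ∪ {y : some hit x→y has E < τ}` (directional;
default τ = 0.05). The **neighborhood similarity kernel (III)** replaces
each sequence's implicit feature vector by its neighborhood mean; the
induced kernel is the double average
`K_nb(x,y) = (1/|N(x)||N(y)|) Σ_{x'∈N(x)} Σ_{y'∈N(y)} K(x',y')`, computed
directly on kernel values as `W K Wᵀ` with W row-stochastic — no feature
vectors are materialized, and every entry stays in the convex hull of the
base kernel's values. The **mismatch profile kernel (IV)** generalizes the
flat average to per-sequence probability weights over the neighborhood. The
weights are taken proportional to the (floored-at-zero) profile-search
scores, falling back to uniform when all scores vanish: this is the minimal
probabilistic refinement of uniform averaging and reduces exactly to
kernel III when scores are flat. Both kernels are PSD-projected and min-max
normalized. Whether the neighborhood average should precede or follow the
species normalization is not externally fixed; here it follows
(symmetrize → normalize → average), which keeps the species correction on
the raw evidence scale.

## Spectral clustering

Ng–Jordan–Weiss: `L = D^{-1/2} K D^{-1/2}` with `D` the diagonal row-sum
matrix; the k eigenvectors of the algebraically largest eigenvalues of L
(ties broken by ascending solver index, signs fixed so the first
non-negligible coordinate is positive) form the embedding, whose rows are
normalized to unit length; seeded k-means++ (10 restarts, max 300
iterations, tolerance 1e−6) partitions the embedding. The symmetric
normalization is used rather than the random-walk variant because the
D^{-1/2}-scaled form is the one the kernel constructions assume. Kernels
are used as affinities directly, with no extra exponentiation: they are
already normalized similarities. PSD projection of thresholded matrices can
leave small negative entries; a negative similarity carries no affinity
mass, so the affinity step clips negatives to zero (entries more negative
than a quarter of the maximum are rejected as not-a-similarity). k is a
required input — in evaluation runs it is the number of true families; no
eigengap model selection is attempted.

## Modified point-symmetry correction

In the embedding space, for point x and candidate centroid c: the
reflection is `x* = 2c − x`; the symmetry term `d_sym` is the mean
Euclidean distance from x* to its `knear` nearest data points among all
clustered points (excluding x itself by default; `knear = 1` recovers the
classical first-nearest-neighbor form, default 2); the modified norm is
`d_ms = d_sym · ‖x − c‖`. The product form amplifies outliers — their
reflection lands in empty space and they are far from every centroid — and
vanishes both at the centroid and when a data point sits exactly at the
mirror position. Correction is a single gated sweep (not iterated to a
fixpoint — it is a post-hoc correction of a spectral solution, not a
clustering algorithm): every point moves to its argmin-d_ms cluster
(ties → lowest index; the current cluster is a legal argmin, so staying is
allowed) iff that minimum is below θ, and centroids are recomputed once
afterwards. θ defaults to the 90th percentile of all points' best d_ms in
the current clustering — a data-adaptive gate that stays meaningful across
embedding scales — with an absolute override available. Both d_sym and
d_ms are reported in the audit output so the multiplicative choice is
inspectable. The sweep can only reuse existing labels, so the number of
distinct clusters never grows.

## Evaluation

A hard clustering carries no per-sequence score, so for ROC purposes each
family is matched to the cluster with maximal member overlap (ties: larger
cluster, then lower index) and every sequence is scored by its mean kernel
similarity to that cluster's members (excluding itself; a singleton match
scores 0). This uses only the kernel and the partition, mirrors
nearest-centroid reasoning in kernel space, and yields ROC = 1 on perfect
block structure. ROC is computed in Mann–Whitney form (ties one half);
ROC50 ranks by descending score with ties broken by sequence ID, truncates
at the 50th false positive, and normalizes by `P · min(N, 50)` so a perfect
ranking scores 1 (with ≤ 50 negatives and no ties it equals ROC). Per-family
ROC50 values are the paired samples for the Wilcoxon signed-rank
comparisons; the test drops zero differences, mid-ranks ties, enumerates
all 2ⁿ sign patterns exactly for n ≤ 12 and otherwise uses the normal
approximation with tie and continuity corrections, reporting the median
difference alongside the p-value. Geometric validity indices (Dunn with
single-linkage separation over maximal diameter; Davies–Bouldin with mean
member-to-centroid scatter; Goodman–Kruskal gamma over within/between
distance comparisons) are computed on the spectral embedding coordinates —
the space in which both k-means and the symmetry correction operate — and
Rand/Jaccard compare partitions by pair counting. Degenerate cases are
defined explicitly: Jaccard with no co-clustered pairs anywhere is 1.0;
zero-diameter or single-cluster geometry raises, and `evaluate` reports
such indices as NaN.

## Synthetic benchmark

The generator emulates the structure of curated all-vs-all benchmarks on a
[0, 1] similarity scale: same-family pairs at `within_mean` (0.8), others at
`between_mean` (0.2); bridge sequences scored at within-level to **both** of
their families (their "primary family" truth tag is an arbitrary
convention — the planted signal is exactly ambiguous); one random
contiguous member pair per family boosted by `paralog_boost` (0.15) as a
recent-paralog analogue; outliers at background level everywhere with the
reserved tag `outlier`; symmetric Gaussian noise (sd 0.05) plus independent
per-direction noise (sd 0.02) for asymmetry, clipped at zero; species
assigned round-robin (3 species). The pinned benchmark is 4 families of
40/30/20/10 plus 4 bridges and 5 outliers (109 sequences, seed 42).

Pseudo-BLAST statistics derive from the similarity s as `bit = 100·s` and
`E = 10^(−50·s)`, placing the planted means at 80 vs 20 bits and 1e−40 vs
1e−10 — a realistic significance gap. Under this calibration the benchmark
neighborhood threshold is 1e−20 (halfway between the planted significance
levels) so neighborhoods contain family members but not background; the
general-purpose default stays 0.05.

What the generator does **not** emulate: actual sequences or alignment
artifacts (length effects, compositional bias), realistic E-value/bit-score
joint distributions, family-size and similarity heterogeneity of curated
databases, or promiscuous domains linking more than two families. Passing
tests therefore demonstrate the algebraic contracts (kernel validity,
reductions, metric correctness) and recovery under controlled noise — not
performance on curated benchmark corpora such as full multi-genome family
databases, which require the external score data this package only parses.

The planted-family recovery statistic (ARI) is computed over sequences
carrying a family label — bridges count, with their primary-family tag;
outliers carry a reserved non-family tag and are excluded — while the
Rand/Jaccard columns of the evaluation reports compare against the full
truth including the outlier tag as one class. The mirror-point fixture for
the symmetry correction is built directly in embedding space (a point
placed at the exact reflection of a cluster member), because mirror
geometry cannot be guaranteed through the full pipeline; it isolates the
reassignment rule.

## Numerical choices and problem sizes

PSD tolerance is 1e−8 relative to the largest eigenvalue (eigensolvers
return tiny negative values for genuinely PSD matrices). Matrix TSV output
uses 12 significant digits. Test-suite and acceptance runs use the
109-sequence benchmark with ten replicate seeds and random property
fixtures of n ≤ 50, sizes at which every check runs in seconds on one core
while exercising all code paths; nothing in the algorithms depends on those
sizes. All k-means and replicate randomness flows through explicit integer
seeds.

## Known limitations

* The HSP score cutoff (recipe I) and the profile-weight construction
  (recipe IV) are design choices, not externally validated values.
* The symmetry correction is a single sweep; pathological configurations
  could in principle oscillate if iterated, which is one reason not to.
* Validity indices on the embedding coordinates reflect the geometry the
  clustering saw, not the raw score space (a flag allows kernel-row space).
* With many isolated sequences, a thresholded kernel's affinity graph has
  more connected components than k, and the top-k eigenbasis of the
  normalized affinity is then ill-determined within its degenerate
  eigenspace — recipe I's weak benchmark performance is exactly this
  failure mode, not a numerical artifact.
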