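"""Scoring clusterings against true protein families.

Per-family retrieval quality is measured with ROC (area under the curve,
equivalently the Mann-Whitney probability that a random family member
outranks a random non-member, ties counting one half) and ROC50 (the area
accumulated only until the 50th false positive, normalized so a perfect
ranking scores 1 — the stringent standard for ranked homolog retrieval).
Because a hard clustering carries no per-sequence score, each family is
matched to the cluster with the largest overlap and every sequence is
scored by its mean kernel similarity to that cluster's members.

Paired kernel variants are compared with the Wilcoxon signed-rank test
(exact enumeration for small samples, normal approximation with tie and
continuity corrections otherwise), and cluster geometry is summarized with
five validity indices: Dunn (higher is better), Davies-Bouldin (lower),
Goodman-Kruskal gamma, Rand, and Jaccard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics.cluster import pair_confusion_matrix

from .kernels import Kernel
from .spectral import Clustering, SpectralEmbedding, embed

__all__ = [
    "FamilyLabels",
    "WilcoxonResult",
    "EvaluationReport",
    "family_scores",
    "roc_auc",
    "roc50",
    "wilcoxon_signed_rank",
    "rand_index",
    "jaccard_index",
    "dunn_index",
    "davies_bouldin_index",
    "goodman_kruskal_index",
    "evaluate",
]


@dataclass
class FamilyLabels:
    """True family assignment: ID -> family name."""

    mapping: dict[str, str]

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for fam in self.mapping.values():
            seen.setdefault(fam)
        return list(seen)

    def members(self, family: str) -> list[str]:
        return [sid for sid, fam in self.mapping.items() if fam == family]

    def to_clustering(self, ids: Sequence[str]) -> Clustering:
        """View the family labels as a Clustering over the given ID order."""
        fams = self.families
        fam_index = {f: i for i, f in enumerate(fams)}
        labels = np.array([fam_index[self.mapping[sid]] for sid in ids])
        return Clustering(list(ids), labels, k=len(fams), source="truth")


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+: rank sum of positive differences
    p_value: float
    median_diff: float
    n_used: int  # non-zero differences entering the test
    all_zero: bool = False
    exact: bool = True


@dataclass
class EvaluationReport:
    """Per-family ROC/ROC50, their means, and the validity indices."""

    per_family_roc: dict[str, float]
    per_family_roc50: dict[str, float]
    mean_roc: float
    mean_roc50: float
    indices: dict[str, float]
    n_families: int


def family_scores(
    kernel: Kernel,
    clustering: Clustering,
    labels: FamilyLabels,
    family: str,
) -> dict[str, float]:
    """Score every sequence against the cluster matched to one family.

    The family's predicted cluster is the one overlapping most of its true
    members (ties: larger cluster, then lower index); each sequence scores
    its mean kernel similarity to that cluster's members, excluding itself.
    A sequence whose predicted cluster contains only itself scores 0.
    """
    members = set(labels.members(family))
    if not members:
        raise ValueError(f"family {family!r} has no members")
    idx = {sid: i for i, sid in enumerate(kernel.ids)}
    sizes = clustering.cluster_sizes()
    overlaps = np.zeros(clustering.k, dtype=int)
    for sid, lab in zip(clustering.ids, clustering.labels):
        if sid in members:
            overlaps[lab] += 1
    # maximal overlap; ties -> larger cluster, then lower index
    order = sorted(
        range(clustering.k), key=lambda c: (-overlaps[c], -sizes[c], c)
    )
    predicted = order[0]
    cluster_ids = [sid for sid, lab in zip(clustering.ids, clustering.labels) if lab == predicted]
    cluster_rows = np.array([idx[sid] for sid in cluster_ids])
    scores: dict[str, float] = {}
    for sid in kernel.ids:
        i = idx[sid]
        rows = cluster_rows[cluster_rows != i]
        scores[sid] = float(kernel.values[i, rows].mean()) if rows.size else 0.0
    return scores


def _split_scores(
    scores: Mapping[str, float], positives: Iterable[str]
) -> tuple[np.ndarray, np.ndarray]:
    pos = set(positives)
    p = np.array([v for sid, v in scores.items() if sid in pos], dtype=float)
    n = np.array([v for sid, v in scores.items() if sid not in pos], dtype=float)
    if p.size == 0 or n.size == 0:
        raise ValueError("need at least one positive and one negative")
    return p, n


def roc_auc(scores: Mapping[str, float], positives: Iterable[str]) -> float:
    """Area under the ROC curve in Mann-Whitney form (ties count one half)."""
    p, n = _split_scores(scores, positives)
    ranks = stats.rankdata(np.concatenate([p, n]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * n.size))


def roc50(
    scores: Mapping[str, float], positives: Iterable[str], max_fp: int = 50
) -> float:
    """ROC area truncated at the ``max_fp``-th false positive, normalized to [0, 1].

    Sequences are ranked by descending score with ties broken by ID order;
    the area sums, over each of the first ``min(N, max_fp)`` false positives,
    the number of true positives already retrieved, normalized by
    ``P * min(N, max_fp)`` so a perfect ranking scores 1.  With at most
    ``max_fp`` negatives (and no score ties) this equals :func:`roc_auc`.
    """
    pos = set(positives)
    p, n = _split_scores(scores, pos)  # validates
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    fp_budget = min(n.size, max_fp)
    tp = fp = 0
    area = 0
    for sid, _ in ranked:
        if sid in pos:
            tp += 1
        else:
            fp += 1
            area += tp
            if fp == fp_budget:
                break
    return float(area / (p.size * fp_budget))


def wilcoxon_signed_rank(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two_sided",
    exact_max_n: int = 12,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon convention); absolute differences
    are ranked with mid-rank ties and the statistic is W+, the rank sum of
    positive differences.  For up to ``exact_max_n`` non-zero differences the
    p-value is exact, by enumerating the W+ distribution over all 2^n sign
    patterns (conditioned on the observed tied ranks); beyond that, a normal
    approximation with tie and continuity corrections is used.  If every
    difference is zero the result is flagged with p = 1.
    """
    if alternative not in ("two_sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("a and b must be equal-length non-empty 1-D sequences")
    diffs = a - b
    median_diff = float(np.median(diffs))
    d = diffs[diffs != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, median_diff, 0, all_zero=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        # subset-sum distribution of W+ over all sign patterns; ranks are
        # half-integers under mid-rank ties, so double to integers
        r2 = np.rint(2.0 * ranks).astype(np.int64)
        counts = np.zeros(int(r2.sum()) + 1, dtype=np.int64)
        counts[0] = 1
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        total = float(2**n)
        w2 = int(np.rint(2.0 * w_plus))
        p_greater = counts[w2:].sum() / total
        p_less = counts[: w2 + 1].sum() / total
        if alternative == "greater":
            p = p_greater
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return WilcoxonResult(w_plus, float(p), median_diff, n, exact=True)

    mn = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / 48.0
    se = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if alternative == "greater":
        z = (w_plus - mn - 0.5) / se
        p = stats.norm.sf(z)
    else:
        dev = w_plus - mn
        z = (dev - 0.5 * np.sign(dev)) / se if dev != 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
    return WilcoxonResult(w_plus, float(min(p, 1.0)), median_diff, n, exact=False)


def _aligned_labels(c1: Clustering, c2: Clustering) -> tuple[np.ndarray, np.ndarray]:
    if set(c1.ids) != set(c2.ids):
        raise ValueError("clusterings cover different ID sets")
    order2 = {sid: i for i, sid in enumerate(c2.ids)}
    l1 = c1.labels
    l2 = np.array([c2.labels[order2[sid]] for sid in c1.ids])
    return l1, l2


def rand_index(c1: Clustering, c2: Clustering) -> float:
    """Fraction of ID pairs on which the two partitions agree (together/apart)."""
    l1, l2 = _aligned_labels(c1, c2)
    C = pair_confusion_matrix(l1, l2).astype(float)
    total = C.sum()
    if total == 0:  # single ID: no pairs to compare
        return 1.0
    return float((C[0, 0] + C[1, 1]) / total)


def jaccard_index(c1: Clustering, c2: Clustering) -> float:
    """Co-clustered pairs in both partitions over co-clustered pairs in either.

    If neither partition co-clusters any pair the index is degenerate and
    defined as 1.0 (the partitions agree vacuously).
    """
    l1, l2 = _aligned_labels(c1, c2)
    C = pair_confusion_matrix(l1, l2).astype(float)
    denom = C[1, 1] + C[1, 0] + C[0, 1]
    if denom == 0:
        return 1.0
    return float(C[1, 1] / denom)


def _cluster_points(
    points: np.ndarray, clustering: Clustering
) -> list[np.ndarray]:
    points = np.asarray(points, dtype=float)
    return [points[clustering.labels == c] for c in range(clustering.k)
            if (clustering.labels == c).any()]


def dunn_index(points: np.ndarray, clustering: Clustering) -> float:
    """min inter-cluster (single-linkage) distance / max cluster diameter."""
    groups = _cluster_points(points, clustering)
    if len(groups) < 2:
        raise ValueError("Dunn index needs at least two non-empty clusters")
    diameters = [pdist(g).max() if g.shape[0] > 1 else 0.0 for g in groups]
    max_diam = max(diameters)
    if max_diam == 0.0:
        raise ValueError("all clusters degenerate (zero diameter)")
    min_inter = min(
        cdist(groups[i], groups[j]).min()
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    )
    return float(min_inter / max_diam)


def davies_bouldin_index(points: np.ndarray, clustering: Clustering) -> float:
    """Mean over clusters of the worst (s_i + s_j) / d(c_i, c_j) ratio.

    s is the mean member-to-centroid distance and d the centroid distance;
    lower values mean tighter, better-separated clusters.
    """
    groups = _cluster_points(points, clustering)
    if len(groups) < 2:
        raise ValueError("Davies-Bouldin index needs at least two clusters")
    cents = np.array([g.mean(axis=0) for g in groups])
    scatter = np.array([np.linalg.norm(g - c, axis=1).mean() for g, c in zip(groups, cents)])
    D = cdist(cents, cents)
    m = len(groups)
    worst = np.zeros(m)
    for i in range(m):
        ratios = [
            (scatter[i] + scatter[j]) / D[i, j] for j in range(m) if j != i and D[i, j] > 0
        ]
        if not ratios:
            raise ValueError("coincident centroids make Davies-Bouldin undefined")
        worst[i] = max(ratios)
    return float(worst.mean())


def goodman_kruskal_index(points: np.ndarray, clustering: Clustering) -> float:
    """Goodman-Kruskal gamma over (within, between) distance comparisons.

    Every within-cluster distance is compared with every between-cluster
    distance; comparisons with the within distance strictly smaller are
    concordant (S+), strictly larger discordant (S-), and gamma is
    (S+ - S-) / (S+ + S-) in [-1, 1].
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    i, j = np.triu_indices(n, k=1)
    d = pdist(points)
    within_mask = clustering.labels[i] == clustering.labels[j]
    wd = np.sort(d[within_mask])
    bd = d[~within_mask]
    if wd.size == 0 or bd.size == 0:
        raise ValueError("need both within- and between-cluster distance pairs")
    s_plus = int(np.searchsorted(wd, bd, side="left").sum())
    s_minus = int((wd.size - np.searchsorted(wd, bd, side="right")).sum())
    if s_plus + s_minus == 0:
        raise ValueError("all distance comparisons tied")
    return float((s_plus - s_minus) / (s_plus + s_minus))


def evaluate(
    kernel: Kernel,
    clustering: Clustering,
    labels: FamilyLabels,
    embedding: SpectralEmbedding | None = None,
    index_space: str = "embedding",
) -> EvaluationReport:
    """Full evaluation: per-family ROC/ROC50 plus the five validity indices.

    Geometric indices (Dunn, Davies-Bouldin, Goodman-Kruskal) are computed on
    the spectral embedding coordinates used for clustering (recomputed from
    the kernel if not supplied), or on raw kernel rows with
    ``index_space="kernel_rows"``; Rand and Jaccard compare the clustering
    with the true family partition.  Families covering zero or all sequences
    are skipped for ROC (no ranking is defined); degenerate geometric indices
    are reported as NaN.
    """
    if index_space not in ("embedding", "kernel_rows"):
        raise ValueError(f"unknown index_space {index_space!r}")
    ids = kernel.ids
    known = [sid for sid in ids if sid in labels.mapping]
    if len(known) != len(ids):
        raise ValueError(f"{len(ids) - len(known)} IDs lack a family label")
    if embedding is None:
        embedding = embed(kernel, clustering.k)
    index_points = (
        embedding.coordinates if index_space == "embedding" else kernel.values
    )

    per_roc: dict[str, float] = {}
    per_roc50: dict[str, float] = {}
    for family in labels.families:
        members = [sid for sid in ids if labels.mapping[sid] == family]
        if not members or len(members) == len(ids):
            continue
        scores = family_scores(kernel, clustering, labels, family)
        per_roc[family] = roc_auc(scores, members)
        per_roc50[family] = roc50(scores, members)

    truth = labels.to_clustering(ids)
    indices: dict[str, float] = {
        "rand": rand_index(clustering, truth),
        "jaccard": jaccard_index(clustering, truth),
    }
    for name, fn in (
        ("dunn", dunn_index),
        ("davies_bouldin", davies_bouldin_index),
        ("goodman_kruskal", goodman_kruskal_index),
    ):
        try:
            indices[name] = fn(index_points, clustering)
        except ValueError:
            indices[name] = float("nan")

    mean_roc = float(np.mean(list(per_roc.values()))) if per_roc else float("nan")
    mean_roc50 = float(np.mean(list(per_roc50.values()))) if per_roc50 else float("nan")
    return EvaluationReport(
        per_family_roc=per_roc,
        per_family_roc50=per_roc50,
        mean_roc=mean_roc,
        mean_roc50=mean_roc50,
        indices=indices,
        n_families=len(per_roc),
    )
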