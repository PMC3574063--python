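"""Modified point-symmetry proximity norm and cluster reassignment.

Euclidean-style distances cannot see symmetrical overlapping clusters: a
point on the far side of a cluster is Euclidean-far from most members yet
clearly belongs if the cluster is symmetric about its centroid.  The
point-symmetry distance reflects the point through the candidate centroid,
``x* = 2c - x``, and asks how close x* falls to actual data: the symmetry
term ``d_sym`` is the mean Euclidean distance from x* to its ``knear``
nearest data points.  The modified norm rescales it by the point-centroid
distance,

    d_ms(x, c) = d_sym(x, c) * ||x - c||,

which amplifies outliers (their reflection lands in empty space AND they
sit far from every centroid) while vanishing for points at the centroid or
with a data point at their mirror position.

``reassign`` applies the norm as a single-pass post-hoc correction to a
spectral clustering: a point moves to the cluster minimizing d_ms whenever
that minimum clears a threshold theta; otherwise it keeps its spectral
label.  All geometry lives in the spectral embedding (Hilbert) space, whose
Gram matrix is PSD because the embedding comes from a PSD kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .spectral import Clustering, SpectralEmbedding, compute_centroids

__all__ = [
    "SymmetryParams",
    "SymmetryScore",
    "reflect",
    "sym_distance",
    "modified_symmetry_matrix",
    "reassign",
    "singleton_count",
]


@dataclass
class SymmetryParams:
    """Tuning knobs for the symmetry norm and the reassignment gate.

    ``knear=1`` recovers the first-nearest-neighbor form of the symmetry
    distance; the default 2 averages the two nearest neighbors of the
    reflected point.  ``theta=None`` picks a data-adaptive threshold: the
    ``theta_percentile`` percentile of every point's best (minimum over
    clusters) d_ms, so the gate stays meaningful across embedding scales.
    """

    knear: int = 2
    theta: float | None = None
    exclude_self: bool = True
    theta_percentile: float = 90.0

    def __post_init__(self) -> None:
        if self.knear < 1:
            raise ValueError("knear must be >= 1")
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive")


@dataclass
class SymmetryScore:
    """The symmetry diagnostics of one point against one cluster."""

    point_id: str
    cluster: int
    reflected_point: np.ndarray
    d_sym: float
    d_euclid: float
    d_ms: float
    truncated: bool = False  # fewer than knear candidate points were available


def reflect(point: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Mirror image of ``point`` through ``centroid``: ``2 c - x`` (an involution)."""
    point = np.asarray(point, dtype=float)
    centroid = np.asarray(centroid, dtype=float)
    if point.shape != centroid.shape:
        raise ValueError(
            f"dimension mismatch: point {point.shape} vs centroid {centroid.shape}"
        )
    return 2.0 * centroid - point


def _centroids_for(embedding: SpectralEmbedding, clustering: Clustering) -> np.ndarray:
    if clustering.centroids is not None:
        return np.asarray(clustering.centroids, dtype=float)
    return compute_centroids(embedding.coordinates, clustering.labels, clustering.k)


def sym_distance(
    point_id: str,
    cluster: int,
    embedding: SpectralEmbedding,
    clustering: Clustering,
    params: SymmetryParams | None = None,
) -> SymmetryScore:
    """Modified symmetry distance of one point to one cluster centroid.

    Nearest-neighbor candidates for the reflected point are *all* clustered
    points (not just the candidate cluster's members), excluding the query
    itself when ``exclude_self``.  If fewer than ``knear`` candidates exist,
    all of them are used and the score is flagged ``truncated``.
    """
    params = params or SymmetryParams()
    X = embedding.coordinates
    idx = embedding.ids.index(point_id)
    centroids = _centroids_for(embedding, clustering)
    if not 0 <= cluster < clustering.k:
        raise ValueError(f"cluster {cluster} out of range [0, {clustering.k})")
    c = centroids[cluster]
    x = X[idx]
    star = reflect(x, c)
    dists = np.linalg.norm(X - star, axis=1)
    if params.exclude_self:
        dists = np.delete(dists, idx)
    truncated = dists.size < params.knear
    take = min(params.knear, dists.size)
    if take == 0:
        raise ValueError("no candidate points available for the symmetry distance")
    d_sym = float(np.sort(dists)[:take].mean())
    d_euclid = float(np.linalg.norm(x - c))
    return SymmetryScore(
        point_id=point_id,
        cluster=cluster,
        reflected_point=star,
        d_sym=d_sym,
        d_euclid=d_euclid,
        d_ms=d_sym * d_euclid,
        truncated=truncated,
    )


def modified_symmetry_matrix(
    embedding: SpectralEmbedding,
    clustering: Clustering,
    params: SymmetryParams | None = None,
) -> np.ndarray:
    """The n x k matrix of d_ms values of every point against every centroid."""
    params = params or SymmetryParams()
    X = embedding.coordinates
    n = X.shape[0]
    centroids = _centroids_for(embedding, clustering)
    out = np.zeros((n, clustering.k))
    for c in range(clustering.k):
        if np.isnan(centroids[c]).any():
            out[:, c] = np.inf  # empty cluster: never a reassignment target
            continue
        star = 2.0 * centroids[c] - X  # reflections of every point at once
        D = cdist(star, X)
        if params.exclude_self:
            np.fill_diagonal(D, np.inf)
        take = min(params.knear, n - int(params.exclude_self))
        if take < 1:
            raise ValueError("no candidate points available for the symmetry distance")
        near = np.partition(D, take - 1, axis=1)[:, :take]
        d_sym = near.mean(axis=1)
        d_euclid = np.linalg.norm(X - centroids[c], axis=1)
        out[:, c] = d_sym * d_euclid
    return out


def reassign(
    embedding: SpectralEmbedding,
    clustering: Clustering,
    params: SymmetryParams | None = None,
    with_audit: bool = False,
):
    """Single-pass symmetry-gated reassignment of a spectral clustering.

    Each point's d_ms against every centroid is computed from the *current*
    labels; a point moves to (or stays in) the argmin cluster when its
    minimum d_ms is below theta, ties going to the lowest cluster index;
    otherwise it keeps its spectral label.  Centroids are recomputed once
    after the sweep.  The number of distinct labels never increases.

    With ``with_audit=True`` also returns a pandas DataFrame with one row per
    point: old/new label, best d_ms, and the gate decision.
    """
    import pandas as pd

    params = params or SymmetryParams()
    dms = modified_symmetry_matrix(embedding, clustering, params)
    best = dms.min(axis=1)
    argbest = dms.argmin(axis=1)  # ties -> lowest index
    theta = params.theta
    if theta is None:
        finite = best[np.isfinite(best)]
        theta = float(np.percentile(finite, params.theta_percentile)) if finite.size else 0.0
    moved_mask = best < theta
    new_labels = np.where(moved_mask, argbest, clustering.labels)
    centroids = compute_centroids(embedding.coordinates, new_labels, clustering.k)
    corrected = Clustering(
        ids=list(clustering.ids),
        labels=new_labels,
        k=clustering.k,
        centroids=centroids,
        source="symmetry_corrected",
    )
    if not with_audit:
        return corrected
    audit = pd.DataFrame(
        {
            "id": clustering.ids,
            "old_label": clustering.labels,
            "new_label": new_labels,
            "d_ms": best,
            "gated": moved_mask,
            "theta": theta,
        }
    )
    return corrected, audit


def singleton_count(clustering: Clustering) -> int:
    """Number of clusters with exactly one member (unassigned-homolog outliers)."""
    sizes = np.bincount(clustering.labels, minlength=clustering.k)
    return int((sizes == 1).sum())
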