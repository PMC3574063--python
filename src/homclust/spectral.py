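"""Ng-Jordan-Weiss spectral clustering over a kernel matrix.

The kernel is read as the affinity matrix of a weighted graph, normalized
symmetrically, ``L = D^{-1/2} K D^{-1/2}`` with ``D`` the diagonal degree
matrix; the eigenvectors of the k largest eigenvalues of L, row-normalized
to the unit sphere, embed the sequences; seeded k-means partitions the
embedding.  On an affinity that is exactly block-constant with k blocks the
embedding collapses each block to a single point, so the blocks are
recovered for any seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .kernels import Kernel

__all__ = [
    "SpectralEmbedding",
    "Clustering",
    "normalized_affinity",
    "embed",
    "kmeans",
    "spectral_cluster",
]


@dataclass
class SpectralEmbedding:
    """Row-normalized top-k eigenvector coordinates for each sequence."""

    ids: list[str]
    coordinates: np.ndarray  # n x k
    k: int
    zero_rows: np.ndarray | None = None  # rows that were exactly zero pre-normalization

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape[0] != len(self.ids):
            raise ValueError("coordinate rows must match ids")
        if self.zero_rows is None:
            self.zero_rows = np.zeros(len(self.ids), dtype=bool)


@dataclass
class Clustering:
    """Hard assignment of each ID to one of k clusters.

    ``centroids`` (k x dim), when present, are the means of the members'
    embedding rows.  ``source`` records whether the labels come straight from
    spectral k-means or from the symmetry correction.
    """

    ids: list[str]
    labels: np.ndarray  # int array aligned with ids
    k: int
    centroids: np.ndarray | None = None
    source: str = "spectral"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.ids),):
            raise ValueError("labels must align with ids")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels must lie in [0, k)")

    @property
    def label_map(self) -> dict[str, int]:
        return dict(zip(self.ids, self.labels.tolist()))

    def members(self, cluster: int) -> list[str]:
        return [sid for sid, lab in zip(self.ids, self.labels) if lab == cluster]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def compute_centroids(points: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Mean member coordinates per cluster; empty clusters get NaN rows."""
    dim = points.shape[1]
    centroids = np.full((k, dim), np.nan)
    for c in range(k):
        mask = labels == c
        if mask.any():
            centroids[c] = points[mask].mean(axis=0)
    return centroids


def normalized_affinity(kernel: Kernel, clip_tol: float = 0.25) -> np.ndarray:
    """Symmetric normalization ``D^{-1/2} K D^{-1/2}`` of a similarity kernel.

    The kernel is read as graph affinity, which must be non-negative.  PSD
    projection of thresholded score matrices legitimately leaves small
    negative entries; a negative similarity carries no affinity mass, so
    negatives are clipped to 0.  Entries more negative than ``clip_tol``
    times the largest entry indicate the input is not a similarity matrix
    and raise, as does a zero row sum (an isolated vertex, named).
    """
    K = kernel.values.copy()
    scale = max(np.abs(K).max(), 1e-30)
    if K.min() < -clip_tol * scale:
        raise ValueError(
            f"kernel has strongly negative entries (min {K.min():g}); "
            "it does not look like a similarity/affinity matrix"
        )
    K[K < 0.0] = 0.0
    d = K.sum(axis=1)
    dead = np.nonzero(d <= 0.0)[0]
    if dead.size:
        raise ValueError(
            f"zero affinity row sum for IDs {[kernel.ids[i] for i in dead[:5]]}"
        )
    inv = 1.0 / np.sqrt(d)
    L = K * np.outer(inv, inv)
    return (L + L.T) / 2.0


def embed(kernel: Kernel, k: int) -> SpectralEmbedding:
    """Top-k eigenvector embedding of the normalized affinity.

    Eigenvectors of the k algebraically largest eigenvalues are taken
    (degenerate eigenvalues broken by ascending solver index), each column's
    sign fixed so its first non-negligible coordinate is positive, and rows
    scaled to unit Euclidean norm.  Rows that are exactly zero are flagged
    and left at the origin.
    """
    n = kernel.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    L = normalized_affinity(kernel)
    w, V = np.linalg.eigh(L)
    order = np.argsort(-w, kind="stable")[:k]
    U = V[:, order].copy()
    # deterministic sign: first coordinate above noise level made positive
    for j in range(k):
        col = U[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12 * max(np.abs(col).max(), 1e-30))[0]
        if nz.size and col[nz[0]] < 0:
            U[:, j] = -col
    norms = np.linalg.norm(U, axis=1)
    zero_rows = norms <= 1e-12
    safe = np.where(zero_rows, 1.0, norms)
    coords = U / safe[:, None]
    coords[zero_rows] = 0.0
    return SpectralEmbedding(kernel.ids, coords, k=k, zero_rows=zero_rows)


def kmeans(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
    ids: list[str] | None = None,
) -> Clustering:
    """Seeded k-means++ with multiple restarts; best inertia kept.

    Deterministic given the seed.  ``sklearn`` repairs empty clusters by
    reseeding them to the point farthest from its center.  Reported
    centroids are recomputed exactly as member means.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(points)
    labels = km.labels_.astype(int)
    centroids = compute_centroids(points, labels, k)
    # a cluster can end up empty only pathologically; fall back to sklearn's center
    nan_rows = np.isnan(centroids).any(axis=1)
    if nan_rows.any():
        centroids[nan_rows] = km.cluster_centers_[nan_rows]
    return Clustering(ids, labels, k=k, centroids=centroids, source="spectral")


def spectral_cluster(
    kernel: Kernel,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
    return_embedding: bool = False,
):
    """Full NJW pipeline: normalized affinity -> top-k embedding -> k-means."""
    embedding = embed(kernel, k)
    clustering = kmeans(
        embedding.coordinates, k, seed=seed, restarts=restarts,
        max_iter=max_iter, tol=tol, ids=kernel.ids,
    )
    if return_embedding:
        return clustering, embedding
    return clustering
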