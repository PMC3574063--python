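"""Turning raw alignment-score matrices into valid Mercer kernels.

Raw all-vs-all similarity scores are neither symmetric (an A-vs-B search
does not score like B-vs-A) nor positive semidefinite, so they are not
kernels.  The constructors here apply the canonical repair chain:

1. symmetrize, ``(S + S^T) / 2``;
2. project to the PSD cone by eigendecomposing and clamping negative
   eigenvalues to zero (for a symmetric matrix this is the nearest PSD
   matrix in Frobenius norm);
3. normalize — onto the unit sphere, ``K'_{ij} = K_{ij} / sqrt(K_{ii} K_{jj})``,
   or affinely into [0, 1].

Two concrete local-alignment kernels are provided: ``blastp_kernel`` (HSP
bit scores thresholded at a cutoff) and ``psiblast_kernel`` (profile search
scores used as-is), plus ``combine``, the Hadamard (Schur) product closure
that builds combined kernels — PSD is preserved by the Schur product
theorem, and asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .score_io import ScoreMatrix

__all__ = [
    "Kernel",
    "EigenDecomposition",
    "symmetrize",
    "eigendecompose",
    "psd_project",
    "unit_sphere_normalize",
    "minmax_normalize",
    "repair_diagonal",
    "blastp_kernel",
    "psiblast_kernel",
    "combine",
]

#: Relative PSD tolerance: eigensolvers report tiny negative eigenvalues for
#: genuinely PSD matrices; anything above -DEFAULT_PSD_TOL * lambda_max passes.
DEFAULT_PSD_TOL = 1e-8

#: Default HSP bit-score cutoff for the BLASTP kernel.  Conventional "reliable
#: hit" scale for protein searches; not validated against any benchmark and
#: exposed as a parameter everywhere.
DEFAULT_SCORE_CUTOFF = 50.0


@dataclass
class Kernel:
    """Symmetric PSD similarity matrix over an ordered ID index.

    ``normalization`` records provenance: ``raw`` (no normalization),
    ``unit_sphere`` (unit diagonal), or ``minmax`` (entries in [0, 1]).
    """

    ids: list[str]
    values: np.ndarray
    normalization: str = "raw"
    psd_tolerance: float = DEFAULT_PSD_TOL

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {self.values.shape}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        """Assert symmetry, PSD within tolerance, and the normalization contract."""
        K = self.values
        scale = max(np.abs(K).max(), 1.0)
        asym = np.abs(K - K.T).max()
        if asym > 1e-12 * scale:
            raise ValueError(f"kernel not symmetric: max |K - K^T| = {asym:g}")
        w = np.linalg.eigvalsh((K + K.T) / 2.0)
        lam_max = max(w[-1], 0.0)
        if w[0] < -self.psd_tolerance * max(lam_max, 1e-30):
            raise ValueError(
                f"kernel not PSD: min eigenvalue {w[0]:g} vs max {lam_max:g}"
            )
        tol = 1e-8 * scale
        if self.normalization == "unit_sphere":
            if np.abs(np.diag(K) - 1.0).max() > tol:
                raise ValueError("unit_sphere kernel must have unit diagonal")
        elif self.normalization == "minmax":
            if K.min() < -tol or K.max() > 1.0 + tol:
                raise ValueError("minmax kernel entries must lie in [0, 1]")

    def min_eigenvalue_ratio(self) -> float:
        """min eigenvalue / max eigenvalue; >= -psd_tolerance for a valid kernel."""
        w = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        return float(w[0] / max(w[-1], 1e-30))


@dataclass
class EigenDecomposition:
    """Eigenpairs of a symmetric matrix, eigenvalues in descending order."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # orthonormal columns, aligned with eigenvalues

    def reconstruct(self) -> np.ndarray:
        V, w = self.eigenvectors, self.eigenvalues
        return (V * w) @ V.T


def _as_values(matrix: ScoreMatrix | Kernel | np.ndarray) -> np.ndarray:
    if isinstance(matrix, (ScoreMatrix, Kernel)):
        return np.asarray(matrix.values, dtype=float)
    return np.asarray(matrix, dtype=float)


def _ids_of(matrix: ScoreMatrix | Kernel | np.ndarray) -> list[str]:
    if isinstance(matrix, (ScoreMatrix, Kernel)):
        return list(matrix.ids)
    return [str(i) for i in range(np.asarray(matrix).shape[0])]


def symmetrize(matrix: ScoreMatrix) -> ScoreMatrix:
    """Return the symmetric part ``(S + S^T) / 2`` of a square score matrix."""
    values = _as_values(matrix)
    sym = (values + values.T) / 2.0
    return ScoreMatrix(_ids_of(matrix), sym, missing_value=getattr(matrix, "missing_value", 0.0))


def eigendecompose(matrix: ScoreMatrix | Kernel | np.ndarray) -> EigenDecomposition:
    """Symmetric eigendecomposition with eigenvalues sorted descending."""
    values = _as_values(matrix)
    _require_symmetric(values)
    w, V = np.linalg.eigh(values)
    return EigenDecomposition(eigenvalues=w[::-1].copy(), eigenvectors=V[:, ::-1].copy())


def _require_symmetric(values: np.ndarray, what: str = "matrix") -> None:
    scale = max(np.abs(values).max(), 1.0)
    if np.abs(values - values.T).max() > 1e-10 * scale:
        raise ValueError(f"{what} is not symmetric; apply symmetrize() first")


def psd_project(
    matrix: ScoreMatrix | Kernel | np.ndarray, psd_tolerance: float = DEFAULT_PSD_TOL
) -> Kernel:
    """Project a symmetric matrix onto the PSD cone by clamping negative eigenvalues.

    Keeping each eigenvalue if positive and replacing it by 0 otherwise gives
    the closest PSD matrix in Frobenius norm.  Already-PSD inputs are fixed
    points up to floating-point round-off.
    """
    values = _as_values(matrix)
    _require_symmetric(values)
    w, V = np.linalg.eigh(values)
    w_clamped = np.where(w > 0.0, w, 0.0)
    K = (V * w_clamped) @ V.T
    K = (K + K.T) / 2.0  # round-off symmetry repair
    return Kernel(_ids_of(matrix), K, normalization="raw", psd_tolerance=psd_tolerance)


def unit_sphere_normalize(kernel: Kernel) -> Kernel:
    """Normalize onto the unit sphere: ``K'_{ij} = K_{ij} / sqrt(K_{ii} K_{jj})``.

    Equivalent to scaling every implicit feature vector to unit length, so the
    diagonal becomes exactly 1 and PSD is preserved (congruence with a positive
    diagonal matrix).  A non-positive diagonal entry is an error naming the ID.
    """
    d = np.diag(kernel.values).copy()
    bad = np.nonzero(d <= 0.0)[0]
    if bad.size:
        raise ValueError(
            "non-positive diagonal entries for IDs "
            f"{[kernel.ids[i] for i in bad[:5]]}; repair the diagonal first"
        )
    inv = 1.0 / np.sqrt(d)
    K = kernel.values * np.outer(inv, inv)
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    return Kernel(kernel.ids, K, normalization="unit_sphere", psd_tolerance=kernel.psd_tolerance)


def minmax_normalize(kernel: Kernel) -> Kernel:
    """Map entries affinely onto [0, 1], then re-project to PSD.

    The affine shift adds a rank-one all-ones term that can push the spectrum
    negative, so the result is re-projected.  Projection can in turn nudge
    entries slightly outside [0, 1]; a final PSD-safe rescale (adding a
    non-negative multiple of the all-ones matrix and/or dividing by the new
    maximum, both of which preserve PSD) restores the range exactly.
    """
    K = kernel.values
    lo, hi = K.min(), K.max()
    if not hi > lo:
        raise ValueError("constant matrix cannot be min-max normalized")
    scaled = (K - lo) / (hi - lo)
    proj = psd_project(ScoreMatrix(kernel.ids, (scaled + scaled.T) / 2.0),
                       psd_tolerance=kernel.psd_tolerance)
    V = proj.values
    lo2, hi2 = V.min(), V.max()
    if lo2 < 0.0:
        V = (V - lo2) / (hi2 - lo2)  # subtracting lo2 < 0 adds +|lo2|*J: PSD-safe
    elif hi2 > 1.0:
        V = V / hi2
    return Kernel(kernel.ids, V, normalization="minmax",
                  psd_tolerance=kernel.psd_tolerance)


def repair_diagonal(
    matrix: ScoreMatrix,
    strategy: str = "row_max",
    constant: float | None = None,
) -> ScoreMatrix:
    """Overwrite the diagonal to tame diagonal dominance.

    Self-scores from alignment searches are orders of magnitude larger than
    cross scores and would swamp every downstream normalization, so they are
    replaced: ``row_max`` sets ``M(i,i)`` to the largest off-diagonal entry of
    row i (0 for a 1x1 matrix, by the empty-max convention); ``constant`` sets
    the whole diagonal to ``constant``.
    """
    values = _as_values(matrix).copy()
    n = values.shape[0]
    if strategy == "row_max":
        if n == 1:
            values[0, 0] = 0.0
        else:
            off = values.copy()
            np.fill_diagonal(off, -np.inf)
            values[np.diag_indices(n)] = off.max(axis=1)
    elif strategy == "constant":
        if constant is None:
            raise ValueError("strategy 'constant' requires the constant value")
        values[np.diag_indices(n)] = constant
    else:
        raise ValueError(f"unknown diagonal repair strategy {strategy!r}")
    return ScoreMatrix(_ids_of(matrix), values, missing_value=getattr(matrix, "missing_value", 0.0))


def _repair_zero_diagonal(kernel: Kernel) -> Kernel:
    """Give effectively-isolated sequences a unit self-similarity.

    After PSD projection a sequence with no retained hits has a (near-)zero
    row; unit-sphere normalization needs a positive diagonal.  For a PSD
    matrix a zero diagonal entry forces a zero row, so setting that row/column
    to exactly 0 and the diagonal entry to 1 keeps the matrix PSD while making
    the sequence self-similar and dissimilar to everything else.
    """
    K = kernel.values.copy()
    d = np.diag(K)
    scale = max(d.max(), 1.0)
    dead = np.nonzero(d <= 1e-12 * scale)[0]
    if dead.size:
        K[dead, :] = 0.0
        K[:, dead] = 0.0
        K[dead, dead] = 1.0
    return Kernel(kernel.ids, K, normalization=kernel.normalization,
                  psd_tolerance=kernel.psd_tolerance)


def blastp_kernel(
    hsp_matrix: ScoreMatrix, score_cutoff: float = DEFAULT_SCORE_CUTOFF
) -> Kernel:
    """BLASTP HSP-score kernel (kernel I).

    Bit scores below ``score_cutoff`` are zeroed (no reliable homology
    signal), then the matrix is symmetrized, PSD-projected, and unit-sphere
    normalized.  Sequences isolated by the cutoff get unit self-similarity
    and zero similarity to all others.
    """
    values = _as_values(hsp_matrix).copy()
    values[values < score_cutoff] = 0.0
    sym = symmetrize(ScoreMatrix(_ids_of(hsp_matrix), values))
    proj = _repair_zero_diagonal(psd_project(sym))
    return unit_sphere_normalize(proj)


def psiblast_kernel(psi_matrix: ScoreMatrix) -> Kernel:
    """PSI-BLAST score kernel (kernel II).

    The (asymmetric) profile-search score matrix S is symmetrized to
    ``(S + S^T) / 2``, its negative eigenvalues clamped to zero, and the
    result unit-sphere normalized.
    """
    sym = symmetrize(psi_matrix)
    proj = _repair_zero_diagonal(psd_project(sym))
    return unit_sphere_normalize(proj)


def combine(k1: Kernel, k2: Kernel) -> Kernel:
    """Hadamard (Schur) product of two kernels over one ID index.

    Elementwise products of PSD matrices are PSD (Schur product theorem);
    the product is unit-sphere renormalized so combined kernels stay on the
    same scale as their factors.
    """
    if k1.ids != k2.ids:
        only1 = sorted(set(k1.ids) - set(k2.ids))
        only2 = sorted(set(k2.ids) - set(k1.ids))
        raise ValueError(
            f"kernel ID indexes differ (only in first: {only1[:5]}, "
            f"only in second: {only2[:5]}, or ordering differs)"
        )
    prod = k1.values * k2.values
    prod = (prod + prod.T) / 2.0
    out = Kernel(k1.ids, prod, normalization="raw",
                 psd_tolerance=max(k1.psd_tolerance, k2.psd_tolerance))
    return unit_sphere_normalize(_repair_zero_diagonal(out))
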