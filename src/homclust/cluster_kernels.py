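"""Markov-cluster-style similarity normalization and neighborhood kernels.

The OrthoMCL weighting scheme builds a symmetric graph from averaged
-log10 E-values and divides each edge by the mean weight of its species
pair, damping the excess similarity of recent within-species paralogs so
that cross-species remote homologs stand out.

On top of that normalized similarity, two kernels average over sequence
neighborhoods (the set of database sequences hit below an E-value
threshold):

* the neighborhood similarity kernel replaces each sequence's implicit
  feature vector by the mean over its neighborhood — the induced kernel is
  the double average ``K_nb(x, y) = mean over x' in N(x), y' in N(y) of
  K(x', y')`` and needs no explicit feature vectors;
* the mismatch profile kernel generalizes the flat average to
  probability-weighted neighbors (weights proportional to profile-search
  scores), and reduces exactly to the neighborhood kernel when the weights
  are uniform.

Both are PSD-projected and min-max normalized into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import Kernel, minmax_normalize, psd_project
from .score_io import PairScoreTable, ScoreMatrix, SpeciesMap

__all__ = [
    "NeighborhoodMap",
    "ProfileWeights",
    "build_neighborhoods",
    "orthomcl_normalize",
    "neighborhood_average",
    "neighborhood_kernel",
    "mismatch_profile_kernel",
    "profile_weights_from_scores",
]

#: Conventional E-value cutoff for neighborhood membership.
DEFAULT_EVALUE_THRESHOLD = 0.05


@dataclass
class NeighborhoodMap:
    """For each sequence, the set of sequences it hits below an E-value threshold.

    Every sequence is a member of its own neighborhood, so neighborhoods are
    never empty and the degenerate (all-singleton) map reproduces the base
    kernel.
    """

    neighbors: dict[str, tuple[str, ...]]
    evalue_threshold: float

    def __post_init__(self) -> None:
        for sid, members in self.neighbors.items():
            if sid not in members:
                raise ValueError(f"{sid!r} missing from its own neighborhood")

    def sizes(self) -> dict[str, int]:
        return {sid: len(members) for sid, members in self.neighbors.items()}


@dataclass
class ProfileWeights:
    """Per-sequence probability weights over its neighborhood (each sums to 1)."""

    weights: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for sid, wv in self.weights.items():
            total = sum(wv.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"weights for {sid!r} sum to {total}, not 1")
            if any(w < 0 for w in wv.values()):
                raise ValueError(f"negative weight for {sid!r}")

    @classmethod
    def uniform(cls, nbhd: NeighborhoodMap) -> "ProfileWeights":
        """Flat weights over each neighborhood (recovers the neighborhood kernel)."""
        return cls(
            {
                sid: {m: 1.0 / len(members) for m in members}
                for sid, members in nbhd.neighbors.items()
            }
        )


def build_neighborhoods(
    table: PairScoreTable,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    ids: list[str] | None = None,
) -> NeighborhoodMap:
    """Neighborhoods from query->subject hits with E-value below the threshold.

    Membership is directional: ``y in N(x)`` iff some hit x -> y scores below
    the threshold (plus x itself).  Members are kept sorted for determinism.
    """
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be positive")
    universe = list(ids) if ids is not None else table.id_universe
    members: dict[str, set[str]] = {sid: {sid} for sid in universe}
    for rec in table.records:
        if rec.e_value < evalue_threshold:
            members.setdefault(rec.query_id, {rec.query_id}).add(rec.subject_id)
            members.setdefault(rec.subject_id, {rec.subject_id})
    return NeighborhoodMap(
        {sid: tuple(sorted(ms)) for sid, ms in members.items()},
        evalue_threshold=evalue_threshold,
    )


def orthomcl_normalize(weights: ScoreMatrix, species: SpeciesMap) -> ScoreMatrix:
    """Divide each edge weight by the mean positive weight of its species pair.

    For every unordered species pair (s, t) — including s = t, the
    within-species (paralog) case — the mean m(s, t) is taken over positive
    off-diagonal weights between sequences of s and t, and every cell of that
    block (diagonal included) is divided by it.  Blocks with no positive
    weight are left untouched.  Rescaling one species pair by c > 0 therefore
    cancels.  A symmetric input is expected (symmetrize first).
    """
    missing = [sid for sid in weights.ids if sid not in species]
    if missing:
        raise ValueError(f"IDs missing from species map: {missing[:5]}")
    sp = np.array([species[sid] for sid in weights.ids])
    V = weights.values
    out = V.copy()
    tags = sorted(set(sp))
    offdiag = ~np.eye(len(sp), dtype=bool)
    for a_i, s in enumerate(tags):
        in_s = sp == s
        for t in tags[a_i:]:
            in_t = sp == t
            block = np.outer(in_s, in_t) | np.outer(in_t, in_s)
            sample = block & offdiag & (V > 0)
            if not sample.any():
                continue
            m = V[sample].mean()
            out[block] = V[block] / m
    return ScoreMatrix(weights.ids, out, missing_value=weights.missing_value)


def _weight_matrix(
    ids: list[str], nbhd: NeighborhoodMap, profile: ProfileWeights | None
) -> np.ndarray:
    """Row-stochastic averaging matrix W with W[x, x'] = weight of x' for x."""
    idx = {sid: i for i, sid in enumerate(ids)}
    n = len(ids)
    W = np.zeros((n, n))
    for sid in ids:
        if sid not in nbhd.neighbors:
            raise ValueError(f"{sid!r} missing from the neighborhood map")
        members = nbhd.neighbors[sid]
        if profile is None:
            w = {m: 1.0 / len(members) for m in members}
        else:
            w = profile.weights[sid]
            outside = set(w) - set(members)
            if outside:
                raise ValueError(
                    f"profile weights for {sid!r} assign mass outside its "
                    f"neighborhood: {sorted(outside)[:5]}"
                )
        for m, v in w.items():
            if m not in idx:
                raise ValueError(f"neighbor {m!r} not in the kernel ID index")
            W[idx[sid], idx[m]] = v
    return W


def neighborhood_average(
    base: Kernel, nbhd: NeighborhoodMap, profile: ProfileWeights | None = None
) -> np.ndarray:
    """The raw double average ``W K W^T`` before projection/normalization.

    With singleton neighborhoods (and no profile) this is exactly the base
    kernel; every entry lies in the convex hull of the base kernel's values.
    """
    W = _weight_matrix(base.ids, nbhd, profile)
    K = W @ base.values @ W.T
    return (K + K.T) / 2.0


def neighborhood_kernel(base: Kernel, nbhd: NeighborhoodMap) -> Kernel:
    """Neighborhood similarity kernel (kernel III over the OrthoMCL base).

    Averages the base kernel over neighborhood pairs, re-projects to PSD,
    and min-max normalizes into [0, 1].
    """
    avg = neighborhood_average(base, nbhd)
    proj = psd_project(ScoreMatrix(base.ids, avg), psd_tolerance=base.psd_tolerance)
    return minmax_normalize(proj)


def mismatch_profile_kernel(
    base: Kernel, nbhd: NeighborhoodMap, profile: ProfileWeights
) -> Kernel:
    """Mismatch profile kernel (kernel IV): probability-weighted neighborhood average.

    ``K_mp(x, y) = sum over x' in N(x), y' in N(y) of w_x(x') w_y(y') K(x', y')``,
    then PSD projection and min-max normalization.  Uniform weights reproduce
    :func:`neighborhood_kernel` exactly.
    """
    avg = neighborhood_average(base, nbhd, profile)
    proj = psd_project(ScoreMatrix(base.ids, avg), psd_tolerance=base.psd_tolerance)
    return minmax_normalize(proj)


def profile_weights_from_scores(
    psi_matrix: ScoreMatrix, nbhd: NeighborhoodMap
) -> ProfileWeights:
    """Neighbor weights proportional to (non-negative) profile-search scores.

    ``w_x(x') = max(psi(x, x'), 0) / sum over N(x)``; if every score in the
    neighborhood is non-positive the weights fall back to uniform.
    """
    idx = psi_matrix.index_of()
    V = psi_matrix.values
    weights: dict[str, dict[str, float]] = {}
    for sid, members in nbhd.neighbors.items():
        raw = {m: max(V[idx[sid], idx[m]], 0.0) for m in members}
        total = sum(raw.values())
        if total > 0:
            weights[sid] = {m: v / total for m, v in raw.items()}
        else:
            weights[sid] = {m: 1.0 / len(members) for m in members}
    return ProfileWeights(weights)
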