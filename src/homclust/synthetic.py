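"""Synthetic all-vs-all score matrices with planted family structure.

Real remote-homology benchmarks are all-vs-all search score matrices over
sequences grouped into families, contaminated by exactly the artifacts the
kernel pipeline is built to survive: asymmetric scores (A-vs-B != B-vs-A),
recent-paralog sub-blocks with inflated within-species similarity,
multi-domain "bridge" sequences that score highly against two families at
once (the promiscuous-domain problem), and outlier sequences with no family
signal.  The generator plants each of these deliberately on a [0, 1]
similarity scale:

* same-family pairs score ``within_mean``, cross-family pairs ``between_mean``;
* bridge sequences get ``within_mean`` to BOTH of their families (the truth
  label records an arbitrary primary family — the signal itself is exactly
  ambiguous);
* one random contiguous member pair per family gets ``paralog_boost`` extra;
* outliers score ``between_mean`` against everything and carry the reserved
  truth tag ``"outlier"``;
* symmetric Gaussian noise (``noise_sd``) plus independent per-direction
  Gaussian noise (``asymmetry_sd``) is added and the result clipped at 0.

Helpers convert the similarity scale to pseudo-BLAST statistics
(``bit = bit_scale * s``, ``E = 10^(-evalue_scale * s)``) so the tabular
writer can emit realistic hit files, and a pinned ``default_benchmark``
fixes the study conditions used throughout the test-suite and the
acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .score_io import (
    PairScoreRecord,
    PairScoreTable,
    ScoreMatrix,
    SpeciesMap,
    write_blast_tabular,
    write_matrix_tsv,
    write_two_column_map,
)
from .evaluation import FamilyLabels
from .spectral import Clustering, SpectralEmbedding

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "OUTLIER_TAG",
    "generate",
    "default_benchmark",
    "dataset_to_pair_table",
    "mirror_fixture",
]

#: Reserved truth tag for planted outliers (not a family).
OUTLIER_TAG = "outlier"


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset; all similarity values on a [0, 1] scale."""

    n_families: int = 4
    sizes: tuple[int, ...] = (40, 30, 20, 10)
    within_mean: float = 0.8
    between_mean: float = 0.2
    noise_sd: float = 0.05
    asymmetry_sd: float = 0.02
    n_bridges: int = 4
    n_outliers: int = 5
    paralog_boost: float = 0.15
    n_species: int = 3
    seed: int = 42

    def validate(self) -> None:
        problems = []
        if self.n_families < 1:
            problems.append("n_families must be >= 1")
        if len(self.sizes) != self.n_families:
            problems.append(f"len(sizes)={len(self.sizes)} != n_families={self.n_families}")
        if any(s < 1 for s in self.sizes):
            problems.append("all family sizes must be positive")
        if not self.within_mean > self.between_mean:
            problems.append("within_mean must exceed between_mean")
        if self.noise_sd < 0 or self.asymmetry_sd < 0:
            problems.append("noise levels must be non-negative")
        if self.n_bridges < 0 or self.n_outliers < 0:
            problems.append("bridge/outlier counts must be non-negative")
        if self.paralog_boost < 0:
            problems.append("paralog_boost must be >= 0")
        if self.n_bridges > 0 and self.n_families < 2:
            problems.append("bridges need at least two families")
        if self.n_species < 1:
            problems.append("n_species must be >= 1")
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    @property
    def n_total(self) -> int:
        return sum(self.sizes) + self.n_bridges + self.n_outliers


@dataclass
class SyntheticDataset:
    """A generated benchmark: asymmetric scores, truth labels, species tags."""

    matrix: ScoreMatrix
    truth: FamilyLabels
    species: SpeciesMap
    spec: SyntheticSpec
    bridge_families: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def family_ids(self) -> list[str]:
        """IDs whose truth label is a planted family (bridges included)."""
        return [sid for sid, fam in self.truth.mapping.items() if fam != OUTLIER_TAG]

    @property
    def core_ids(self) -> list[str]:
        """IDs belonging unambiguously to exactly one planted family."""
        return [
            sid
            for sid, fam in self.truth.mapping.items()
            if fam != OUTLIER_TAG and sid not in self.bridge_families
        ]


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate one dataset; deterministic under ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    fam_names = [f"fam{f + 1}" for f in range(spec.n_families)]
    ids: list[str] = []
    truth: dict[str, str] = {}
    fam_of: dict[str, int] = {}
    fam_member_ids: list[list[str]] = []
    for f, (name, size) in enumerate(zip(fam_names, spec.sizes)):
        members = [f"{name}_s{j + 1:03d}" for j in range(size)]
        fam_member_ids.append(members)
        for sid in members:
            truth[sid] = name
            fam_of[sid] = f
        ids.extend(members)

    bridge_families: dict[str, tuple[str, str]] = {}
    for b in range(spec.n_bridges):
        sid = f"bridge{b + 1}"
        f1, f2 = rng.choice(spec.n_families, size=2, replace=False)
        bridge_families[sid] = (fam_names[f1], fam_names[f2])
        truth[sid] = fam_names[f1]  # primary family: an arbitrary convention
        ids.append(sid)

    for o in range(spec.n_outliers):
        sid = f"outlier{o + 1}"
        truth[sid] = OUTLIER_TAG
        ids.append(sid)

    n = len(ids)
    idx = {sid: i for i, sid in enumerate(ids)}
    base = np.full((n, n), spec.between_mean)
    for members in fam_member_ids:
        rows = np.array([idx[sid] for sid in members])
        base[np.ix_(rows, rows)] = spec.within_mean
    fam_index = {name: f for f, name in enumerate(fam_names)}
    for sid, (fa, fb) in bridge_families.items():
        i = idx[sid]
        for fam in (fa, fb):
            fam_rows = [idx[m] for m in fam_member_ids[fam_index[fam]]]
            base[i, fam_rows] = spec.within_mean
            base[fam_rows, i] = spec.within_mean
    np.fill_diagonal(base, spec.within_mean)  # self-similarity is always strong

    # recent-paralog analogue: one contiguous member pair per family scores extra
    if spec.paralog_boost > 0:
        for members in fam_member_ids:
            if len(members) < 2:
                continue
            start = int(rng.integers(0, len(members) - 1))
            i, j = idx[members[start]], idx[members[start + 1]]
            base[i, j] += spec.paralog_boost
            base[j, i] += spec.paralog_boost

    if spec.noise_sd > 0:
        upper = rng.normal(0.0, spec.noise_sd, size=(n, n))
        sym_noise = np.triu(upper, 1)
        sym_noise = sym_noise + sym_noise.T
        base = base + sym_noise
    if spec.asymmetry_sd > 0:
        asym = rng.normal(0.0, spec.asymmetry_sd, size=(n, n))
        np.fill_diagonal(asym, 0.0)
        base = base + asym
    base = np.clip(base, 0.0, None)

    species = SpeciesMap({sid: f"sp{(i % spec.n_species) + 1}" for i, sid in enumerate(ids)})
    return SyntheticDataset(
        matrix=ScoreMatrix(ids, base),
        truth=FamilyLabels(truth),
        species=species,
        spec=spec,
        bridge_families=bridge_families,
    )


def default_benchmark(seed: int = 42) -> SyntheticDataset:
    """The pinned benchmark: 4 families (40, 30, 20, 10), within 0.8, between 0.2,
    noise 0.05, asymmetry 0.02, 4 bridges, 5 outliers, paralog boost 0.15,
    3 species — 109 sequences in total."""
    return generate(SyntheticSpec(seed=seed))


def dataset_to_pair_table(
    dataset: SyntheticDataset,
    bit_scale: float = 100.0,
    evalue_scale: float = 50.0,
    include_self: bool = True,
) -> PairScoreTable:
    """Express the similarity matrix as pseudo-BLAST hits.

    Each positive cell (i, j) becomes one hit with bit score
    ``bit_scale * s`` and E-value ``10^(-evalue_scale * s)``, so the planted
    within/between means map onto a realistic significance gap.
    """
    M = dataset.matrix
    records: list[PairScoreRecord] = []
    for i, qid in enumerate(M.ids):
        for j, sid in enumerate(M.ids):
            if i == j and not include_self:
                continue
            s = M.values[i, j]
            if s <= 0:
                continue
            records.append(
                PairScoreRecord(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=min(100.0, 100.0 * s),
                    align_length=100,
                    e_value=10.0 ** (-evalue_scale * s),
                    bit_score=bit_scale * s,
                )
            )
    return PairScoreTable(records)


def write_dataset(
    dataset: SyntheticDataset,
    out_dir: str | Path,
    bit_scale: float = 100.0,
    evalue_scale: float = 50.0,
) -> dict[str, Path]:
    """Emit matrix TSV, pseudo-BLAST tabular hits, truth TSV, and species TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "scores.tsv",
        "blast": out / "hits.blast.tsv",
        "truth": out / "truth.tsv",
        "species": out / "species.tsv",
    }
    write_matrix_tsv(dataset.matrix, paths["matrix"])
    write_blast_tabular(
        dataset_to_pair_table(dataset, bit_scale=bit_scale, evalue_scale=evalue_scale),
        paths["blast"],
    )
    write_two_column_map(dataset.truth.mapping, paths["truth"])
    write_two_column_map(dataset.species.mapping, paths["species"])
    return paths


def mirror_fixture() -> tuple[SpectralEmbedding, Clustering, str, int]:
    """A hand-built embedding where one point is the exact mirror of another.

    Cluster 0 holds three points with centroid c; the point ``"mirror"`` is
    placed at the exact reflection of a cluster-0 member through c but is
    initially labeled into cluster 1 (three far-away points).  Reflecting
    ``"mirror"`` through cluster 0's centroid therefore lands exactly on a
    data point, so with ``knear=1`` its symmetry distance to cluster 0 is 0
    and reassignment must pull it into cluster 0.

    Returns (embedding, clustering, mirror_id, target_cluster).
    """
    a = np.array([[0.0, 0.0], [2.0, 2.0], [4.0, 0.0]])
    c = a.mean(axis=0)  # (2, 2/3)
    mirror = 2.0 * c - a[0]
    b = np.array([[10.0, 10.0], [10.0, 11.0], [11.0, 10.0]])
    coords = np.vstack([a, mirror[None, :], b])
    ids = ["a1", "a2", "a3", "mirror", "b1", "b2", "b3"]
    labels = np.array([0, 0, 0, 1, 1, 1, 1])
    embedding = SpectralEmbedding(ids, coords, k=2)
    clustering = Clustering(ids, labels, k=2, source="spectral")
    return embedding, clustering, "mirror", 0
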