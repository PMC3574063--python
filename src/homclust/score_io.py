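"""Reading and writing pairwise similarity data.

All-vs-all sequence comparison tools (BLASTP, PSI-BLAST) emit ragged hit
lists; everything downstream wants a square score matrix over one ordered
ID index.  This module parses BLAST tabular output (``-outfmt 6``, twelve
standard columns), assembles score matrices from hit tables, and round-trips
matrices and two-column ID maps through plain TSV files.

Missing pairs (no reported hit) score 0: in the weighted-graph reading of a
similarity matrix, absence of a hit is absence of an edge, and 0 is the
additive identity for the averaging steps applied later.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairScoreRecord",
    "PairScoreTable",
    "ScoreMatrix",
    "SpeciesMap",
    "read_blast_tabular",
    "table_to_matrix",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_two_column_map",
    "write_two_column_map",
]

#: Default cap applied before taking -log10 of an E-value, so that reported
#: E-values of exactly 0 stay finite (-log10 -> 180).
DEFAULT_EVALUE_FLOOR = 1e-180


@dataclass(frozen=True)
class PairScoreRecord:
    """One pairwise hit: query, subject, and the alignment statistics used here."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("query_id and subject_id must be non-empty")
        if self.e_value < 0:
            raise ValueError(f"E-value must be >= 0, got {self.e_value}")
        if self.align_length < 0:
            raise ValueError(f"alignment length must be >= 0, got {self.align_length}")


@dataclass
class PairScoreTable:
    """An ordered list of pairwise hits plus the universe of IDs they mention."""

    records: list[PairScoreRecord] = field(default_factory=list)

    @property
    def id_universe(self) -> list[str]:
        """All query/subject IDs in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.query_id)
            seen.setdefault(rec.subject_id)
        return list(seen)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ScoreMatrix:
    """Square real matrix over an ordered ID index.

    The matrix may be asymmetric (all-vs-all search scores are not symmetric
    for a pair of sequences) and sparse-in-effect: cells for which no hit was
    observed hold ``missing_value``.
    """

    ids: list[str]
    values: np.ndarray
    missing_value: float = 0.0

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate IDs in ScoreMatrix index")
        if self.values.shape != (n, n):
            raise ValueError(
                f"values must be {n}x{n} to match ids, got {self.values.shape}"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self) -> dict[str, int]:
        return {sid: i for i, sid in enumerate(self.ids)}

    def is_symmetric(self, rtol: float = 1e-12) -> bool:
        scale = max(np.abs(self.values).max(), 1.0)
        return bool(np.abs(self.values - self.values.T).max() <= rtol * scale)


@dataclass
class SpeciesMap:
    """ID -> tag mapping; used for species assignments and true family labels."""

    mapping: dict[str, str]

    def __getitem__(self, key: str) -> str:
        return self.mapping[key]

    def __contains__(self, key: str) -> bool:
        return key in self.mapping

    def tags(self) -> list[str]:
        """Distinct tags in first-appearance order."""
        seen: dict[str, None] = {}
        for tag in self.mapping.values():
            seen.setdefault(tag)
        return list(seen)


def read_blast_tabular(path: str | Path) -> PairScoreTable:
    """Parse BLAST tabular output (``-outfmt 6``, >= 12 tab-separated columns).

    Columns follow the NCBI default order (qseqid, sseqid, pident, length,
    mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore); extra
    trailing columns are ignored.  Lines starting with ``#`` and blank lines
    are skipped.  A malformed line raises ``ValueError`` naming its number.
    """
    records: list[PairScoreRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 12 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                rec = PairScoreRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return PairScoreTable(records)


def write_blast_tabular(table: PairScoreTable, path: str | Path) -> None:
    """Write a hit table back out in 12-column outfmt-6 layout.

    Positional columns not tracked here (mismatches, gap opens, coordinates)
    are emitted as zeros / full-length placeholders.
    """
    with open(path, "w") as handle:
        for rec in table.records:
            handle.write(
                "\t".join(
                    [
                        rec.query_id,
                        rec.subject_id,
                        f"{rec.percent_identity:.2f}",
                        str(rec.align_length),
                        "0",
                        "0",
                        "1",
                        str(max(rec.align_length, 1)),
                        "1",
                        str(max(rec.align_length, 1)),
                        f"{rec.e_value:.3g}",
                        f"{rec.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def table_to_matrix(
    table: PairScoreTable,
    score_field: Literal["bit_score", "neg_log10_evalue"] = "bit_score",
    aggregate: Literal["max", "mean"] | None = None,
    evalue_floor: float = DEFAULT_EVALUE_FLOOR,
    ids: Sequence[str] | None = None,
) -> ScoreMatrix:
    """Assemble a square score matrix from a hit table.

    Cell (i, j) aggregates all hits i -> j of the chosen field.  For
    ``neg_log10_evalue`` the value is ``-log10(max(e, evalue_floor))``.
    Default aggregation is ``max`` for bit scores (best HSP) and ``mean``
    for -log10 E-values (MCL-style averaged edge weights).  Pairs with no
    hit get 0.  IDs are ordered lexicographically unless ``ids`` is given.
    """
    if evalue_floor <= 0:
        raise ValueError("evalue_floor must be positive")
    if aggregate is None:
        aggregate = "max" if score_field == "bit_score" else "mean"
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")

    if ids is None:
        order = sorted(table.id_universe)
    else:
        order = list(ids)
        missing = set(table.id_universe) - set(order)
        if missing:
            raise ValueError(f"records mention IDs outside supplied order: {sorted(missing)}")
    idx = {sid: i for i, sid in enumerate(order)}
    n = len(order)

    sums = np.zeros((n, n))
    maxes = np.full((n, n), -np.inf)
    counts = np.zeros((n, n), dtype=int)
    for rec in table.records:
        i, j = idx[rec.query_id], idx[rec.subject_id]
        if score_field == "bit_score":
            v = rec.bit_score
        else:
            v = -math.log10(max(rec.e_value, evalue_floor))
        sums[i, j] += v
        maxes[i, j] = max(maxes[i, j], v)
        counts[i, j] += 1

    values = np.zeros((n, n))
    hit = counts > 0
    if aggregate == "max":
        values[hit] = maxes[hit]
    else:
        values[hit] = sums[hit] / counts[hit]
    return ScoreMatrix(order, values, missing_value=0.0)


def write_matrix_tsv(
    matrix: ScoreMatrix, path: str | Path, precision: int = 12
) -> None:
    """Write a matrix as TSV: empty corner cell, column IDs, then ID + row values."""
    fmt = f"%.{precision}g"
    with open(path, "w") as handle:
        handle.write("\t" + "\t".join(matrix.ids) + "\n")
        for sid, row in zip(matrix.ids, matrix.values):
            handle.write(sid + "\t" + "\t".join(fmt % v for v in row) + "\n")


def read_matrix_tsv(path: str | Path, missing_value: float = 0.0) -> ScoreMatrix:
    """Read the matrix TSV dialect written by :func:`write_matrix_tsv`.

    ``.`` or empty cells denote missing pairs and become ``missing_value``.
    Duplicate IDs, a non-square body, or row IDs that disagree with the
    header raise ``ValueError``.
    """
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        raise ValueError(f"{path}: duplicate column IDs")
    df = pd.read_csv(
        path, sep="\t", index_col=0, header=0, na_values=[".", ""],
        keep_default_na=False,
    )
    row_ids = [str(r) for r in df.index]
    if len(set(row_ids)) != len(row_ids):
        raise ValueError(f"{path}: duplicate row IDs")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: body is {df.shape[0]}x{df.shape[1]}, not square")
    if row_ids != col_ids:
        raise ValueError(f"{path}: row IDs do not match column IDs")
    values = df.to_numpy(dtype=float)
    values[np.isnan(values)] = missing_value
    return ScoreMatrix(row_ids, values, missing_value=missing_value)


def read_two_column_map(path: str | Path) -> SpeciesMap:
    """Read a two-column TSV (ID, tag); conflicting duplicate IDs raise."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two tab-separated columns"
                )
            sid, tag = fields[0], fields[1]
            if sid in mapping and mapping[sid] != tag:
                raise ValueError(
                    f"{path}: line {lineno}: conflicting tags for ID {sid!r}: "
                    f"{mapping[sid]!r} vs {tag!r}"
                )
            mapping[sid] = tag
    return SpeciesMap(mapping)


def write_two_column_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for sid, tag in mapping.items():
            handle.write(f"{sid}\t{tag}\n")


def write_kernel_metadata(path: str | Path, meta: Mapping[str, object]) -> None:
    """Write a sidecar metadata file recording a kernel's construction recipe."""
    with open(path, "w") as handle:
        json.dump(dict(meta), handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")


def read_kernel_metadata(path: str | Path) -> dict[str, object]:
    with open(path) as handle:
        return json.load(handle)
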