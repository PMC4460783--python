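"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices are plain tab-separated text with a sample header row
and feature identifiers in the first column.  Target predictions come
either in a TargetScan-style context-score layout (one row per
miRNA/gene/3'UTR-isoform with a total context score in [-1, 0]) or as a
pre-aggregated (miRNA, gene, weight) table with weights in (0, 1].
Annotation gene sets use the standard GMT layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TargetPredictionRecord",
    "GeneSetCollection",
    "TableFormatError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_target_predictions",
    "read_gmt",
    "write_results_table",
    "read_results_table",
]

RESULT_COLUMNS = [
    "mirna_id",
    "es",
    "p_value",
    "p_adjusted",
    "n_targets_in_universe",
    "leading_edge_size",
    "leading_edge_genes",
]


class TableFormatError(ValueError):
    """A malformed input table (duplicate ids, missing or non-numeric cells)."""


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise TableFormatError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A features-by-samples real-valued expression matrix.

    Feature and sample identifiers are unique and ordered; ``values`` has
    shape ``(len(feature_ids), len(sample_ids))`` and contains no missing
    cells.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise TableFormatError("expression matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, feature_id: str) -> np.ndarray:
        """Expression vector of one feature across samples."""
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None
        return self.values[i]

    def subset_features(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep_set = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep_set]
        return ExpressionMatrix(
            [self.feature_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep_set = set(keep)
        idx = [j for j, s in enumerate(self.sample_ids) if s in keep_set]
        return ExpressionMatrix(
            list(self.feature_ids), [self.sample_ids[j] for j in idx], self.values[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(float))


@dataclass(frozen=True)
class TargetPredictionRecord:
    """One sequence-based prediction row.

    TargetScan-style rows carry a 3'UTR isoform identifier/length and a
    total context score in [-1, 0] (more negative = higher confidence);
    pre-aggregated rows carry a ready-made weight in (0, 1] instead.
    """

    mirna_id: str
    gene_id: str
    utr_id: str | None = None
    utr_length: int | None = None
    total_context_score: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.total_context_score is not None:
            if not (-1.0 <= self.total_context_score <= 0.0):
                raise TableFormatError(
                    f"total context score {self.total_context_score} for "
                    f"({self.mirna_id}, {self.gene_id}) outside [-1, 0]"
                )
        if self.weight is not None:
            if not (0.0 < self.weight <= 1.0):
                raise TableFormatError(
                    f"weight {self.weight} for ({self.mirna_id}, {self.gene_id}) "
                    "outside (0, 1]"
                )
        if self.utr_length is not None and self.utr_length < 0:
            raise TableFormatError(f"negative UTR length for {self.utr_id!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets (GO / KEGG / Reactome / ... categories)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_expression_tsv(path: str | Path, transpose_if_needed: bool = False) -> ExpressionMatrix:
    """Load a tab-separated expression matrix.

    The file must have a sample header row and feature identifiers in the
    first column (set ``transpose_if_needed`` for samples-in-rows input).
    Duplicate identifiers, missing cells and non-numeric cells are hard
    errors naming the offending location.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if transpose_if_needed:
        df = df.T
    _check_unique(map(str, df.index), "feature")
    _check_unique(map(str, df.columns), "sample")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy(dtype=object)
        for i, cell in enumerate(raw):
            text = str(cell).strip()
            if text == "" or text.upper() in {"NA", "NAN"}:
                raise TableFormatError(
                    f"missing cell at feature {df.index[i]!r}, sample {col!r}"
                )
            try:
                values[i, j] = float(text)
            except ValueError:
                raise TableFormatError(
                    f"non-numeric cell {text!r} at feature {df.index[i]!r}, sample {col!r}"
                ) from None
            if not math.isfinite(values[i, j]):
                raise TableFormatError(
                    f"missing cell at feature {df.index[i]!r}, sample {col!r}"
                )
    return ExpressionMatrix(list(map(str, df.index)), list(map(str, df.columns)), values)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix in the layout ``read_expression_tsv`` expects."""
    m.to_frame().to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


_CONTEXT_COLUMNS = ["mirna_id", "gene_id", "utr_id", "utr_length", "total_context_score"]
_PREAGG_COLUMNS = ["mirna_id", "gene_id", "weight"]


def read_target_predictions(
    path: str | Path, dialect: str = "targetscan_context"
) -> list[TargetPredictionRecord]:
    """Load sequence-based target predictions.

    ``targetscan_context`` expects columns mirna_id, gene_id, utr_id,
    utr_length, total_context_score (scores in [-1, 0], the public
    context-score distribution layout with canonicalized headers);
    ``preaggregated`` expects mirna_id, gene_id, weight with weights in
    (0, 1].
    """
    if dialect not in {"targetscan_context", "preaggregated"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = _CONTEXT_COLUMNS if dialect == "targetscan_context" else _PREAGG_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing column(s) {missing} in {path}")
    records: list[TargetPredictionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        try:
            if dialect == "targetscan_context":
                rec = TargetPredictionRecord(
                    mirna_id=str(d["mirna_id"]),
                    gene_id=str(d["gene_id"]),
                    utr_id=str(d["utr_id"]),
                    utr_length=int(float(d["utr_length"])),
                    total_context_score=float(d["total_context_score"]),
                )
            else:
                rec = TargetPredictionRecord(
                    mirna_id=str(d["mirna_id"]),
                    gene_id=str(d["gene_id"]),
                    weight=float(d["weight"]),
                )
        except ValueError as exc:
            raise TableFormatError(f"malformed value on line {i} of {path}: {exc}") from None
        records.append(rec)
    return records


def read_gmt(path: str | Path, source: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: per line a set name, a description, then gene ids."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableFormatError(
                    f"GMT line {lineno}: expected at least 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise TableFormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise TableFormatError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets, source=source or str(path))


def write_results_table(results, path: str | Path) -> None:
    """Write per-miRNA enrichment results as TSV, sorted by ES descending.

    ``results`` is a sequence of objects exposing mirna_id, es, p_value,
    p_adjusted, n_targets_in_universe and leading_edge (MirnaResult).
    """
    rows = []
    for r in sorted(results, key=lambda r: (-r.es, r.mirna_id)):
        rows.append(
            {
                "mirna_id": r.mirna_id,
                "es": f"{r.es:.6f}",
                "p_value": f"{r.p_value:.6f}",
                "p_adjusted": f"{r.p_adjusted:.6f}",
                "n_targets_in_universe": r.n_targets_in_universe,
                "leading_edge_size": len(r.leading_edge),
                "leading_edge_genes": ";".join(r.leading_edge),
            }
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results table back; leading_edge_genes becomes a list column."""
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str}, keep_default_na=False)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"results table missing column(s) {missing}")
    for col in ("es", "p_value", "p_adjusted"):
        df[col] = df[col].astype(float)
    df["leading_edge_genes"] = [
        str(x).split(";") if str(x) else [] for x in df["leading_edge_genes"]
    ]
    return df
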