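"""Expression-data cleaning applied before enrichment analysis.

Microarray miRNA intensities are variance-stabilized with the inverse
hyperbolic sine, quantile normalized across samples, corrected for an
additive hybridization-batch effect, filtered for probes that are negative
in nearly all arrays, and technical replicates averaged.  Sequencing-based
miRNA counts instead use a detection filter (more than ``threshold`` reads
in at least a given fraction of samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, TableFormatError

__all__ = [
    "SampleAnnotation",
    "read_sample_annotation",
    "asinh_quantile_normalize",
    "filter_low_signal_features",
    "average_technical_replicates",
    "remove_batch_effect",
]

ANNOTATION_COLUMNS = ["sample_id", "batch", "replicate_group", "subtype"]


@dataclass
class SampleAnnotation:
    """Per-sample metadata: hybridization batch, technical-replicate group
    and tumour subtype label."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise TableFormatError(f"duplicate sample_id {dup!r} in annotation")
        for col in ("batch", "replicate_group", "subtype"):
            if col not in self.table.columns:
                raise TableFormatError(f"annotation missing column {col!r}")

    @classmethod
    def from_records(cls, records: list[dict]) -> "SampleAnnotation":
        df = pd.DataFrame(records).set_index("sample_id")
        return cls(df)

    def require(self, sample_ids: list[str]) -> None:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples missing from annotation: {missing}")

    def batch(self, sample_ids: list[str]) -> np.ndarray:
        self.require(sample_ids)
        return self.table.loc[sample_ids, "batch"].to_numpy(dtype=object)

    def replicate_group(self, sample_ids: list[str]) -> np.ndarray:
        self.require(sample_ids)
        return self.table.loc[sample_ids, "replicate_group"].to_numpy(dtype=object)

    def samples_with_subtype(self, subtype: str) -> list[str]:
        return list(self.table.index[self.table["subtype"] == subtype])


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"annotation missing column(s) {missing}")
    return SampleAnnotation(df.set_index("sample_id"))


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Mean-of-order-statistics quantile normalization of the columns.

    Tied values within a column receive the mean of the reference values at
    their tied ranks, so the map is invariant to how ties are ordered.
    """
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    ref = sorted_vals.mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col_sorted = sorted_vals[:, j]
        change = np.r_[True, np.diff(col_sorted) != 0]
        group = np.cumsum(change) - 1
        means = np.bincount(group, weights=ref) / np.bincount(group)
        out[order[:, j], j] = means[group]
    return out


def asinh_quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply asinh variance stabilization, then quantile-normalize samples.

    After the transform every sample column shares the same reference
    distribution: the across-sample mean of each order statistic.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    transformed = np.arcsinh(m.values)
    return ExpressionMatrix(
        list(m.feature_ids), list(m.sample_ids), _quantile_normalize(transformed)
    )


def filter_low_signal_features(
    m: ExpressionMatrix,
    rule: str,
    threshold: float = 0.0,
    fraction: float = 0.95,
) -> ExpressionMatrix:
    """Drop features without usable signal.

    ``negative_in_frac`` discards a feature whose value is negative in at
    least ``fraction`` of the samples (microarray convention, default 0.95).
    ``min_reads_in_frac`` keeps a feature whose value exceeds ``threshold``
    in at least ``fraction`` of the samples (sequencing convention, e.g.
    threshold 10 reads, fraction 0.10).  Surviving features keep their
    original order.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = m.n_samples
    if rule == "negative_in_frac":
        frac_negative = (m.values < 0).sum(axis=1) / n
        keep = frac_negative < fraction
    elif rule == "min_reads_in_frac":
        frac_detected = (m.values > threshold).sum(axis=1) / n
        keep = frac_detected >= fraction
    else:
        raise ValueError(f"unknown filter rule {rule!r}")
    kept = [f for f, k in zip(m.feature_ids, keep) if k]
    return ExpressionMatrix(kept, list(m.sample_ids), m.values[keep])


def average_technical_replicates(
    m: ExpressionMatrix, ann: SampleAnnotation
) -> ExpressionMatrix:
    """Collapse technical replicates to their per-feature arithmetic mean.

    Output has one column per replicate group, named after the group,
    ordered by first appearance; singleton groups pass through unchanged.
    """
    groups = ann.replicate_group(m.sample_ids)
    seen: dict[str, list[int]] = {}
    for j, g in enumerate(groups):
        seen.setdefault(str(g), []).append(j)
    new_ids = list(seen)
    new_values = np.column_stack([m.values[:, idx].mean(axis=1) for idx in seen.values()])
    return ExpressionMatrix(list(m.feature_ids), new_ids, new_values)


def remove_batch_effect(m: ExpressionMatrix, ann: SampleAnnotation) -> ExpressionMatrix:
    """Remove an additive batch effect, feature by feature.

    Fits value ~ grand mean + batch (fixed effect) by least squares and
    subtracts the fitted batch deviations, which equalizes per-batch means
    while preserving each feature's grand mean.
    """
    batches = ann.batch(m.sample_ids)
    labels, inverse = np.unique(batches, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("batch correction needs at least 2 batches")
    counts = np.bincount(inverse)
    if counts.min() < 2:
        small = labels[np.argmin(counts)]
        raise ValueError(f"batch {small!r} has a single sample; effect inestimable")
    grand = m.values.mean(axis=1, keepdims=True)
    corrected = m.values.copy()
    for b in range(len(labels)):
        cols = inverse == b
        batch_mean = m.values[:, cols].mean(axis=1, keepdims=True)
        corrected[:, cols] -= batch_mean - grand
    return ExpressionMatrix(list(m.feature_ids), list(m.sample_ids), corrected)
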