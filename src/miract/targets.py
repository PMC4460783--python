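"""Aggregation of sequence-based prediction records into weighted target sets.

A miRNA's target set maps each predicted target gene to a confidence
weight in (0, 1].  For TargetScan-style records the weight is the absolute
value of the total context score of the gene's longest annotated 3'UTR
isoform (scores live in [-1, 0] with more-negative meaning more confident,
so |score| and -score coincide).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .io import TargetPredictionRecord

__all__ = ["TargetSet", "build_target_sets", "restrict_to_universe", "write_target_sets_tsv"]


@dataclass(frozen=True)
class TargetSet:
    """One miRNA's predicted targets with positive confidence weights."""

    mirna_id: str
    targets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, w in self.targets.items():
            if not (0.0 < w <= 1.0):
                raise ValueError(
                    f"weight {w} for ({self.mirna_id}, {gene}) outside (0, 1]"
                )

    def __len__(self) -> int:
        return len(self.targets)


def _select_isoform(cands: list[TargetPredictionRecord]) -> TargetPredictionRecord:
    # longest 3'UTR isoform; ties by most-negative score, then utr_id
    return min(
        cands,
        key=lambda r: (-(r.utr_length or 0), r.total_context_score, r.utr_id or ""),
    )


def build_target_sets(
    records: Iterable[TargetPredictionRecord], score_to_weight: str = "abs"
) -> list[TargetSet]:
    """Collapse prediction records to one weighted target set per miRNA.

    For each (miRNA, gene) pair with several 3'UTR isoforms the longest
    isoform's total context score is taken; the weight is |score| (the
    ``"negate"`` convention, -score, is identical for scores in [-1, 0]).
    Genes whose selected score is exactly 0 carry no signal and are
    dropped.  Pre-aggregated records contribute their weight directly;
    duplicated pre-aggregated pairs keep the maximum weight.  Output is
    deterministic and independent of input record order.
    """
    records = list(records)
    if not records:
        raise ValueError("no prediction records given")
    if score_to_weight not in {"abs", "negate"}:
        raise ValueError(f"unknown weight convention {score_to_weight!r}")
    by_pair: dict[tuple[str, str], list[TargetPredictionRecord]] = {}
    preagg: dict[tuple[str, str], float] = {}
    for r in records:
        key = (r.mirna_id, r.gene_id)
        if r.weight is not None:
            preagg[key] = max(preagg.get(key, 0.0), r.weight)
        else:
            by_pair.setdefault(key, []).append(r)
    weights: dict[str, dict[str, float]] = {}
    for (mirna, gene), cands in by_pair.items():
        chosen = _select_isoform(cands)
        w = abs(chosen.total_context_score or 0.0)
        if w > 0.0:
            weights.setdefault(mirna, {})[gene] = w
    for (mirna, gene), w in preagg.items():
        weights.setdefault(mirna, {})[gene] = w
    return [
        TargetSet(mirna, dict(sorted(weights[mirna].items())))
        for mirna in sorted(weights)
    ]


def restrict_to_universe(
    sets: Iterable[TargetSet],
    expressed_genes: set[str],
    expressed_mirnas: set[str],
    min_targets: int = 10,
) -> tuple[list[TargetSet], dict[str, str]]:
    """Intersect target sets with the measured gene/miRNA universe.

    Keeps only miRNAs that were measured and retain at least
    ``min_targets`` predicted targets among the measured genes.  Returns
    the surviving sets plus a {mirna_id: reason} report for dropped ones.
    """
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    if not expressed_genes:
        raise ValueError("expressed gene universe is empty")
    kept: list[TargetSet] = []
    dropped: dict[str, str] = {}
    for ts in sets:
        if ts.mirna_id not in expressed_mirnas:
            dropped[ts.mirna_id] = "miRNA not measured"
            continue
        inter = {g: w for g, w in ts.targets.items() if g in expressed_genes}
        if len(inter) < min_targets:
            dropped[ts.mirna_id] = "too few measured targets"
            continue
        kept.append(TargetSet(ts.mirna_id, inter))
    return kept, dropped


def write_target_sets_tsv(sets: Iterable[TargetSet], path: str | Path) -> None:
    """Export aggregated (mirna_id, gene_id, weight) rows for audits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tgene_id\tweight\n")
        for ts in sets:
            for gene, w in ts.targets.items():
                fh.write(f"{ts.mirna_id}\t{gene}\t{w:.6g}\n")
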