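"""Leading-edge extraction and follow-up overrepresentation statistics.

The leading-edge subset of a miRNA's targets — the targets appearing in
the ranked list up to the position where the running sum peaks (positive
ES) or after it (negative ES) — is the core of genes driving the
enrichment signal.  These subsets are tested for functional coherence
against annotation gene sets with an exact hypergeometric tail test and
Bonferroni correction, and detected-regulator lists from two datasets are
compared with the same tail test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np
from scipy.stats import hypergeom

if TYPE_CHECKING:  # typing only; no runtime dependency on the core module
    from .enrichment import MirnaResult, RankedList

from .io import GeneSetCollection
from .targets import TargetSet

__all__ = [
    "CategoryResult",
    "extract_leading_edge",
    "hypergeometric_tail",
    "annotate_leading_edges",
    "overlap_significance",
]


@dataclass(frozen=True)
class CategoryResult:
    """Overlap of one leading edge with one annotation category."""

    set_name: str
    overlap_count: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    p_bonferroni: float


def extract_leading_edge(
    ranked: "RankedList", tset: TargetSet, es: float, argmax_index: int
) -> list[str]:
    """Targets in the ranked-list prefix (es > 0) or suffix (es < 0)
    delimited by the running sum's peak; ranked-list order is preserved.
    """
    if not (1 <= argmax_index <= len(ranked.gene_ids)):
        raise ValueError(f"argmax_index {argmax_index} outside [1, {len(ranked.gene_ids)}]")
    if es > 0:
        window = ranked.gene_ids[:argmax_index]
    elif es < 0:
        window = ranked.gene_ids[argmax_index:]
    else:
        return []
    return [g for g in window if g in tset.targets]


def hypergeometric_tail(
    overlap: int, query_size: int, set_size: int, universe_size: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set_size, query_size).

    Exact upper-tail probability of drawing at least ``overlap`` members of
    a ``set_size`` category in ``query_size`` draws without replacement
    from ``universe_size`` genes.
    """
    if query_size > universe_size or set_size > universe_size:
        raise ValueError("query/set size exceeds universe")
    if overlap > min(query_size, set_size) or overlap < 0:
        raise ValueError("overlap inconsistent with set sizes")
    return float(hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def annotate_leading_edges(
    results: Iterable["MirnaResult"],
    collections: GeneSetCollection,
    universe: set[str],
    bonferroni_threshold: float = 1e-2,
    only_detected: bool = True,
) -> dict[str, list[CategoryResult]]:
    """Functional-enrichment tests of leading edges against annotation sets.

    For each (detected) miRNA, every annotation set with a non-empty
    intersection with the measured universe is tested; p-values are
    Bonferroni-corrected over the number of sets actually tested for that
    miRNA, and categories with corrected p below the threshold are
    reported, ordered by increasing p.
    """
    if not universe:
        raise ValueError("empty gene universe")
    tested = {
        name: genes & universe
        for name, genes in collections.items()
        if genes & universe
    }
    m = len(tested)
    out: dict[str, list[CategoryResult]] = {}
    for res in results:
        if only_detected and not res.detected:
            continue
        query = set(res.leading_edge) & universe
        found: list[CategoryResult] = []
        if query and m:
            for name, genes in tested.items():
                k = len(query & genes)
                p = hypergeometric_tail(k, len(query), len(genes), len(universe))
                p_bonf = min(1.0, p * m)
                if p_bonf < bonferroni_threshold:
                    found.append(
                        CategoryResult(
                            set_name=name,
                            overlap_count=k,
                            set_size=len(genes),
                            query_size=len(query),
                            universe_size=len(universe),
                            p_value=p,
                            p_bonferroni=p_bonf,
                        )
                    )
        found.sort(key=lambda c: (c.p_value, c.set_name))
        out[res.mirna_id] = found
    return out


def overlap_significance(
    detected_a: set[str], detected_b: set[str], common_universe: set[str]
) -> tuple[int, float]:
    """Size and hypergeometric tail p of the overlap of two detected-miRNA
    lists within their common analyzed universe."""
    for name, s in (("detected_a", detected_a), ("detected_b", detected_b)):
        if not s <= common_universe:
            raise ValueError(f"{name} is not contained in the common universe")
    overlap = len(detected_a & detected_b)
    p = hypergeometric_tail(
        overlap, len(detected_a), len(detected_b), len(common_universe)
    )
    return overlap, p
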