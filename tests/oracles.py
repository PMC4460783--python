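"""Independent brute-force oracles used to validate the implementation.

Everything here is written as plain loops/enumeration, deliberately
sharing no code with the package.
"""

from itertools import combinations
from math import comb


def brute_force_profile(correlations, gene_ids, target_weights, alpha=1.0,
                        baseline="universe"):
    """Prefix sums of the weighted enrichment walk, one position at a time."""
    n = len(gene_ids)
    contributions = []
    for g, r in zip(gene_ids, correlations):
        w = target_weights.get(g, 0.0)
        contributions.append(w * abs(r) ** alpha)
    total = sum(c for c in contributions)
    denom = n if baseline == "universe" else len(target_weights)
    b = total / denom
    profile = []
    running = 0.0
    for c in contributions:
        running += c - b
        profile.append(running)
    return profile


def brute_force_es(profile):
    """Signed value at maximal |deviation|, earliest tie, 1-based index."""
    best_i, best_abs = 0, abs(profile[0])
    for i, v in enumerate(profile):
        if abs(v) > best_abs:
            best_i, best_abs = i, abs(v)
    return profile[best_i], best_i + 1


def enumerate_null_es(correlations, n_targets, weight=1.0, alpha=1.0):
    """ES of every possible placement of ``n_targets`` equal-weight targets
    on the ranked positions (uniform membership null)."""
    n = len(correlations)
    out = []
    for combo in combinations(range(n), n_targets):
        gene_ids = [f"g{i}" for i in range(n)]
        weights = {f"g{i}": weight for i in combo}
        prof = brute_force_profile(correlations, gene_ids, weights, alpha=alpha)
        es, _ = brute_force_es(prof)
        out.append((combo, es))
    return out


def enumerate_hypergeom_tail(overlap, query_size, set_size, universe_size):
    """P(X >= overlap) by summing counts of all draw outcomes."""
    total = comb(universe_size, query_size)
    favourable = 0
    for k in range(overlap, min(query_size, set_size) + 1):
        favourable += comb(set_size, k) * comb(universe_size - set_size, query_size - k)
    return favourable / total


def stepup_bh(p_values):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        q = min(prev, p_values[i] * m / rank_from_top)
        adjusted[i] = q
        prev = q
    return adjusted
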