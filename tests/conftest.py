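import numpy as np
import pytest

from miract import ExpressionMatrix, RankedList, TargetSet


@pytest.fixture
def ranked5():
    """The 5-gene worked example used throughout the running-sum tests."""
    return RankedList("miR-X", ["g1", "g2", "g3", "g4", "g5"],
                      np.array([0.9, 0.5, 0.4, 0.2, 0.1]))


@pytest.fixture
def top_targets():
    return TargetSet("miR-X", {"g1": 1.0, "g3": 1.0})


@pytest.fixture
def bottom_targets():
    return TargetSet("miR-X", {"g4": 1.0, "g5": 1.0})


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        [f"G{i}" for i in range(8)],
        [f"S{j}" for j in range(6)],
        rng.standard_normal((8, 6)),
    )


def random_instance(rng, max_n=50, max_targets=10):
    """A random ranked list + weighted target set for oracle comparisons."""
    n = int(rng.integers(5, max_n + 1))
    k = int(rng.integers(1, min(max_targets, n) + 1))
    corr = np.sort(rng.uniform(-1, 1, size=n))[::-1]
    gene_ids = [f"g{i:03d}" for i in range(n)]
    target_pos = rng.choice(n, size=k, replace=False)
    weights = 1.0 - rng.random(k)  # (0, 1]
    tset = TargetSet("m", {gene_ids[p]: float(w) for p, w in zip(target_pos, weights)})
    return RankedList("m", gene_ids, corr), tset
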