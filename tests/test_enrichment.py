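import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from miract import (
    ExpressionMatrix,
    RankedList,
    TargetSet,
    bh_adjust,
    derive_seed,
    empirical_pvalue,
    enrichment_score,
    permutation_null,
    rank_genes,
    run_mirna_analysis,
    running_sum_profile,
    spearman_correlation,
)
from miract.simulate import SimulationConfig, generate_planted_dataset

from conftest import random_instance
from oracles import brute_force_es, brute_force_profile, stepup_bh


class TestSpearman:
    def test_perfect_concordance(self):
        assert spearman_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert spearman_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_pearson_of_average_ranks(self):
        # ranks of x=(1,2,2,4) are (1, 2.5, 2.5, 4); of y=(1,3,2,4) are (1,3,2,4)
        rx, ry = np.array([1, 2.5, 2.5, 4]), np.array([1, 3, 2, 4])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_correlation([1, 2, 2, 4], [1, 3, 2, 4]) == pytest.approx(expected)

    def test_agrees_with_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.choice(5, size=15).astype(float)  # heavy ties
            assert spearman_correlation(x, y) == pytest.approx(
                spearmanr(x, y).statistic, abs=1e-12
            )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2, 3], [1, 2])


class TestRankGenes:
    def _matrix(self, rows, ids):
        vals = np.asarray(rows, dtype=float)
        return ExpressionMatrix(ids, [f"S{j}" for j in range(vals.shape[1])], vals)

    def test_sorted_by_correlation_descending(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 2.5])
        m = self._matrix([v[::-1], v + np.array([0, 0, 0, 0, -3]), v], ["g3", "g1", "g2"])
        ranked = rank_genes(m, v, "miR")
        assert ranked.gene_ids[0] == "g2" and ranked.gene_ids[-1] == "g3"
        assert np.all(np.diff(ranked.correlations) <= 1e-12)

    def test_tie_broken_lexicographically(self):
        v = np.array([1.0, 2.0, 3.0])
        m = self._matrix([v, v], ["gB", "gA"])
        ranked = rank_genes(m, v, "miR")
        assert ranked.gene_ids == ["gA", "gB"]

    def test_self_correlation_first(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=10)
        m = self._matrix([rng.normal(size=10), v, rng.normal(size=10)],
                         ["ga", "self", "gc"])
        ranked = rank_genes(m, v, "miR")
        assert ranked.gene_ids[0] == "self"
        assert ranked.correlations[0] == pytest.approx(1.0)

    def test_constant_gene_row_warns_and_gets_zero(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        m = self._matrix([np.full(4, 7.0), v], ["flat", "g"])
        with pytest.warns(UserWarning, match="constant"):
            ranked = rank_genes(m, v, "miR")
        assert ranked.correlations[ranked.gene_ids.index("flat")] == 0.0

    def test_constant_mirna_rejected(self):
        m = self._matrix([[1.0, 2.0, 3.0]], ["g"])
        with pytest.raises(ValueError, match="constant"):
            rank_genes(m, np.ones(3), "miR")

    def test_sample_count_mismatch(self):
        m = self._matrix([[1.0, 2.0, 3.0]], ["g"])
        with pytest.raises(ValueError):
            rank_genes(m, np.ones(4), "miR")


class TestRunningSum:
    def test_top_enrichment_profile(self, ranked5, top_targets):
        prof = running_sum_profile(ranked5, top_targets)
        np.testing.assert_allclose(prof, [0.64, 0.38, 0.52, 0.26, 0.0], atol=1e-12)
        assert enrichment_score(prof) == (pytest.approx(0.64), 1)

    def test_bottom_enrichment_profile(self, ranked5, bottom_targets):
        prof = running_sum_profile(ranked5, bottom_targets)
        np.testing.assert_allclose(prof, [-0.06, -0.12, -0.18, -0.04, 0.0], atol=1e-12)
        es, idx = enrichment_score(prof)
        assert es == pytest.approx(-0.18) and idx == 3

    def test_zero_correlations_zero_profile(self):
        ranked = RankedList("m", ["a", "b", "c"], np.zeros(3))
        prof = running_sum_profile(ranked, TargetSet("m", {"a": 0.5}))
        np.testing.assert_array_equal(prof, np.zeros(3))
        assert enrichment_score(prof) == (0.0, 1)

    def test_empty_target_set_rejected(self, ranked5):
        with pytest.raises(ValueError):
            running_sum_profile(ranked5, TargetSet("m", {}))

    def test_target_set_baseline_variant_drifts_negative(self, ranked5, top_targets):
        prof = running_sum_profile(ranked5, top_targets, baseline="target_set")
        # literal |S_m| average: b = 1.3/2; walk ends at sum(hits) - N*b < 0
        assert prof[-1] == pytest.approx(1.3 - 5 * 0.65)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            ranked, tset = random_instance(rng)
            alpha = float(rng.choice([0.5, 1.0, 2.0]))
            prof = running_sum_profile(ranked, tset, alpha=alpha)
            expected = brute_force_profile(
                ranked.correlations, ranked.gene_ids, dict(tset.targets), alpha=alpha
            )
            np.testing.assert_allclose(prof, expected, atol=1e-12)
            es, idx = enrichment_score(prof)
            es_o, idx_o = brute_force_es(expected)
            assert es == pytest.approx(es_o, abs=1e-12) and idx == idx_o

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_zero_sum_and_reversal_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        ranked, tset = random_instance(rng)
        prof = running_sum_profile(ranked, tset)
        assert abs(prof[-1]) < 1e-9
        # reversed list: same |r| pattern walked bottom-up
        reversed_ranked = RankedList(
            "m", ranked.gene_ids[::-1], -ranked.correlations[::-1]
        )
        es, _ = enrichment_score(prof)
        es_rev, _ = enrichment_score(running_sum_profile(reversed_ranked, tset))
        peak = np.max(np.abs(prof))
        if np.max(prof) >= peak - 1e-12 and -np.min(prof) >= peak - 1e-12:
            # two-sided magnitude tie: reversal cannot flip the sign
            assert abs(es_rev) == pytest.approx(abs(es), abs=1e-9)
        else:
            assert es_rev == pytest.approx(-es, abs=1e-9)


class TestPermutationNull:
    def test_deterministic_given_seed(self, ranked5, top_targets):
        a = permutation_null(ranked5, top_targets, n_perm=10, seed=5)
        b = permutation_null(ranked5, top_targets, n_perm=10, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_zero_correlations_zero_null(self):
        ranked = RankedList("m", list("abcde"), np.zeros(5))
        null = permutation_null(ranked, TargetSet("m", {"a": 1.0}), n_perm=20, seed=0)
        np.testing.assert_array_equal(null, np.zeros(20))

    def test_matches_exhaustive_enumeration_frequencies(self, ranked5):
        from oracles import enumerate_null_es

        tset = TargetSet("m", {"g1": 1.0, "g2": 1.0})
        null = permutation_null(ranked5, tset, n_perm=10000, seed=7)
        exact = sorted({round(es, 9) for _, es in
                        enumerate_null_es(ranked5.correlations, 2)})
        # every sampled value is one of the C(5,2)=10 enumerated scores,
        # and each placement's frequency is near 1/10
        sampled = np.round(null, 9)
        assert set(sampled) <= set(exact)
        values, counts = np.unique(sampled, return_counts=True)
        freqs = dict(zip(values, counts / 10000))
        exact_freq = {}
        for _, es in enumerate_null_es(ranked5.correlations, 2):
            exact_freq[round(es, 9)] = exact_freq.get(round(es, 9), 0) + 0.1
        for v, f in exact_freq.items():
            assert abs(freqs.get(v, 0.0) - f) < 0.02

    def test_invalid_arguments(self, ranked5, top_targets):
        with pytest.raises(ValueError):
            permutation_null(ranked5, TargetSet("m", {}), n_perm=10, seed=0)
        with pytest.raises(ValueError):
            permutation_null(ranked5, top_targets, n_perm=0, seed=0)


class TestEmpiricalPvalue:
    def test_positive_region_counting(self):
        assert empirical_pvalue(1.5, np.array([-1, 0, 1, 2]), denominator="all") == 0.25

    def test_negative_region_counting(self):
        assert empirical_pvalue(-2, np.array([-3, -1, 0, 2]), denominator="all") == 0.25

    def test_region_normalized_counting(self):
        # positive region has 3 members (0, 1, 2); one of them >= 1.5
        assert empirical_pvalue(1.5, np.array([-1, 0, 1, 2])) == pytest.approx(1 / 3)

    def test_extreme_observation_gives_zero(self):
        assert empirical_pvalue(10.0, np.array([-1, 0, 1, 2])) == 0.0

    def test_zero_es_gives_one(self):
        assert empirical_pvalue(0.0, np.array([-1.0, 1.0])) == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, np.array([]))


class TestBHAdjust:
    def test_textbook_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_zeros(self):
        np.testing.assert_array_equal(bh_adjust([0.0, 0.0]), [0.0, 0.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_stepup_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), stepup_bh(p), atol=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_at_least_raw(self, p):
        assert np.all(bh_adjust(p) >= np.asarray(p) - 1e-12)


@pytest.fixture(scope="module")
def planted_small():
    cfg = SimulationConfig(
        n_genes=150, n_mirnas=6, n_samples=40, targets_per_mirna=25,
        n_planted_regulators=2, seed=11,
    )
    return generate_planted_dataset(cfg)


class TestRunMirnaAnalysis:

    def test_planted_regulators_detected(self, planted_small):
        mrna, mirna, sets, truth = planted_small
        results = run_mirna_analysis(mrna, mirna, sets, n_perm=200, seed=4)
        detected = {r.mirna_id for r in results if r.detected}
        assert truth.regulators <= detected
        for r in results:
            assert r.p_adjusted >= r.p_value - 1e-12
            assert set(r.leading_edge) <= set(
                next(s.targets for s in sets if s.mirna_id == r.mirna_id)
            )

    def test_deterministic_given_master_seed(self, planted_small):
        mrna, mirna, sets, _ = planted_small
        a = run_mirna_analysis(mrna, mirna, sets, n_perm=100, seed=9)
        b = run_mirna_analysis(mrna, mirna, sets, n_perm=100, seed=9)
        assert a == b

    def test_result_independent_of_other_mirnas(self, planted_small):
        # per-miRNA seeds derive from (master seed, id): dropping one miRNA
        # leaves the others' ES and raw p untouched
        mrna, mirna, sets, _ = planted_small
        full = run_mirna_analysis(mrna, mirna, sets, n_perm=100, seed=9)
        subset = run_mirna_analysis(mrna, mirna, sets[1:], n_perm=100, seed=9)
        by_id = {r.mirna_id: r for r in full}
        for r in subset:
            assert r.es == by_id[r.mirna_id].es
            assert r.p_value == by_id[r.mirna_id].p_value

    def test_sample_mismatch_rejected(self, planted_small):
        mrna, mirna, sets, _ = planted_small
        reordered = ExpressionMatrix(
            list(mirna.feature_ids), mirna.sample_ids[::-1], mirna.values[:, ::-1]
        )
        with pytest.raises(ValueError, match="sample"):
            run_mirna_analysis(mrna, reordered, sets)

    def test_empty_set_list_rejected(self, planted_small):
        mrna, mirna, _, _ = planted_small
        with pytest.raises(ValueError):
            run_mirna_analysis(mrna, mirna, [])


def test_derive_seed_stable_and_bounded():
    s = derive_seed(42, "miR-001")
    assert s == derive_seed(42, "miR-001")
    assert 0 <= s < 2**31
    assert s != derive_seed(42, "miR-002")
    assert s != derive_seed(43, "miR-001")
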