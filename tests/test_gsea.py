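import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromode import (
    GeneSet,
    RankedList,
    enrichment_score,
    leading_edge,
    permutation_null,
    rank_genes,
)
from chromode.expression import ExpressionTable
from chromode.gsea import nominal_p, read_gmt, read_rnk, run_gsea, write_gmt, write_rnk


def brute_force_es(genes, metric, members, p=1.0):
    """Independent running-sum oracle, computed stepwise in pure Python."""
    hit_mass = sum(abs(m) ** p for g, m in zip(genes, metric) if g in members)
    n = len(genes)
    k = sum(g in members for g in genes)
    running, total = [], 0.0
    for g, m in zip(genes, metric):
        if g in members:
            total += (abs(m) ** p) / hit_mass if hit_mass > 0 else 1.0 / k
        else:
            total -= 1.0 / (n - k)
        running.append(total)
    idx = max(range(n), key=lambda i: (abs(running[i]), -i))
    return running[idx], running, idx


FIVE = RankedList(["g1", "g2", "g3", "g4", "g5"], np.array([3, 2, 1, -1, -2.0]))


class TestEnrichmentScore:
    def test_worked_example(self):
        es, running, idx = enrichment_score(FIVE, GeneSet("s", frozenset({"g1", "g3"})))
        np.testing.assert_allclose(
            running, [0.75, 0.75 - 1 / 3, 2 / 3, 1 / 3, 0.0], atol=1e-12
        )
        assert es == pytest.approx(0.75) and idx == 0

    def test_single_top_gene(self):
        es, _, _ = enrichment_score(FIVE, GeneSet("s", frozenset({"g1"})))
        assert es == pytest.approx(1.0)

    def test_single_bottom_gene(self):
        # four misses at -1/(N-1) each reach -1 just before the hit
        es, _, idx = enrichment_score(FIVE, GeneSet("s", frozenset({"g5"})))
        assert es == pytest.approx(-1.0) and idx == 3

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(FIVE, GeneSet("s", frozenset({"zzz"})))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(5, 200),
        k=st.integers(1, 20),
        seed=st.integers(0, 10_000),
    )
    def test_matches_brute_force_and_bounded(self, n, k, seed):
        k = min(k, n - 1)
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        metric = np.sort(rng.normal(0, 2, n))[::-1]
        ranked = RankedList(genes, metric)
        members = frozenset(rng.choice(genes, k, replace=False))
        es, running, idx = enrichment_score(ranked, GeneSet("s", members))
        oracle_es, oracle_running, oracle_idx = brute_force_es(genes, metric, members)
        np.testing.assert_allclose(running, oracle_running, atol=1e-12)
        assert es == pytest.approx(oracle_es, abs=1e-12) and idx == oracle_idx
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12


class TestRanking:
    def test_order_matches_reference_sort(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:02d}" for i in range(50)]
        wt = rng.uniform(0, 50, 50)
        ko = rng.uniform(0, 50, 50)
        fpkm = pd.DataFrame(
            {"WT_1": wt, "WT_2": wt, "KO_1": ko, "KO_2": ko}, index=genes
        )
        design = pd.DataFrame(
            {"sample": fpkm.columns, "genotype": ["WT", "WT", "KO", "KO"],
             "replicate": [1, 2, 1, 2]}
        )
        ranked = rank_genes(ExpressionTable(fpkm, design))
        metric = np.log2((wt + 0.01) / (ko + 0.01))
        expected = [genes[i] for i in sorted(range(50), key=lambda i: (-metric[i], genes[i]))]
        assert ranked.genes == expected

    def test_all_ties_lexicographic(self):
        fpkm = pd.DataFrame(
            {c: [5.0, 5.0, 5.0] for c in ["WT_1", "WT_2", "KO_1", "KO_2"]},
            index=["gc", "ga", "gb"],
        )
        design = pd.DataFrame(
            {"sample": fpkm.columns, "genotype": ["WT", "WT", "KO", "KO"],
             "replicate": [1, 2, 1, 2]}
        )
        ranked = rank_genes(ExpressionTable(fpkm, design))
        assert ranked.genes == ["ga", "gb", "gc"]


class TestPermutationNull:
    def test_deterministic_given_seed(self):
        null1 = permutation_null(FIVE, GeneSet("s", frozenset({"g1", "g3"})), 100, rng=42)
        null2 = permutation_null(FIVE, GeneSet("s", frozenset({"g1", "g3"})), 100, rng=42)
        np.testing.assert_array_equal(null1, null2)

    def test_min_permutations_enforced(self):
        with pytest.raises(ValueError):
            permutation_null(FIVE, GeneSet("s", frozenset({"g1"})), 99)

    def test_extreme_observation_boundary_p(self):
        null = permutation_null(FIVE, GeneSet("s", frozenset({"g1", "g3"})), 500, rng=0)
        n_pos = (null >= 0).sum()
        assert nominal_p(2.0, null) == pytest.approx(1 / (n_pos + 1))


class TestLeadingEdge:
    def test_positive_es(self):
        gs = GeneSet("s", frozenset({"g1", "g3"}))
        es, _, idx = enrichment_score(FIVE, gs)
        assert leading_edge(FIVE, gs, es, idx) == ["g1"]

    def test_negative_es_tail(self):
        gs = GeneSet("s", frozenset({"g4", "g5"}))
        es, _, idx = enrichment_score(FIVE, gs)
        assert es < 0
        assert leading_edge(FIVE, gs, es, idx) == ["g4", "g5"]

    def test_extremum_at_last_rank_returns_whole_set(self):
        ranked = RankedList(["a", "b", "c"], np.array([3.0, 2.0, 1.0]))
        gs = GeneSet("s", frozenset({"a", "c"}))
        assert leading_edge(ranked, gs, 0.5, 2) == ["a", "c"]


class TestPipeline:
    def test_planted_set_scores_positive(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i:03d}" for i in range(500)]
        metric = np.sort(rng.normal(0, 1, 500))[::-1]
        ranked = RankedList(genes, metric)
        planted = GeneSet("planted", frozenset(rng.choice(genes[:50], 25, replace=False)))
        (res,) = run_gsea(ranked, [planted], n_perm=500, seed=9)
        assert res.es > 0 and res.nes > 0
        assert res.p_nominal < 0.05 and res.q_fdr < 0.05
        assert set(res.leading_edge) <= planted.members

    def test_same_seed_identical_nes(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(200)]
        ranked = RankedList(genes, np.sort(rng.normal(size=200))[::-1])
        gs = GeneSet("s", frozenset(genes[:20]))
        r1 = run_gsea(ranked, [gs], n_perm=200, seed=3)[0]
        r2 = run_gsea(ranked, [gs], n_perm=200, seed=3)[0]
        assert r1.nes == r2.nes and r1.p_nominal == r2.p_nominal


class TestFileFormats:
    def test_gmt_round_trip(self, tmp_path):
        sets = [GeneSet("s1", frozenset({"a", "b"})), GeneSet("s2", frozenset({"c"}))]
        p = tmp_path / "sets.gmt"
        write_gmt(sets, p)
        back = read_gmt(p)
        assert {s.name: s.members for s in back} == {s.name: s.members for s in sets}

    def test_rnk_round_trip_sorted(self, tmp_path):
        ranked = RankedList(["a", "b", "c"], np.array([2.0, 1.0, -1.0]))
        p = tmp_path / "r.rnk"
        write_rnk(ranked, p)
        back = read_rnk(p)
        assert back.genes == ranked.genes
        np.testing.assert_allclose(back.metric, ranked.metric)
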