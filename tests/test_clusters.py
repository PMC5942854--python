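"""Gene-cluster scan: binning, hypergeometric test, BH FDR, cluster calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mspkit import (
    ClusterScanner,
    assign_in_out,
    bin_genome,
    call_clusters,
    fdr_correct,
    hypergeom_bin_test,
)
from mspkit import simulate as sim


def make_map(positions, categories, chrom="chrV"):
    pos = np.asarray(positions)
    return pd.DataFrame({
        "chrom": chrom,
        "start": pos,
        "end": pos + 1,
        "gene_id": [f"g{i}" for i in range(len(pos))],
        "category": list(categories),
    })


class TestBinGenome:
    def test_all_genes_in_first_bin(self):
        gm = make_map(range(10), [False] * 10)
        bins = bin_genome(gm, {"chrV": 1_000_000}, 50_000)
        assert len(bins) == 20
        assert bins.loc[0, "n_genes"] == 10
        assert bins["n_genes"].sum() == 10

    def test_half_open_boundary(self):
        gm = make_map([50_000], [True])
        bins = bin_genome(gm, {"chrV": 200_000}, 50_000)
        assert bins.loc[1, "n_genes"] == 1
        assert bins.loc[0, "n_genes"] == 0

    def test_uniform_count_conservation(self):
        gm = sim.gen_gene_map(20_000_000, 400, 0, [], seed=0)
        bins = bin_genome(gm, {"chrV": 20_000_000}, 50_000)
        assert len(bins) == 400
        assert bins["n_genes"].mean() == pytest.approx(1.0)

    def test_gene_beyond_chromosome_rejected(self):
        gm = make_map([1_000_001], [False])
        with pytest.raises(ValueError, match="beyond"):
            bin_genome(gm, {"chrV": 1_000_000}, 50_000)


class TestHypergeomBinTest:
    def test_zero_category_genes_gives_one(self):
        assert hypergeom_bin_test(0, 5, 100, 10) == 1.0

    def test_exact_combinatorial_value(self):
        # all 5 drawn genes category, from 10 of 100: C(10,5)/C(100,5)
        p = hypergeom_bin_test(5, 5, 100, 10)
        assert p == pytest.approx(3.347168295621904e-06, rel=1e-9)

    def test_saturated_universe_gives_one(self):
        assert hypergeom_bin_test(10, 10, 10, 10) == 1.0

    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_bin_test(5, 3, 100, 10)

    def test_agrees_with_enumeration_small_universe(self):
        # brute-force upper tail over all possible outcomes, N <= 30
        for N, K, n in [(10, 3, 4), (20, 8, 6), (30, 10, 9), (12, 12, 5)]:
            for k in range(0, min(K, n) + 1):
                brute = sum(
                    math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
                    for j in range(k, min(K, n) + 1)
                )
                assert hypergeom_bin_test(k, n, N, K) == pytest.approx(brute, rel=1e-10)


class TestFdrCorrect:
    def test_single_p_unchanged(self):
        assert fdr_correct([0.03])[0] == pytest.approx(0.03)

    def test_step_up_recursion_by_hand(self):
        np.testing.assert_allclose(fdr_correct([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_correct([1.0, 1.0, 1.0]), 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_q_at_least_p_and_monotone_in_rank(self, ps):
        q = fdr_correct(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallClusters:
    @staticmethod
    def bins_with_q(q_by_index, n=10, chrom="chrV"):
        return pd.DataFrame({
            "chrom": chrom,
            "start": np.arange(n) * 50_000,
            "end": (np.arange(n) + 1) * 50_000,
            "bin_index": np.arange(n),
            "n_genes": 1,
            "n_category": 0,
            "p_value": 1.0,
            "q_value": [q_by_index.get(i, 1.0) for i in range(n)],
        })

    def test_no_significant_bins(self):
        assert call_clusters(self.bins_with_q({}), q_threshold=0.05) == []

    def test_gap_tolerance_merges(self):
        bins = self.bins_with_q({3: 0.01, 4: 0.01, 6: 0.01})
        calls = call_clusters(bins, q_threshold=0.05, max_gap_bins=1)
        assert len(calls) == 1
        assert calls[0].bin_indices == [3, 4, 5, 6]
        assert (calls[0].start, calls[0].end) == (150_000, 350_000)

    def test_zero_gap_splits(self):
        bins = self.bins_with_q({3: 0.01, 4: 0.01, 6: 0.01})
        calls = call_clusters(bins, q_threshold=0.05, max_gap_bins=0)
        assert [(c.start, c.end) for c in calls] == [(150_000, 250_000),
                                                     (300_000, 350_000)]

    def test_intervals_disjoint_and_sorted(self, planted_gene_map):
        scanner = ClusterScanner(q_threshold=0.05).fit(planted_gene_map,
                                                       {"chrV": 20_000_000})
        calls = scanner.clusters_
        for a, b in zip(calls, calls[1:]):
            assert a.end <= b.start
        flags = scanner.transform(planted_gene_map)
        member = set().union(*(c.gene_ids for c in calls)) if calls else set()
        assert member == set(planted_gene_map.loc[flags, "gene_id"])


class TestAssignInOut:
    def test_half_open_conventions(self):
        gm = make_map([100, 199, 200], [True, True, True])
        from mspkit.clusters import ClusterCall
        cluster = ClusterCall("chrV", 100, 200, [0], 0.01, [], 0)
        flags = assign_in_out(gm, [cluster])
        assert flags.tolist() == [True, True, False]

    def test_empty_cluster_list(self):
        gm = make_map([1, 2, 3], [False, False, False])
        assert not assign_in_out(gm, []).any()


class TestScanner:
    def test_planted_cluster_is_called(self, planted_gene_map):
        scanner = ClusterScanner().fit(planted_gene_map, {"chrV": 20_000_000})
        assert any(c.start <= 15_000_000 <= c.end for c in scanner.clusters_)
        best = min(c.min_q for c in scanner.clusters_)
        assert best < 0.01

    def test_q_not_below_p(self, planted_gene_map):
        scanner = ClusterScanner().fit(planted_gene_map, {"chrV": 20_000_000})
        bt = scanner.bin_table_
        assert (bt["q_value"] >= bt["p_value"] - 1e-12).all()

    def test_uniform_null_rarely_significant(self):
        hits = 0
        for seed in range(25):
            gm = sim.gen_gene_map(20_000_000, 400, 120, [], seed=seed)
            scanner = ClusterScanner().fit(gm, {"chrV": 20_000_000})
            hits += (scanner.bin_table_["q_value"] <= 0.05).any()
        assert hits / 25 <= 0.12  # ~FDR level plus sampling slack at 25 seeds
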