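"""Category bookkeeping, shift tests, enrichment and correlation statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mspkit import (
    categorize,
    correlate,
    family_summary,
    mean_log2fc,
    overlap_enrichment,
    rank_by_abs_log2fc,
    rank_enrichment,
    shift_test,
    tissue_expression_call,
)


def table_from(lfc_by_gene, genotype="mutant"):
    return pd.DataFrame({
        "gene_id": list(lfc_by_gene),
        f"log2fc_{genotype}": list(lfc_by_gene.values()),
        "logcpm": 5.0,
        "significant": False,
    })


class TestCategorize:
    def test_empty_set(self):
        counts = categorize([], {"a": "spermatogenic"})
        assert all(v == 0 for v in counts.values())

    def test_direct_count(self):
        cmap = {"a": "spermatogenic", "b": "spermatogenic", "c": "non_germline"}
        counts = categorize({"a", "b", "c"}, cmap)
        assert counts["spermatogenic"] == 2
        assert counts["non_germline"] == 1
        assert counts["oogenic"] == 0

    def test_unmapped_counted_and_total_preserved(self):
        counts = categorize({"a", "zzz"}, {"a": "oogenic"})
        assert counts["unmapped"] == 1
        assert sum(counts.values()) == 2


class TestMeanLog2fc:
    def test_uniform_two_fold_down(self):
        t = table_from({"a": -1.0, "b": -1.0})
        mean, fold = mean_log2fc(["a", "b"], t, "mutant")
        assert mean == -1.0 and fold == 2.0

    def test_mixed_values(self):
        t = table_from({"a": 0.0, "b": -2.0})
        mean, _ = mean_log2fc(["a", "b"], t, "mutant")
        assert mean == -1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mean_log2fc([], table_from({"a": 0.0}), "mutant")


class TestFamilySummary:
    @pytest.mark.parametrize("lfc,pct", [(0.0, 100.0), (-1.0, 50.0)])
    def test_closed_form(self, lfc, pct):
        t = table_from({f"m{i}": lfc for i in range(28)})
        assert family_summary(list(t["gene_id"]), t, "mutant") == pytest.approx(pct)

    def test_synthetic_default_family_near_half(self, expression_table):
        table, mis = expression_table
        pct = family_summary(mis[:28], table, "mutant")
        assert pct == pytest.approx(50.0, abs=5.0)


class TestShiftTest:
    def test_identical_samples_ks(self):
        r = shift_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], method="ks")
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_mw_exact_one_sided_enumeration_value(self):
        r = shift_test([1, 2], [3, 4], method="mw_exact", alternative="less")
        assert r.p_value == pytest.approx(1 / 6)

    def test_mw_exact_two_sided_enumeration_value(self):
        r = shift_test([1, 2], [3, 4], method="mw_exact")
        assert r.p_value == pytest.approx(1 / 3)

    def test_exact_size_cap(self):
        with pytest.raises(ValueError, match="combined n"):
            shift_test(np.zeros(15), np.ones(15), method="mw_exact")

    def test_exact_close_to_normal_without_ties(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        pe = shift_test(x, y, method="mw_exact").p_value
        pn = shift_test(x, y, method="mw_normal").p_value
        assert abs(pe - pn) < 0.02

    @pytest.mark.parametrize("method", ["mw_exact", "mw_normal", "ks"])
    def test_two_sided_symmetry(self, method):
        x, y = [0.1, 0.4, 0.9, 1.3], [0.2, 0.5, 0.6, 2.0]
        assert shift_test(x, y, method=method).p_value == pytest.approx(
            shift_test(y, x, method=method).p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            shift_test([], [1.0], method="ks")


class TestRankEnrichment:
    def test_hand_curve(self):
        cmap = {"a": "spermatogenic", "b": "non_germline",
                "c": "spermatogenic", "d": "spermatogenic"}
        curve = rank_enrichment(["a", "b", "c", "d"], cmap, "spermatogenic")
        np.testing.assert_allclose(curve, [1.0, 0.5, 2 / 3, 0.75])

    @pytest.mark.parametrize("cat,expected", [("spermatogenic", 1.0), ("oogenic", 0.0)])
    def test_constant_curves(self, cat, expected):
        cmap = {g: "spermatogenic" for g in "abc"}
        curve = rank_enrichment(list("abc"), cmap, cat)
        assert (curve == expected).all()

    def test_final_point_equals_overall_fraction(self):
        genes = [f"g{i}" for i in range(40)]
        cmap = {g: ("spermatogenic" if i % 3 == 0 else "oogenic")
                for i, g in enumerate(genes)}
        curve = rank_enrichment(genes, cmap, "spermatogenic")
        n_cat = sum(1 for g in genes if cmap[g] == "spermatogenic")
        assert curve[-1] == pytest.approx(n_cat / len(genes))

    def test_ranking_is_deterministic_with_ties(self):
        t = table_from({"b": -1.0, "a": -1.0, "c": 0.5})
        assert rank_by_abs_log2fc(t, "mutant") == ["a", "b", "c"]


class TestOverlapEnrichment:
    def test_disjoint_partition_gives_one(self):
        n, p = overlap_enrichment({"a", "b"}, {"c", "d"}, 4)
        assert n == 0 and p == 1.0

    def test_identical_sets_exact_value(self):
        n, p = overlap_enrichment(set("abcde"), set("abcde"), 100)
        assert n == 5
        assert p == pytest.approx(1.3282413871515492e-08, rel=1e-9)

    def test_monotone_decreasing_in_overlap(self):
        universe = 50
        a = {f"g{i}" for i in range(10)}
        ps = []
        for k in range(0, 11):
            b = {f"g{i}" for i in range(k)} | {f"h{i}" for i in range(10 - k)}
            ps.append(overlap_enrichment(a, b, universe)[1])
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_set_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(set(range(10)), set(), 5)


class TestCorrelate:
    def test_perfect_linear(self):
        r, r2, _ = correlate([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)

    def test_hand_value(self):
        r, r2, p = correlate([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)
        assert r2 == pytest.approx(0.25)

    def test_anti_linear(self):
        r, _, _ = correlate([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])


class TestTissueExpressionCall:
    @staticmethod
    def matrix(counts_by_animal, tissue="germline"):
        rows = []
        for animal, counts in counts_by_animal.items():
            for i, c in enumerate(counts):
                rows.append((animal, f"{animal}_c{i}", tissue, c))
        return pd.DataFrame(rows, columns=["animal", "cell", "tissue", "count"])

    def test_rule_satisfied(self):
        m = self.matrix({"a1": [2, 2, 0], "a2": [2, 2, 0], "a3": [2, 2, 0]})
        assert tissue_expression_call(m, "germline")["expressed"]

    def test_one_animal_below_transcript_threshold(self):
        m = self.matrix({"a1": [2, 2, 0], "a2": [1, 1, 1]})
        assert not tissue_expression_call(m, "germline")["expressed"]

    def test_single_positive_cell_is_not_multiple(self):
        m = self.matrix({"a1": [5, 0, 0], "a2": [5, 0, 0]})
        assert not tissue_expression_call(m, "germline")["expressed"]

    def test_missing_tissue_rejected(self):
        m = self.matrix({"a1": [2, 2]})
        with pytest.raises(ValueError):
            tissue_expression_call(m, "muscle")


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(-4, 4), min_size=2, max_size=8),
       st.lists(st.floats(-4, 4), min_size=2, max_size=8))
def test_mw_exact_matches_full_enumeration(x, y):
    """Exact Mann-Whitney p equals brute-force enumeration of rank assignments."""
    from itertools import combinations
    pooled = list(x) + list(y)
    nx, n = len(x), len(pooled)

    def u_stat(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    obs = u_stat(x, y)
    us = []
    for idx in combinations(range(n), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.asarray(us)
    p_brute = min(1.0, 2 * min(np.mean(us <= obs), np.mean(us >= obs)))
    p_impl = shift_test(x, y, method="mw_exact").p_value
    if len(set(pooled)) == n:  # exact null assumes no ties
        assert p_impl == pytest.approx(p_brute, abs=1e-12)
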