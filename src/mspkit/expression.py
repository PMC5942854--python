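"""Expression-shift and enrichment statistics over gene categories.

Operates on differential-expression tables (per-gene log2 fold-change vs
wild type per genotype, with significance flags) and on gene-category
maps assigning each gene to one of the germline expression classes
(spermatogenic, oogenic, sperm_and_oocyte, non_germline). Provides:

* category bookkeeping for a flagged (misregulated) gene set;
* mean log2FC summaries and family-level percent-of-wild-type levels;
* distribution-shift tests (exact/normal Mann-Whitney U,
  Kolmogorov-Smirnov) between gene sets, e.g. in-cluster vs out-of-cluster;
* rank-correlation enrichment curves;
* set-overlap enrichment by the hypergeometric test;
* Pearson correlation (e.g. msp level vs fertility);
* the binary tissue-expression call used for smFISH count matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORIES",
    "ShiftTestResult",
    "categorize",
    "mean_log2fc",
    "family_summary",
    "shift_test",
    "rank_enrichment",
    "rank_by_abs_log2fc",
    "overlap_enrichment",
    "correlate",
    "tissue_expression_call",
]

CATEGORIES = ("spermatogenic", "oogenic", "sperm_and_oocyte", "non_germline")

MW_EXACT_MAX_N = 20
KS_EXACT_MAX_N = 10


def _log2fc_column(table: pd.DataFrame, genotype: str) -> pd.Series:
    col = f"log2fc_{genotype}"
    if col not in table.columns:
        raise KeyError(f"table has no column {col!r} for genotype {genotype!r}")
    return table.set_index("gene_id")[col]


def categorize(flagged: Iterable[str], category_map: Mapping[str, str]) -> dict[str, int]:
    """Partition a flagged gene set into expression-category counts.

    Genes absent from the map are counted under ``"unmapped"``. The counts
    always sum to the size of the flagged set.
    """
    counts = {c: 0 for c in CATEGORIES}
    counts["unmapped"] = 0
    for gene in set(flagged):
        cat = category_map.get(gene)
        if cat is None:
            counts["unmapped"] += 1
        elif cat in counts:
            counts[cat] += 1
        else:
            raise ValueError(f"unknown category {cat!r} for gene {gene!r}")
    return counts


def mean_log2fc(
    genes: Iterable[str], table: pd.DataFrame, genotype: str
) -> tuple[float, float]:
    """Mean log2 fold-change of a gene set and the implied fold-change.

    Returns ``(mean_log2fc, fold_change)`` where the fold-change is
    ``2**|mean|`` (the direction is the sign of the mean).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    lfc = _log2fc_column(table, genotype)
    missing = set(genes) - set(lfc.index)
    if missing:
        raise KeyError(f"genes not in table: {sorted(missing)[:5]}")
    m = float(lfc.loc[genes].mean())
    return m, float(2.0 ** abs(m))


def family_summary(
    family_genes: Iterable[str], table: pd.DataFrame, genotype: str
) -> float:
    """Family expression level as a percentage of wild type.

    ``100 * 2**mean(log2FC)`` over the family; e.g. a family uniformly at
    log2FC = -1 reports 50%.
    """
    m, _ = mean_log2fc(family_genes, table, genotype)
    return 100.0 * 2.0 ** m


@dataclass
class ShiftTestResult:
    method: str
    statistic: float
    p_value: float
    alternative: str = "two-sided"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alternative": self.alternative,
        }


def shift_test(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "mw_normal",
    alternative: str = "two-sided",
) -> ShiftTestResult:
    """Two-sample distribution-shift test between log2FC samples.

    ``mw_exact`` enumerates the exact Mann-Whitney U null (combined
    n <= 20); ``mw_normal`` uses the normal approximation with tie
    correction; ``ks`` is the two-sample Kolmogorov-Smirnov test
    (exact null for combined n <= 10, asymptotic otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "mw_exact":
        if x.size + y.size > MW_EXACT_MAX_N:
            raise ValueError(
                f"mw_exact limited to combined n <= {MW_EXACT_MAX_N}; "
                "use mw_normal"
            )
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
        return ShiftTestResult("mw_exact", float(res.statistic), float(res.pvalue),
                               alternative)
    if method == "mw_normal":
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        return ShiftTestResult("mw_normal", float(res.statistic), float(res.pvalue),
                               alternative)
    if method == "ks":
        mode = "exact" if x.size + y.size <= KS_EXACT_MAX_N else "asymp"
        res = stats.ks_2samp(x, y, alternative=alternative, method=mode)
        return ShiftTestResult("ks", float(res.statistic), float(res.pvalue),
                               alternative)
    raise ValueError(f"unknown method {method!r}")


def rank_by_abs_log2fc(table: pd.DataFrame, genotype: str) -> list[str]:
    """Gene ids ordered by |log2FC| descending; ties broken by gene_id."""
    lfc = _log2fc_column(table, genotype)
    order = sorted(lfc.index, key=lambda g: (-abs(lfc[g]), g))
    return order


def rank_enrichment(
    ranked_genes: Sequence[str],
    category_map: Mapping[str, str],
    category: str,
) -> np.ndarray:
    """Cumulative category fraction along a ranked gene list.

    Value at rank r (1-based) is the fraction of the top r genes that
    belong to ``category``; the final value equals the overall category
    fraction of the list.
    """
    is_cat = np.array([category_map.get(g) == category for g in ranked_genes])
    if is_cat.size == 0:
        return np.array([])
    return np.cumsum(is_cat) / np.arange(1, is_cat.size + 1)


def overlap_enrichment(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> tuple[int, float]:
    """Overlap count and upper-tail hypergeometric p-value.

    ``P[X >= |A∩B|]`` with ``X ~ Hypergeometric(universe, |A|, |B|)``.
    The universe size must be supplied explicitly.
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than the universe")
    overlap = len(a & b)
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))
    return overlap, min(p, 1.0)


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson correlation: returns (r, R^2, two-tailed p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate sample: zero variance")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def tissue_expression_call(
    matrix: pd.DataFrame,
    tissue: str,
    min_cells: int = 2,
    min_transcripts: int = 2,
) -> dict:
    """Binary expression call for a gene in a tissue from smFISH counts.

    A gene is called expressed in a tissue when, in *every* animal, at
    least ``min_cells`` cells of that tissue each show at least
    ``min_transcripts`` transcripts ("more than one transcript detected in
    multiple cells in all animals"; the >=2 readings of "multiple" and
    "more than one" are recorded in the returned dict).

    ``matrix`` needs columns ``animal``, ``cell``, ``tissue``, ``count``.
    """
    for col in ("animal", "cell", "tissue", "count"):
        if col not in matrix.columns:
            raise ValueError(f"count matrix missing column {col!r}")
    sub = matrix[matrix["tissue"] == tissue]
    if sub.empty:
        raise ValueError(f"no cells of tissue {tissue!r} in the matrix")
    per_animal = (
        sub.assign(hit=sub["count"] >= min_transcripts)
        .groupby("animal")["hit"]
        .sum()
    )
    expressed = bool((per_animal >= min_cells).all())
    return {
        "tissue": tissue,
        "expressed": expressed,
        "n_animals": int(per_animal.size),
        "min_cells": min_cells,
        "min_transcripts": min_transcripts,
        "cells_passing_per_animal": per_animal.astype(int).to_dict(),
    }
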