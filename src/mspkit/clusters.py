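"""Detection of spermatogenic gene clusters by fixed-bin hypergeometric scan.

The chromosome is tiled with disjoint half-open bins of fixed width
(50 kb by default). For each bin holding at least one gene, an upper-tail
hypergeometric test asks whether the bin's category-gene count is an
unlikely excess given the chromosome's totals: with ``N`` genes on the
chromosome of which ``K_cat`` carry the category label, a bin with ``n``
genes and ``k`` category genes scores ``P[X >= k]`` with
``X ~ Hypergeometric(N, K_cat, n)``. Benjamini-Hochberg correction is
applied across the tested (non-empty) bins, and maximal runs of
significant bins — tolerating a configurable number of interior gaps —
are reported as cluster calls.

Bins containing no genes carry no information under this conditioning
(their p-value is identically 1) and are excluded from the
multiple-testing family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterScanner",
    "ClusterCall",
    "bin_genome",
    "hypergeom_bin_test",
    "fdr_correct",
    "call_clusters",
    "assign_in_out",
]


@dataclass
class ClusterCall:
    """A detected cluster: a maximal run of enriched bins."""

    chrom: str
    start: int
    end: int
    bin_indices: list[int]
    min_q: float
    gene_ids: list[str]
    n_category: int

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "bin_indices": self.bin_indices,
            "min_q": self.min_q,
            "gene_ids": self.gene_ids,
            "n_category": self.n_category,
        }


def _check_gene_map(gene_map: pd.DataFrame) -> None:
    for col in ("chrom", "start", "gene_id", "category"):
        if col not in gene_map.columns:
            raise ValueError(f"gene map missing column {col!r}")
    if gene_map["gene_id"].duplicated().any():
        dup = gene_map.loc[gene_map["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")


def bin_genome(
    gene_map: pd.DataFrame, chrom_lengths: dict[str, int], w: int
) -> pd.DataFrame:
    """Count genes and category genes in disjoint half-open bins of width w.

    Every gene is assigned to exactly one bin by its point position
    (feature start); the bins ``[i*w, (i+1)*w)`` tile each chromosome.
    """
    if w <= 0:
        raise ValueError("bin width must be > 0")
    _check_gene_map(gene_map)
    frames = []
    for chrom, length in chrom_lengths.items():
        sub = gene_map[gene_map["chrom"] == chrom]
        if len(sub) and (sub["start"].min() < 0 or sub["start"].max() >= length):
            bad = sub.loc[(sub["start"] < 0) | (sub["start"] >= length), "gene_id"].iloc[0]
            raise ValueError(f"gene {bad!r} lies beyond chromosome {chrom!r} "
                             f"(length {length})")
        n_bins = int(np.ceil(length / w))
        idx = (sub["start"].to_numpy() // w).astype(int)
        n_genes = np.bincount(idx, minlength=n_bins)[:n_bins]
        n_cat = np.bincount(
            idx, weights=sub["category"].to_numpy().astype(float), minlength=n_bins
        )[:n_bins].astype(int)
        starts = np.arange(n_bins, dtype=np.int64) * w
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + w, length),
                    "bin_index": np.arange(n_bins),
                    "n_genes": n_genes,
                    "n_category": n_cat,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def hypergeom_bin_test(
    n_category: int, n_genes: int, N: int, K_cat: int
) -> float:
    """Upper-tail hypergeometric p-value for one bin.

    Probability of observing >= ``n_category`` category genes among the
    bin's ``n_genes`` draws from a chromosome carrying ``K_cat`` category
    genes among ``N`` total.
    """
    if not (0 <= n_category <= n_genes <= N and 0 <= K_cat <= N):
        raise ValueError(
            f"inconsistent totals: k={n_category}, n={n_genes}, N={N}, K={K_cat}"
        )
    if n_category > K_cat:
        raise ValueError("bin holds more category genes than the chromosome")
    return float(stats.hypergeom.sf(n_category - 1, N, K_cat, n_genes))


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _test_bins(bins: pd.DataFrame, background: str = "chromosome") -> pd.DataFrame:
    """Attach p and BH q values to a bin count table.

    ``background='chromosome'`` uses each chromosome's gene totals as the
    urn; ``'genome'`` pools totals over all chromosomes in the table.
    Empty bins get p = q = 1 and are excluded from the BH family.
    """
    bins = bins.reset_index(drop=True)
    if background == "genome":
        N_all = int(bins["n_genes"].sum())
        K_all = int(bins["n_category"].sum())
    p = np.ones(len(bins))
    for chrom, sub in bins.groupby("chrom", sort=False):
        if background == "chromosome":
            N, K_cat = int(sub["n_genes"].sum()), int(sub["n_category"].sum())
        else:
            N, K_cat = N_all, K_all
        n = sub["n_genes"].to_numpy()
        k = sub["n_category"].to_numpy()
        occ = n > 0
        if occ.any():
            p[sub.index.to_numpy()[occ]] = stats.hypergeom.sf(
                k[occ] - 1, N, K_cat, n[occ]
            )
    bins["p_value"] = np.clip(p, 0.0, 1.0)
    q = np.ones(len(bins))
    occupied = bins["n_genes"].to_numpy() > 0
    if occupied.any():
        q[occupied] = fdr_correct(p[occupied])
    bins["q_value"] = q
    return bins


def call_clusters(
    bins: pd.DataFrame,
    gene_map: pd.DataFrame | None = None,
    q_threshold: float = 0.05,
    max_gap_bins: int = 1,
) -> list[ClusterCall]:
    """Merge runs of significant bins into cluster calls.

    A cluster is a maximal run of bins with q <= ``q_threshold``,
    tolerating up to ``max_gap_bins`` consecutive non-significant bins in
    its interior. Member genes are collected from the full span when a
    gene map is supplied.
    """
    if "q_value" not in bins.columns:
        raise ValueError("bins must be FDR-corrected first (missing q_value)")
    calls: list[ClusterCall] = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        sub = sub.sort_values("bin_index")
        sig = sub[sub["q_value"] <= q_threshold]
        if sig.empty:
            continue
        runs: list[list[int]] = [[int(sig["bin_index"].iloc[0])]]
        for b in sig["bin_index"].iloc[1:]:
            b = int(b)
            if b - runs[-1][-1] - 1 <= max_gap_bins:
                runs[-1].append(b)
            else:
                runs.append([b])
        by_index = sub.set_index("bin_index")
        for run in runs:
            span = list(range(run[0], run[-1] + 1))
            start = int(by_index.loc[run[0], "start"])
            end = int(by_index.loc[run[-1], "end"])
            min_q = float(by_index.loc[run, "q_value"].min())
            genes: list[str] = []
            n_cat = 0
            if gene_map is not None:
                in_span = gene_map[
                    (gene_map["chrom"] == chrom)
                    & (gene_map["start"] >= start)
                    & (gene_map["start"] < end)
                ]
                genes = in_span["gene_id"].tolist()
                n_cat = int(in_span["category"].sum())
            calls.append(ClusterCall(chrom, start, end, span, min_q, genes, n_cat))
    return calls


def assign_in_out(gene_map: pd.DataFrame, clusters: list[ClusterCall]) -> pd.Series:
    """Flag each gene as inside (True) or outside any cluster interval."""
    flags = np.zeros(len(gene_map), dtype=bool)
    for c in clusters:
        flags |= (
            (gene_map["chrom"] == c.chrom)
            & (gene_map["start"] >= c.start)
            & (gene_map["start"] < c.end)
        ).to_numpy()
    return pd.Series(flags, index=gene_map.index, name="in_cluster")


class ClusterScanner(BaseEstimator):
    """Fixed-bin hypergeometric scan for category-gene clusters.

    Parameters
    ----------
    bin_width : int, default 50000
        Width of the disjoint genomic bins in bp.
    q_threshold : float, default 0.05
        BH-corrected significance threshold for cluster membership.
    max_gap_bins : int, default 1
        Number of consecutive non-significant bins tolerated inside a
        cluster run.
    background : {"chromosome", "genome"}, default "chromosome"
        Universe for the hypergeometric urn.

    Attributes
    ----------
    bin_table_ : DataFrame
        Per-bin counts with p and q values.
    clusters_ : list of ClusterCall
        Detected clusters, sorted by chromosome and start.
    """

    def __init__(
        self,
        bin_width: int = 50_000,
        q_threshold: float = 0.05,
        max_gap_bins: int = 1,
        background: str = "chromosome",
    ):
        self.bin_width = bin_width
        self.q_threshold = q_threshold
        self.max_gap_bins = max_gap_bins
        self.background = background

    def fit(self, gene_map: pd.DataFrame, chrom_lengths: dict[str, int]) -> "ClusterScanner":
        if self.background not in ("chromosome", "genome"):
            raise ValueError("background must be 'chromosome' or 'genome'")
        bins = bin_genome(gene_map, chrom_lengths, self.bin_width)
        self.bin_table_ = _test_bins(bins, background=self.background)
        self.clusters_ = call_clusters(
            self.bin_table_, gene_map, self.q_threshold, self.max_gap_bins
        )
        self.gene_map_ = gene_map
        return self

    def transform(self, gene_map: pd.DataFrame) -> pd.Series:
        """Per-gene in-cluster flag against the fitted cluster calls."""
        if not hasattr(self, "clusters_"):
            raise ValueError("ClusterScanner is not fitted")
        return assign_in_out(gene_map, self.clusters_)

    def fit_transform(self, gene_map: pd.DataFrame, chrom_lengths: dict[str, int]) -> pd.Series:
        return self.fit(gene_map, chrom_lengths).transform(gene_map)
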