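"""End-to-end synthetic reproduction: simulate every input at the registry
defaults, run every estimator on it, and summarize how well each
generating parameter is recovered.

Each stage writes its inputs/outputs as TSV plus a JSON report; the final
``summary.json`` lists, for every recoverable registry parameter, the
generating value, the recovered value and a z-score (recovered minus
generating, over the sampling standard error).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np

from . import __version__, burst, clusters, coloc, expression, frap, simulate
from .io import RunConfig, write_bed, write_meta, write_tsv

log = logging.getLogger("mspkit")

# synthetic scale of the gene-map / expression stages
CHROM_LENGTH = 20_000_000
N_GENES_MAP = 400
N_CATEGORY = 120
CLUSTER_WINDOW = (14_900_000, 15_100_000, 40)
N_GENES_EXPR = 2000


def _stage_seed(seed: int, offset: int) -> int:
    return (seed * 101 + offset) % (2**31 - 1)


def run_all(config: RunConfig) -> dict:
    """Run simulate -> ts-fit -> scan -> expr -> frap -> coloc; return the summary."""
    reg = config.registry
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = config.seed
    logging.basicConfig(level=config.log_level)
    reports: dict[str, dict] = {}
    summary_rows: list[dict] = []

    def emit(name: str, report: dict) -> None:
        reports[name] = report
        path = out / f"{name}.json"
        path.write_text(json.dumps(report, indent=1, sort_keys=True))
        write_meta(path, chash, seed)

    def recovered(param: str, generating: float, value: float, se: float | None) -> None:
        z = (value - generating) / se if se else None
        summary_rows.append(
            {"parameter": param, "generating": generating, "recovered": value,
             "se": se, "z": z}
        )

    # -- simulate -----------------------------------------------------------
    counts_wt = simulate.gen_ts_counts(reg.p_wt, reg.K, reg.n_wt,
                                       seed=_stage_seed(seed, 1), genotype="wild_type")
    counts_mut = simulate.gen_ts_counts(reg.p_mut, reg.K, reg.n_mut,
                                        seed=_stage_seed(seed, 2), genotype="mutant")
    gene_map = simulate.gen_gene_map(CHROM_LENGTH, N_GENES_MAP, N_CATEGORY,
                                     [CLUSTER_WINDOW], seed=_stage_seed(seed, 3))
    mis_ids = [f"gene{i:05d}" for i in range(reg.n_misregulated)]
    msp_ids = mis_ids[: reg.n_msp]
    table = simulate.gen_expression_table(N_GENES_EXPR, mis_ids, reg.effect_log2fc,
                                          reg.log2fc_sd, seed=_stage_seed(seed, 4))
    traces_foci = simulate.gen_frap_traces(16, reg.t_half_foci, noise_sd=reg.frap_noise_sd,
                                           seed=_stage_seed(seed, 5), compartment="focus")
    traces_hyp = simulate.gen_frap_traces(10, reg.t_half_hyp, noise_sd=reg.frap_noise_sd,
                                          seed=_stage_seed(seed, 6),
                                          compartment="nucleoplasm")
    scenes = simulate.gen_nucleus_scenes(
        100, reg.foci_range, reg.K, reg.p_wt, reg.coloc_prob, reg.coloc_radius,
        reg.nucleus_radius, seed=_stage_seed(seed, 7),
    )
    if "simulate" in config.stages:
        import pandas as pd

        write_tsv(pd.concat([counts_wt, counts_mut]), out / "ts_counts.tsv")
        write_bed(gene_map, out / "gene_map.bed")
        write_tsv(gene_map.assign(
            category=np.where(gene_map["category"], "spermatogenic", "other")
        )[["gene_id", "category"]], out / "gene_categories.tsv")
        write_tsv(table, out / "expression.tsv")
        write_tsv(pd.concat([traces_foci, traces_hyp]), out / "frap_traces.tsv")
        write_tsv(scenes, out / "scenes.tsv")
        for f in ("ts_counts.tsv", "gene_map.bed", "gene_categories.tsv",
                  "expression.tsv", "frap_traces.tsv", "scenes.tsv"):
            write_meta(out / f, chash, seed)
        emit("simulate", {"version": __version__, "seed": seed,
                          "registry": reg.to_dict()})

    # -- burst model --------------------------------------------------------
    if "ts-fit" in config.stages:
        model_wt = burst.estimate_cluster_probability(counts_wt, reg.K)
        model_mut = burst.estimate_cluster_probability(counts_mut, reg.K)
        gof_wt = model_wt.goodness_of_fit(counts_wt)
        gof_mut = model_mut.goodness_of_fit(counts_mut)
        red = burst.probability_reduction(model_wt, model_mut)
        se_wt = math.sqrt(reg.p_wt * (1 - reg.p_wt) / (reg.K * reg.n_wt))
        se_mut = math.sqrt(reg.p_mut * (1 - reg.p_mut) / (reg.K * reg.n_mut))
        recovered("p_wt", reg.p_wt, model_wt.p_, se_wt)
        recovered("p_mut", reg.p_mut, model_mut.p_, se_mut)
        emit("ts_fit", {
            "wild_type": {"p": model_wt.p_, "mean": model_wt.mean_,
                          "n": model_wt.n_nuclei_,
                          "positive_fraction": model_wt.positive_fraction(),
                          "gof": gof_wt.to_dict()},
            "mutant": {"p": model_mut.p_, "mean": model_mut.mean_,
                       "n": model_mut.n_nuclei_,
                       "positive_fraction": model_mut.positive_fraction(),
                       "gof": gof_mut.to_dict()},
            "probability_reduction": red,
        })

    # -- cluster scan -------------------------------------------------------
    if "scan" in config.stages:
        scanner = clusters.ClusterScanner(bin_width=reg.bin_width).fit(
            gene_map, {"chrV": CHROM_LENGTH}
        )
        win_lo, win_hi, _ = CLUSTER_WINDOW
        bt = scanner.bin_table_
        overlap = bt[(bt["end"] > win_lo) & (bt["start"] < win_hi)]
        min_q = float(overlap["q_value"].min())
        write_tsv(bt, out / "bin_table.tsv")
        write_meta(out / "bin_table.tsv", chash, seed)
        emit("scan", {
            "n_clusters": len(scanner.clusters_),
            "clusters": [c.to_dict() for c in scanner.clusters_],
            "planted_window_min_q": min_q,
        })

    # -- expression stats ---------------------------------------------------
    if "expr" in config.stages:
        mean_lfc, fold = expression.mean_log2fc(mis_ids, table, "mutant")
        msp_pct = expression.family_summary(msp_ids, table, "mutant")
        se_lfc = reg.log2fc_sd / math.sqrt(reg.n_misregulated)
        recovered("effect_log2fc", reg.effect_log2fc, mean_lfc, se_lfc)
        lfc = table.set_index("gene_id")["log2fc_mutant"]
        st = expression.shift_test(lfc.loc[mis_ids], lfc.drop(mis_ids), method="ks")
        ranked = expression.rank_by_abs_log2fc(table, "mutant")
        cat_map = {g: ("spermatogenic" if g in set(mis_ids) else "other")
                   for g in table["gene_id"]}
        curve = expression.rank_enrichment(ranked[:200], cat_map, "spermatogenic")
        emit("expr", {
            "misregulated_mean_log2fc": mean_lfc,
            "misregulated_fold_change": fold,
            "msp_percent_of_wild_type": msp_pct,
            "shift_test": st.to_dict(),
            "rank_enrichment_top50": list(map(float, curve[:50])),
        })

    # -- FRAP ---------------------------------------------------------------
    if "frap" in config.stages:
        fits_foci, failed_f = frap.fit_traces(traces_foci)
        fits_hyp, failed_h = frap.fit_traces(traces_hyp)
        avg_foci = frap.average_halftime(fits_foci, n_excluded=len(failed_f))
        avg_hyp = frap.average_halftime(fits_hyp, n_excluded=len(failed_h))
        ratio = frap.compartment_ratio(fits_foci, fits_hyp)
        recovered("t_half_foci", reg.t_half_foci, avg_foci.mean_t_half, avg_foci.sem)
        recovered("t_half_hyp", reg.t_half_hyp, avg_hyp.mean_t_half, avg_hyp.sem)
        emit("frap", {
            "foci": avg_foci.to_dict(),
            "hypodermis": avg_hyp.to_dict(),
            "ratio_foci_over_hyp": ratio,
            "per_trace": [f.to_dict() for f in fits_foci + fits_hyp],
            "failed": failed_f + failed_h,
        })

    # -- colocalization -----------------------------------------------------
    if "coloc" in config.stages:
        frac, per_nucleus = coloc.coloc_fraction(scenes, reg.coloc_radius)
        foci_summary = coloc.count_foci(scenes)
        n_ts = int(per_nucleus["n_ts"].sum())
        se = math.sqrt(reg.coloc_prob * (1 - reg.coloc_prob) / n_ts)
        recovered("coloc_prob", reg.coloc_prob, frac, se)
        emit("coloc", {
            "fraction": frac,
            "n_ts": n_ts,
            "foci_range": list(foci_summary.range),
            "per_stage_mean_foci": foci_summary.per_stage_mean,
        })

    summary = {
        "version": __version__,
        "seed": seed,
        "config_hash": chash,
        "parameters": summary_rows,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    write_meta(out / "summary.json", chash, seed)
    return summary
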