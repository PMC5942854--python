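# mspkit

Quantitative analyses of spermatocyte gene-cluster transcription in
*C. elegans*, built around the msp (major sperm protein) gene family:
28 clustered genes whose transcription in primary spermatocytes is
visible as nuclear transcription sites (TS) by single-molecule FISH and
is organized by chromatin-associated SET-17 foci (msp locus bodies).

The package is for researchers quantifying smFISH TS counts, genomic
clustering of co-regulated genes, expression shifts between genotypes,
FRAP kinetics of nuclear bodies, and TS/body colocalization — and for
anyone who wants a fully synthetic, seeded re-run of that analysis chain.

## What it computes

* **Binomial burst model** — a nucleus has `K` transcribable cluster
  states (K = 4), each ON with probability `p` in a snapshot, so TS
  counts are Binomial(K, p). Estimation is moment matching
  `p̂ = mean/K`; derived quantities are the positive-nucleus fraction
  `1 − (1−p)^K`, the genotype contrast `1 − p_b/p_a`, and a goodness of
  fit `R²` (squared Pearson correlation of empirical vs model count
  frequencies).
* **Cluster scan** — 50-kb disjoint bins; per-bin upper-tail
  hypergeometric test of category-gene excess against the chromosome's
  totals; Benjamini–Hochberg FDR over occupied bins; gap-tolerant merging
  of significant bins into cluster calls.
* **Expression statistics** — category bookkeeping, mean log2FC / fold
  change summaries, family percent-of-wild-type (`100·2^mean`),
  Mann–Whitney (exact or normal) and Kolmogorov–Smirnov shift tests, rank
  enrichment curves, hypergeometric set-overlap enrichment, Pearson
  correlation, and a binary tissue-expression call.
* **FRAP kinetics** — per-trace least-squares fit of
  `I(t) = plateau − (plateau − floor)·e^{−kt}`, half-time `t½ = ln2/k`,
  per-experiment averaging (mean ± SEM) and compartment ratios.
* **Colocalization** — fraction of TS within a threshold radius (default
  0.3 μm) of the nearest focus, pooled and per nucleus; focus-count
  summaries per stage.
* **Synthetic data** — seeded generators for all of the above at the
  registered study conditions (`mspkit.ParamRegistry`).

## Worked example

```python
from mspkit import simulate as sim
from mspkit import estimate_cluster_probability, probability_reduction

wt = sim.gen_ts_counts(p=0.4375, K=4, n=141, seed=0, genotype="wild_type")
mut = sim.gen_ts_counts(p=0.205, K=4, n=153, seed=1, genotype="mutant")

m_wt = estimate_cluster_probability(wt, K=4)
m_mut = estimate_cluster_probability(mut, K=4)
print(f"wild type: mean {m_wt.mean_:.3f} TS/nucleus, p = {m_wt.p_:.4f}, "
      f"positive fraction {m_wt.positive_fraction():.3f}")
print(f"mutant:    mean {m_mut.mean_:.3f} TS/nucleus, p = {m_mut.p_:.4f}")
print(f"per-cluster probability reduction: {probability_reduction(m_wt, m_mut):.3f}")
print(f"goodness of fit R^2 = {m_wt.goodness_of_fit(wt).r_squared:.3f}")
```

prints

```
wild type: mean 1.872 TS/nucleus, p = 0.4681, positive fraction 0.920
mutant:    mean 0.817 TS/nucleus, p = 0.2042
per-cluster probability reduction: 0.564
goodness of fit R^2 = 0.977
```

Read: in this simulated wild-type sample each of the four msp cluster
states is transcribing in ~47% of snapshots, 92% of nuclei show at least
one active site, and the simulated mutation halves the per-cluster ON
probability (here 56%, sampling noise around the generating reduction of
1 − 0.205/0.4375 ≈ 53%). The `R²` compares the observed TS count
histogram with the fitted binomial distribution.

The same stages run from the shell:

```sh
mspkit simulate all --seed 0 --out data/
mspkit ts-fit --counts data/ts_counts.tsv --genotype wild_type --states 4
mspkit scan --genes data/gene_map.bed --categories data/gene_categories.tsv
mspkit frap --traces data/frap_traces.tsv
mspkit coloc --scenes data/scenes.tsv --radius 0.3
mspkit run-all --seed 0 --out run/     # everything, plus recovery summary
```

`run-all` writes per-stage JSON reports and a `summary.json` listing each
registry parameter with its recovered value and z-score; every artifact
carries a provenance sidecar (tool version, config hash, seed).

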