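# Methods

## Scope and model overview

`mspkit` implements the quantitative analyses surrounding transcription of
the *C. elegans* msp (major sperm protein) gene clusters in primary
spermatocytes: a binomial "burst" model of cluster transcriptional
activity measured by smFISH transcription-site (TS) counting, a
fixed-bin hypergeometric scan for chromosomal clusters of spermatogenic
genes, distribution-shift and enrichment statistics over gene expression
categories, single-exponential FRAP recovery kinetics of nuclear foci,
and a distance-rule colocalization score for TS/focus coincidence.
Because the underlying raw data (images, RNAseq reads) are not consumable
here, a first-class synthetic-data module generates every input at the
study conditions collected in `ParamRegistry`, and the test suite checks
that each estimator recovers its generating parameter.

## Binomial burst model

A nucleus carries `K` transcribable cluster states (default `K = 4`, the
maximum TS count observed in either genotype). A snapshot shows each
state ON independently with probability `p`, so the TS count is
`Binomial(K, p)` with mean `K·p`. Estimation is by moment matching,
`p̂ = mean(ts_count)/K`, clamped to [0, 1] — identical to maximum
likelihood for a binomial with known `K`. Registry defaults encode the
printed genotype means: wild type `1.75/4 = 0.4375` over 141 nuclei,
mutant `0.82/4 = 0.205` over 153.

Derived quantities: the positive-nucleus fraction `1 − (1−p)^K`; the
fractional probability reduction between genotypes `1 − p_b/p_a`
(invariant to `K`, since it is a ratio of means); and a goodness of fit
defined as the squared Pearson correlation between the empirical relative
frequencies and the model frequencies over counts `0..K`. The model
distribution is analytic by default; a seeded simulation mode
(`mode="simulated"`) reproduces a draw-based comparison. Zero-variance
frequency vectors make the correlation undefined; the report then carries
a `degenerate` flag and NaN rather than a number. Counts exceeding `K`
raise an error naming the offending nucleus — they falsify the assumed
state count and are never clamped. Over-dispersion relative to the
binomial is deliberately not modelled: only the genotype means are
constrained by the study, and the binomial is the stated generative law.

## Gene-cluster scan

Genes are points at their feature start on 0-based half-open coordinates
(BED convention; strand ignored — the analysis is purely positional).
Chromosomes are tiled with disjoint half-open bins of width `w`
(default 50 kb; histogram semantics, not sliding windows). For a bin with
`n` genes of which `k` are category-labelled, on a chromosome with `N`
genes of which `K_cat` are category, the enrichment p-value is the
upper-tail hypergeometric probability `P[X ≥ k]`,
`X ~ Hypergeom(N, K_cat, n)` — i.e. the test conditions on the bin's
total gene count, with the gene's own chromosome as the universe
(a genome-wide universe is available via `background="genome"`).

Multiple testing uses Benjamini–Hochberg across the *occupied* bins of
the scanned map. Bins containing no genes have p ≡ 1 under this
conditioning — they are untestable hypotheses and are excluded from the
BH family (independent filtering; occupancy depends only on gene
positions, not on category labels, so FDR control is preserved).

Cluster calls are maximal runs of bins with `q ≤` threshold, tolerating
up to `max_gap_bins` (default 1) consecutive non-significant bins in a
run's interior; the call interval is the union of its member bins and
member genes are collected from the full span. Ties in BH are handled by
the standard step-up minimum.

**Power at the synthetic scale.** The default synthetic map (400 genes,
120 category, 40 planted in one 200-kb window of a 20-Mb chromosome)
places ~11 genes in each cluster bin, which floors the attainable per-bin
p-value near `(K_cat/N)^11`. After BH correction the planted cluster
reaches `q ≤ 1e-4` in roughly two-thirds of seeds; detection at
`q ≤ 0.05` is essentially certain. A real chromosome (thousands of genes,
a lower background category fraction) is far better powered; the
synthetic scale is kept small deliberately and this resolution limit is a
property of the scale, not of the test.

## Expression statistics

Differential-expression tables carry one `log2fc_<genotype>` column per
genotype plus a significance flag; category maps assign each gene to one
of {spermatogenic, oogenic, sperm_and_oocyte, non_germline}. Summaries:
arithmetic mean log2FC with the implied fold-change `2^|mean|`; family
levels as `100·2^mean` percent of wild type (a family uniformly at
log2FC −1 reports 50%).

Shift tests between gene sets offer exact Mann–Whitney U (full
enumeration null; restricted to combined n ≤ 20), the normal
approximation with tie correction, and two-sample Kolmogorov–Smirnov
(exact null for combined n ≤ 10, asymptotic otherwise); all two-sided by
default. Both MW and KS are reported side by side by the pipeline since
either is a defensible choice per comparison. Whether mid-ranks should be
used for ties in the exact test is unsettled; ties fall back to the
tie-less enumeration null with a mid-rank U statistic.

Rank enrichment orders genes by |log2FC| descending (ties broken by
gene_id for determinism) and reports the cumulative category fraction at
each rank; the final point equals the overall category fraction. Overlap
enrichment is the upper-tail hypergeometric `P[X ≥ |A∩B|]` with an
explicitly supplied universe size — no default universe is assumed.
Pearson correlation returns `(r, R², two-tailed p)` and rejects
zero-variance input.

The tissue-expression call declares a gene expressed in a tissue iff in
*every* animal at least 2 cells of that tissue each show at least 2
transcripts. The readings of "multiple" (≥2 cells) and "more than one"
(≥2 spots) are parameters (`min_cells`, `min_transcripts`) and are echoed
in the output so the rule is never silent.

## FRAP kinetics

Traces are normalized to the pre-bleach intensity; the t = 0 point is the
normalization anchor and is excluded from fitting. Each post-bleach trace
is fitted by least squares to
`I(t) = plateau − (plateau − floor)·exp(−k·t)` with free floor and
plateau (no immobile-fraction term) and `k` bounded to (1e-5, 10) 1/s.
Initialization: floor from the first post-bleach point, plateau from the
mean of the last 10% of points, and `k` from the time at which the trace
first crosses halfway between them. Because floor and plateau are free,
fits are invariant to uniform intensity rescaling. The half-time is
`t_half = ln 2 / k` exactly.

Summaries average per-experiment half-times (mean ± SEM) — the average of
fits, never a fit of the averaged curve. Non-converged fits (constant
traces, optimizer failure) are excluded from averages and reported by
trace id, never silently dropped. The compartment ratio is the ratio of
mean half-times (foci over nucleoplasm; > 1 means slower foci). No
acquisition-photobleaching correction is applied.

## Colocalization

A transcription site is colocalized when its Euclidean distance to the
nearest focus in the same nucleus is ≤ the threshold radius (default
0.3 μm — a sub-focus scale; the original scoring was visual and prints no
radius, so the rule is parameterized). The pooled fraction is over all TS
in all scenes; nuclei without TS do not enter the denominator, and scenes
without foci count all their TS as non-colocalized. Focus counts are
summarized per nucleus, as a min–max range, and as per-stage means.

## Synthetic-data generators

All generators take an integer seed and are byte-identical under a fixed
seed. What they emulate, and what they do not:

* **TS counts** — Binomial(K, p) per nucleus at the printed genotype
  means. Real counts may be over-dispersed (stage structure, detection
  efficiency); none of that is modelled, so recovery tests validate the
  estimator, not smFISH detection.
* **Gene maps** — category genes placed uniformly inside assigned cluster
  windows (each window holds exactly its assigned count; remaining
  category genes are placed uniformly outside all windows), non-category
  genes uniform over the chromosome. Real gene spacing is not uniform.
* **Expression tables** — misregulated genes at
  `log2FC ~ N(effect, 0.2)`, others `N(0, 0.2)`; the flag marks exactly
  the misregulated set. The default effect −1.0 encodes the 2-fold
  average down-regulation of the 123-transcript set; the 28-gene msp
  family is modelled as a subset of that set. No mean–variance
  relationship or count-level noise is simulated (differential-expression
  calling itself is out of scope).
* **FRAP traces** — the single-exponential law plus iid Gaussian noise
  (sd 0.02), pre-bleach point fixed at 1, plateau 1 and floor 0 by
  default (full mobile fraction; none reported otherwise). Defaults:
  foci half-time 61 s; hypodermal nuclei 6.1 s from the printed ten-fold
  difference (no hypodermal half-time is printed). dt 2 s, duration 300 s
  (~5 half-times of the slow compartment, enough to constrain the
  plateau).
* **Nucleus scenes** — spherical nuclei of radius 2 μm (an invented but
  plausible scale; all colocalization math depends only on the threshold
  radius), 4–14 foci uniform in count and position, TS counts from the
  wild-type burst model. Each TS is placed within the threshold radius of
  a random focus with probability 0.90, else uniformly at distance
  > radius from every focus, so the downstream fraction estimates the
  generating rate exactly. Stage labels derive from focus-count terciles
  (focus number grows with maturation); real stage effects on TS activity
  are not modelled.

Noise defaults (log2FC sd 0.2, FRAP sd 0.02) were chosen once so that
parameter recovery is non-trivial but reliable at the study sample sizes.

## Pipeline scale and numerical choices

The `run-all` pipeline and the acceptance script use the sample sizes
above (141/153 nuclei, 16 + 10 FRAP traces, 123 flagged genes of 2000,
100 scenes, one 20-Mb chromosome with 400 genes), completing in seconds.
The expression-table universe of 2000 genes is a desk-scale stand-in for
a transcriptome; only the flagged-set statistics depend on it weakly.
BH q-values come from `statsmodels`; hypergeometric, binomial,
Mann–Whitney, KS and Pearson statistics from `scipy.stats`; curve fitting
from `scipy.optimize.curve_fit`. Estimator classes follow the
scikit-learn conventions (`fit`, fitted attributes with trailing
underscores, `get_params`/`set_params`) so they compose with sklearn
tooling.

## Known limitations

* The binomial model fixes `K`; inferring `K`, temporal on/off kinetics
  and TS intensities are out of scope.
* The cluster scan cannot reproduce the real chromosome coordinates of
  the published clusters (not printed); it reproduces the method.
* The planted-cluster benchmark at the default synthetic scale is
  power-limited at `q ≤ 1e-4` (see above).
* Quantities that require the study's unreleased measurements — the
  123/60/40/23 category partition, the 26/28 msp overlap, 53/60
  in-cluster count, the empirical-histogram R² values (0.853/0.987) and
  the fertility correlation r = 0.9981 — are supported as computations on
  user data but are not reproducible from synthetic defaults; they appear
  only as documentation examples.
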