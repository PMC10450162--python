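# Methods

## Pair catalog

Genes and non-coding transcripts are single stranded intervals, 1-based
inclusive internally; BED6 input (0-based half-open) is converted at the
I/O boundary, and chromosome names are compared as exact strings (no "chr"
aliasing — silent aliasing hides input errors). Unstranded records are
rejected outright, since the analysis is meaningless without strand.

The catalog is the composition of three rules:

1. **Overlap join.** Every (gene, ncRNA) pair on the same chromosome
   sharing at least one base, strand ignored; the intersection interval is
   [max(starts), min(ends)]. Abutting intervals (end + 1 = start) do not
   overlap. Implemented with a per-chromosome interval tree over the
   ncRNAs; an O(n·m) double-loop reference implementation lives in the test
   suite and the two are asserted identical on random instances.
2. **Opposite-strand filter.** The antisense configuration.
3. **Per-gene resolution.** One pair per gene, keeping the ncRNA of
   maximal *annotated* length (a property of the transcript, not of the
   overlap). Ties — absent from the underlying procedure's description —
   break deterministically on smaller ncRNA start, then lexicographically
   smaller id, making the catalog invariant to input order. A ncRNA may
   appear under several genes; only the gene side is resolved.

The builder records candidate-pair, opposite-strand-pair and distinct
gene/ncRNA counts at each stage, because external catalogs report such
aggregates in more than one unit and a user should be able to check any of
them.

## Differential expression

A deliberately transparent two-group NB workflow, fully specified by this
note plus two constants (pseudocount c₀ = 0.5, dispersion floor 10⁻⁸, both
exposed as arguments):

* **Normalization** — median-of-ratios: for features with all-positive
  counts, s_j = median_i(K_ij / geomean_i); factors are not rescaled
  afterward. A matrix with no all-positive feature is an error (advice:
  filter or pre-add a pseudocount) rather than a silent fallback.
* **Dispersion** — per-feature method of moments on normalized counts with
  condition means removed: α̂_i = max(α_floor, (v_i − m_i)/m_i²), where m_i
  is the grand mean and v_i the within-condition pooled variance
  (denominator n − 2). There is no shrinkage toward a mean–dispersion
  trend: at the replicate numbers this package targets (≥ 6 per condition
  for estimation-quality results) the simple estimator is adequate, and its
  behaviour is fully predictable. This is a documented deviation from
  shrinkage-based estimators such as DESeq2's; a cross-check test confirms
  the two agree closely on log2FC for well-behaved simulated data.
* **Wald test** — log2fc = log2((μ̂_T + c₀)/(μ̂_C + c₀)) with
  Var(μ̂_c) = (μ̂_c + α̂μ̂_c²)/n_c and
  se = (1/ln 2)·√(Var(μ̂_T)/(μ̂_T + c₀)² + Var(μ̂_C)/(μ̂_C + c₀)²);
  p = 2Φ(−|log2fc/se|). All-zero features are flagged untestable and get
  log2fc = 0, p = 1. No independent filtering, no outlier replacement.
* **FDR** — Benjamini–Hochberg step-up (delegated to statsmodels), output
  aligned to input order.

**Calibration caveat.** The normal reference for the Wald statistic is an
approximation: with 10v10 replicates the plug-in of the estimated
dispersion makes the statistic behave like a t variable with ~18 df, so the
realized type-I error at nominal 0.05 is ≈ 0.065 rather than 0.05 (with the
true dispersion supplied, simulations give ≈ 0.049). This mild
anticonservativeness is inherent to the prescribed plug-in and shrinks with
replicate number; users who need exact levels at small n should treat
p-values near the threshold with care.

## Correlation

Pairs are selected on the gene (sense) q-value only, with strict
inequality (q < threshold, default 0.25); requiring ncRNA significance as
well is available as an explicit flag for sensitivity analyses. "Log
fold-change" is log2 throughout — the base rescales both axes identically
and cannot change r. Pearson's product-moment r is computed with a
two-sided t-test on n − 2 df (scipy); r is reported as undefined, with an
explanatory status rather than an exception, when fewer than 3 pairs
survive selection or a log2FC vector is constant.

## Synthetic data

The generator emulates the statistical structure of a two-condition
nascent-transcription experiment, not its sequence content:

* **Annotation.** Non-overlapping genes (lengths U[500, 3000] bp, gaps
  U[200, 1000] bp) on toy chromosomes of ≤ 500 genes, alternating strands.
  A chosen fraction of genes receives one opposite-strand ncRNA (length
  U[200, 1500] bp) overlapping the gene's 3′ half by ≥ 100 bp — the
  canonical antisense arrangement arising from terminator-proximal
  initiation. The ncRNA's extension beyond its gene is capped at 600 bp
  (below minimum gap + gene length), so a planted partner can reach at most
  the adjacent gene — which shares the ncRNA's strand by construction and
  is removed by the strand filter — keeping the planted pairing
  identifiable in the catalog. Decoys (default 5% each): intergenic ncRNAs
  with no overlap, and same-strand overlapping ncRNAs; both must be
  rejected by the pairing rules.
* **Effects.** Gene true log2FC g_i ~ N(0, σ²) with σ = effect_sd (default
  1 log2 unit); the paired ncRNA gets a_i = ρ·g_i + √(1 − ρ²)·ε_i,
  ε_i ~ N(0, σ²), so Corr(g, a) = ρ exactly in distribution. Unpaired
  ncRNAs get independent effects.
* **Counts.** Baselines μ_i ~ LogNormal(7.0, 0.5) (median ≈ 1100, deep
  coverage typical of well-powered experiments); library-size factors
  s_j ~ U[0.7, 1.3] shared between the gene and ncRNA matrices (they
  describe the same samples); counts NB(mean = s_j·μ_i·2^{lfc·1[treated]},
  Var = μ + αμ²) with α = 0.01 by default and 6 replicates per condition.
  The NB (mean, α) convention is the same one the estimator assumes, so
  generator and test share a single parameterization. α = 0 degenerates to
  Poisson.
* **Reproducibility.** One seed feeds spawned child generators per stage
  (effects, gene counts, ncRNA counts), so bundles are byte-identical per
  seed and stages can be regenerated independently.

What the generator does **not** emulate: transcript isoform structure,
labeling kinetics, positional biases, GC effects, mean–dispersion trends,
or correlated counts between overlapping features on the two strands.
Passing recovery tests therefore demonstrates correctness of the catalog
logic, the estimators and their composition under the stated model — not
robustness to the full messiness of real libraries.

Because the correlation is planted on *true* effects while the pipeline
correlates *estimated* log2FCs, the recovered r is attenuated toward 0 by
estimation noise in both coordinates; under the default conditions the
attenuation is ≈ 0.01–0.03 and the recovery tests allow ±0.05. With high
dispersion and few replicates the attenuation grows but never inflates r
on average, which a dedicated test asserts.

## Pipeline

The orchestrator validates inputs up front (sample sheet consistency, count
ids ⊆ annotation ids — mismatches dropped and counted in the summary),
runs the three stages, and writes every table as TSV plus a summary JSON
with a `schema_version` field so downstream consumers can pin keys. An
empty catalog is a distinct error (CLI exit code 3). Stage counts are
monotone (candidates ≥ opposite-strand ≥ catalog ≥ retained) and asserted
in tests. Reruns on identical inputs are byte-identical.

## Problem sizes

The test suite and acceptance script use 1500-gene datasets with 6v6
replicates for recovery (seconds per run), 2000-feature 10v10 matrices for
null calibration, and 50 random instances up to 500 × 1000 features for
the brute-force pairing cross-check — sizes at which the Monte-Carlo error
of each asserted quantity is several times smaller than its tolerance.
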