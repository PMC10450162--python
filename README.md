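# antisense-pairs

Strand-aware cataloging of gene / antisense non-coding transcript pairs,
two-condition negative-binomial differential expression, and correlation of
the pairs' log2 fold-changes.

## The problem

In compact genomes such as budding yeast, a large fraction of coding genes
are overlapped by a non-coding transcript on the opposite strand (CUTs,
SUTs, XUTs and other antisense lncRNAs). A recurring question is whether
these antisense transcripts repress their sense partner: if they do,
perturbations that change antisense levels should move sense and antisense
expression in *opposite* directions. The direct way to ask this genome-wide
is to (1) catalog every gene paired with an opposite-strand overlapping
ncRNA, (2) measure differential expression of both members of each pair
between two conditions (e.g. a regulatory-factor deletion versus wild
type), and (3) correlate the pairs' log2 fold-changes: a strong positive
Pearson r argues against global antisense-mediated repression, a negative r
would support it, and r ≈ 0 indicates decoupling.

This package implements that analysis as a tested pipeline:

* **annotations** — GFF3 / BED6 / TSV readers normalized to 1-based
  inclusive coordinates with strict strand validation;
* **pairing** — interval-tree overlap join of genes against ncRNAs
  (≥ 1 shared base), opposite-strand filter, and longest-ncRNA-per-gene
  resolution, with stage-count bookkeeping;
* **diffexpr** — a self-contained DESeq-style NB workflow: median-of-ratios
  size factors s_j = median_i (K_ij / (∏_v K_iv)^(1/m)), per-feature
  method-of-moments dispersion α̂_i = max(α_floor, (v_i − m_i)/m_i²), a Wald
  test on log2((μ̂_T + c₀)/(μ̂_C + c₀)) with delta-method standard error
  under Var = μ + αμ², and Benjamini–Hochberg FDR;
* **correlation** — selection of pairs significant at the gene-level FDR
  threshold (default q < 0.25) and Pearson r of (gene log2FC, ncRNA log2FC)
  with a two-sided t-test on n − 2 df;
* **synthetic** — a generator of toy annotations and NB count matrices with
  a *planted* correlation ρ between true sense and antisense effects, so
  the whole pipeline is validated by parameter recovery;
* **pipeline / cli** — one `antisense-pairs` command orchestrating
  pairs → DE × 2 → correlate with a YAML config and a versioned JSON
  summary.

## Worked example

Generate a dataset with a planted effect correlation of 0.9 and run the
full pipeline on it:

```sh
python analysis/01_simulate_datasets.py
python analysis/02_run_pipeline.py
python analysis/03_summarize_correlations.py
```

which prints (1500 genes, each with one antisense partner, 6v6 replicates,
dispersion 0.01):

```
rho0: 1500 catalog pairs, 1500 retained, r = -0.005 (p = 0.858)
rho0.5: 1500 catalog pairs, 1500 retained, r = 0.475 (p = 2.34e-85)
rho0.9: 1500 catalog pairs, 1500 retained, r = 0.884 (p = 0)
```

Reading this: the catalog recovers exactly the 1500 planted opposite-strand
pairs (intergenic and same-strand decoy ncRNAs are rejected); the Pearson r
of the estimated log2 fold-changes tracks the planted ρ closely — slightly
attenuated (0.884 vs 0.9, 0.475 vs 0.5) because both coordinates carry
counting noise — and the null dataset is flat. The same machinery runs on
real annotation and count files:

```sh
antisense-pairs run --config run.yaml        # full pipeline
antisense-pairs pairs --genes genes.gff3 --genes-format gff3 \
    --ncrnas xuts.tsv --ncrnas-format tsv --out catalog.tsv
```

The run summary also reports the candidate-pair, opposite-strand-pair and
distinct gene/ncRNA counts at each stage so catalogs built from published
coordinate sets can be checked against reported totals.

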