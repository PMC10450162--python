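"""Synthetic antisense-overlap annotations and NB count matrices.

The generator emulates the statistical structure of a two-condition
nascent-transcription experiment over sense/antisense pairs:

* a toy genome of non-overlapping genes on alternating strands, a chosen
  fraction of which receive one opposite-strand ncRNA overlapping the
  gene's 3' half, plus intergenic and same-strand decoy ncRNAs that the
  pairing stage must reject;
* true log2 fold-changes drawn so that paired (gene, ncRNA) effects have a
  planted Pearson correlation ``rho``;
* negative-binomial counts parameterized by (mean, dispersion alpha) with
  Var = mu + alpha * mu^2 — the same convention the DE estimator assumes —
  under log-normal baselines and uniform library-size factors.

Because the correlation is planted on the *true* effects, the correlation
recovered from estimated log2FCs is slightly attenuated by counting noise;
recovery tolerances in the tests account for that.

All randomness flows from a single seed through spawned child generators,
one per stage, so annotation and counts are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import FeatureSet, GenomicFeature, write_bed6, write_tsv
from .pairing import PairCatalog

__all__ = [
    "SimConfig",
    "TrueEffects",
    "simulate_annotation",
    "simulate_counts",
    "simulate_dataset",
]

# ncRNA extension beyond the gene body is capped below the minimum
# gap + gene length (200 + 500), so a planted antisense partner can touch at
# most the adjacent (same-strand-as-ncRNA) gene and the planted pairing
# stays identifiable in the catalog.
_MAX_NCRNA_OVERHANG = 600

_GENE_LEN = (500, 3000)
_GAP_LEN = (200, 1000)
_NCRNA_LEN = (200, 1500)
_MIN_AS_OVERLAP = 100
_GENES_PER_CHROM = 500


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a well-powered nascent-transcription-style experiment:
    1500 genes, every gene with an antisense partner, a strong planted
    effect correlation, low biological dispersion, deeply covered features
    (median baseline ~1100 counts), and 6 replicates per condition.
    """

    n_genes: int = 1500
    antisense_fraction: float = 1.0
    rho: float = 0.9
    effect_sd: float = 1.0
    dispersion: float = 0.01
    mean_log_mu: float = 7.0   # natural-log scale: median baseline e^7 ~ 1100
    sd_log_mu: float = 0.5
    n_control: int = 6
    n_treatment: int = 6
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    decoy_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.antisense_fraction <= 1.0):
            raise ValueError("antisense_fraction must lie in [0, 1]")
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [-1, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_control < 2 or self.n_treatment < 2:
            raise ValueError("replicate counts must be >= 2")
        if self.effect_sd < 0 or self.sd_log_mu < 0:
            raise ValueError("scale parameters must be >= 0")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must be positive and ordered")


@dataclass
class TrueEffects:
    """Ground truth for recovery tests: per-feature true log2FCs, the
    planted gene<->ncRNA pairing, and per-sample true size factors."""

    gene_lfc: pd.Series          # index: gene ids
    ncrna_lfc: pd.Series         # index: ncRNA ids (decoys included)
    pairs: list[tuple[str, str]]  # (gene_id, ncrna_id) planted partners
    size_factors: pd.Series      # index: sample ids

    def paired_lfc(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "ncrna_id": n,
             "gene_lfc": self.gene_lfc[g], "ncrna_lfc": self.ncrna_lfc[n]}
            for g, n in self.pairs
        ]
        return pd.DataFrame(rows, columns=["gene_id", "ncrna_id", "gene_lfc", "ncrna_lfc"])


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_annotation(
    config: SimConfig, seed: int | None = None
) -> tuple[FeatureSet, FeatureSet, list[tuple[str, str]]]:
    """Build toy gene and ncRNA annotations.

    Genes are laid end to end (lengths U[500, 3000], gaps U[200, 1000]) on
    chromosomes of at most 500 genes, alternating strands.  A
    ``round(antisense_fraction * n_genes)`` subset gets one opposite-strand
    ncRNA overlapping the gene's 3' half by at least 100 bases.  Decoys —
    ``decoy_fraction`` each of intergenic (non-overlapping) and same-strand
    overlapping ncRNAs — exercise the pairing filters.

    Returns (genes, ncrnas, planted_pairs).
    """
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(config.seed if seed is None else seed))
    )
    genes: list[GenomicFeature] = []
    gaps: list[tuple[str, int, int]] = []  # (chrom, gap_start, gap_end) 1-based
    pos = 1000
    chrom_i = 1
    for i in range(config.n_genes):
        if i > 0 and i % _GENES_PER_CHROM == 0:
            chrom_i += 1
            pos = 1000
        glen = int(rng.integers(_GENE_LEN[0], _GENE_LEN[1] + 1))
        gap = int(rng.integers(_GAP_LEN[0], _GAP_LEN[1] + 1))
        chrom = f"chr{chrom_i}"
        start = pos
        end = start + glen - 1
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GenomicFeature(f"gene_{i + 1:05d}", chrom, start, end, strand))
        gaps.append((chrom, end + 1, end + gap))
        pos = end + gap + 1

    n_as = int(round(config.antisense_fraction * config.n_genes))
    as_idx = rng.choice(config.n_genes, size=n_as, replace=False) if n_as else np.array([], int)
    as_idx = np.sort(as_idx)
    ncrnas: list[GenomicFeature] = []
    planted: list[tuple[str, str]] = []
    nc_kinds = np.array(["CUT", "SUT", "XUT"])
    for k, gi in enumerate(as_idx):
        g = genes[gi]
        half = g.length // 2
        nclen = int(rng.integers(_NCRNA_LEN[0], _NCRNA_LEN[1] + 1))
        max_ov = min(nclen, half)
        ov = int(rng.integers(_MIN_AS_OVERLAP, max_ov + 1)) if max_ov > _MIN_AS_OVERLAP else max_ov
        nclen = ov + min(nclen - ov, _MAX_NCRNA_OVERHANG)
        if g.strand == "+":
            # 3' half is the right half; ncRNA covers the gene's 3' end and
            # extends downstream into the gap.
            nstart = g.end - ov + 1
            nend = nstart + nclen - 1
        else:
            nend = g.start + ov - 1
            nstart = max(1, nend - nclen + 1)
        nc = GenomicFeature(
            f"as_{k + 1:05d}", g.chrom, nstart, nend,
            "-" if g.strand == "+" else "+",
            kind=str(rng.choice(nc_kinds)),
        )
        ncrnas.append(nc)
        planted.append((g.feature_id, nc.feature_id))

    n_decoy = int(round(config.decoy_fraction * config.n_genes))
    wide_gaps = [g for g in gaps if g[2] - g[1] + 1 >= 150]
    for k in range(n_decoy):
        chrom, gs, ge = wide_gaps[int(rng.integers(len(wide_gaps)))]
        width = ge - gs + 1
        dlen = int(rng.integers(100, min(400, width) + 1))
        dstart = gs + int(rng.integers(0, width - dlen + 1))
        ncrnas.append(GenomicFeature(
            f"decoy_ig_{k + 1:04d}", chrom, dstart, dstart + dlen - 1,
            str(rng.choice(["+", "-"])), kind="ncRNA_other",
        ))
    for k in range(n_decoy):
        g = genes[int(rng.integers(config.n_genes))]
        ov = int(rng.integers(_MIN_AS_OVERLAP, min(g.length, 500) + 1))
        dstart = g.start + int(rng.integers(0, g.length - ov + 1))
        dlen = ov + int(rng.integers(0, 200))
        ncrnas.append(GenomicFeature(
            f"decoy_ss_{k + 1:04d}", g.chrom, dstart, dstart + dlen - 1,
            g.strand, kind="ncRNA_other",
        ))

    return (
        FeatureSet(genes, label="genes"),
        FeatureSet(ncrnas, label="ncRNAs"),
        planted,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, dispersion alpha) with Var = mu + alpha mu^2; alpha=0 is Poisson."""
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _counts_for(
    rng: np.random.Generator,
    feature_ids: list[str],
    mu: np.ndarray,
    lfc: np.ndarray,
    sf: np.ndarray,
    config: SimConfig,
) -> pd.DataFrame:
    n_c, n_t = config.n_control, config.n_treatment
    sample_ids = [f"ctrl_{j + 1}" for j in range(n_c)] + [f"trt_{j + 1}" for j in range(n_t)]
    is_trt = np.array([0] * n_c + [1] * n_t)
    mean = mu[:, None] * (2.0 ** (lfc[:, None] * is_trt[None, :])) * sf[None, :]
    counts = _nb_draw(rng, mean, config.dispersion)
    return pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"),
                        columns=sample_ids)


def simulate_counts(
    genes: FeatureSet,
    ncrnas: FeatureSet,
    pairs: list[tuple[str, str]],
    config: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TrueEffects]:
    """Draw two-condition NB count matrices with the planted effect correlation.

    Gene true log2FCs are N(0, effect_sd^2); each planted partner ncRNA gets
    ``a = rho * g + sqrt(1 - rho^2) * eps`` with eps ~ N(0, effect_sd^2), so
    Corr(g, a) = rho exactly in distribution.  Unpaired ncRNAs get
    independent effects.  One shared set of library-size factors applies to
    both matrices (the matrices describe the same samples).
    """
    rng_fx, rng_gene, rng_nc = _spawn(config.seed if seed is None else seed, 3)

    g_lfc = rng_fx.normal(0.0, config.effect_sd, size=len(genes))
    gene_lfc = pd.Series(g_lfc, index=genes.ids)
    paired_nc = {n: g for g, n in pairs}
    eps = rng_fx.normal(0.0, config.effect_sd, size=len(ncrnas))
    nc_lfc_vals = np.empty(len(ncrnas))
    for i, nc in enumerate(ncrnas):
        if nc.feature_id in paired_nc:
            nc_lfc_vals[i] = (
                config.rho * gene_lfc[paired_nc[nc.feature_id]]
                + np.sqrt(1.0 - config.rho**2) * eps[i]
            )
        else:
            nc_lfc_vals[i] = eps[i]
    ncrna_lfc = pd.Series(nc_lfc_vals, index=ncrnas.ids)

    mu_genes = rng_fx.lognormal(config.mean_log_mu, config.sd_log_mu, size=len(genes))
    mu_nc = rng_fx.lognormal(config.mean_log_mu, config.sd_log_mu, size=len(ncrnas))
    n_samples = config.n_control + config.n_treatment
    sf = rng_fx.uniform(*config.size_factor_range, size=n_samples)

    gene_counts = _counts_for(rng_gene, genes.ids, mu_genes, g_lfc, sf, config)
    nc_counts = _counts_for(rng_nc, ncrnas.ids, mu_nc, nc_lfc_vals, sf, config)

    truth = TrueEffects(
        gene_lfc=gene_lfc,
        ncrna_lfc=ncrna_lfc,
        pairs=list(pairs),
        size_factors=pd.Series(sf, index=list(gene_counts.columns)),
    )
    return gene_counts, nc_counts, truth


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> dict:
    """Generate and write a full dataset bundle; returns the manifest.

    Files written: ``genes.bed``, ``ncrnas.bed``, ``ncrnas.tsv`` (with
    kinds), ``gene_counts.tsv``, ``ncrna_counts.tsv``, ``samples.tsv``,
    ``truth.tsv`` (planted pairs + true log2FCs), ``manifest.json``
    (config, seed, per-file SHA-256).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, ncrnas, planted = simulate_annotation(config)
    gene_counts, nc_counts, truth = simulate_counts(genes, ncrnas, planted, config)

    write_bed6(genes, out / "genes.bed")
    write_bed6(ncrnas, out / "ncrnas.bed")
    write_tsv(ncrnas, out / "ncrnas.tsv")
    gene_counts.to_csv(out / "gene_counts.tsv", sep="\t")
    nc_counts.to_csv(out / "ncrna_counts.tsv", sep="\t")
    samples = pd.DataFrame({
        "sample_id": list(gene_counts.columns),
        "condition": ["control"] * config.n_control + ["treatment"] * config.n_treatment,
    })
    samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    truth.paired_lfc().to_csv(out / "truth.tsv", sep="\t", index=False,
                              float_format="%.10g")

    files = ["genes.bed", "ncrnas.bed", "ncrnas.tsv", "gene_counts.tsv",
             "ncrna_counts.tsv", "samples.tsv", "truth.tsv"]
    manifest = {
        "config": dataclasses.asdict(config),
        "files": {f: _sha256(out / f) for f in files},
        "n_planted_pairs": len(planted),
    }
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
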