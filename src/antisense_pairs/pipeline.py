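"""End-to-end orchestration: pair catalog -> DE on both strands -> correlation.

Given annotation files, two count matrices (genes and ncRNAs over the same
samples), and a sample sheet, :func:`run_pipeline` writes the pair catalog,
both DE tables, the per-pair log2FC table, and a versioned summary JSON.
The run is deterministic given identical inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotations import FeatureSet, read_features
from .correlation import correlate_pairs, scatter_plot
from .diffexpr import CountMatrix, DiffExprError, nb_wald_test, read_count_matrix, write_de_table
from .pairing import build_pair_catalog, write_catalog

__all__ = ["RunConfig", "PipelineError", "EmptyCatalogError", "run_pipeline"]

SCHEMA_VERSION = 1

logger = logging.getLogger("antisense_pairs")


class PipelineError(Exception):
    pass


class EmptyCatalogError(PipelineError):
    """No sense/antisense pairs found — nothing to correlate."""


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    genes: str
    ncrnas: str
    gene_counts: str
    ncrna_counts: str
    samples: str
    out_dir: str
    genes_format: str = "bed6"
    ncrnas_format: str = "bed6"
    fdr_threshold: float = 0.25
    require_ncrna_significant: bool = False
    make_plot: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_threshold <= 1.0):
            raise PipelineError(
                f"fdr_threshold must lie in (0, 1], got {self.fdr_threshold}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise PipelineError("run config must be a flat key-value document")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _restrict_counts(cm: CountMatrix, features: FeatureSet, what: str) -> tuple[CountMatrix, int]:
    """Drop count rows whose ids are absent from the annotation set."""
    keep = [i for i, fid in enumerate(cm.feature_ids) if fid in features]
    dropped = len(cm.feature_ids) - len(keep)
    if dropped:
        logger.warning("%s: dropped %d count rows absent from annotations "
                       "(%d kept)", what, dropped, len(keep))
    if dropped == 0:
        return cm, 0
    return CountMatrix(
        feature_ids=[cm.feature_ids[i] for i in keep],
        sample_ids=cm.sample_ids,
        counts=cm.counts[keep, :],
        condition=cm.condition,
    ), dropped


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for name in ("genes", "ncrnas", "gene_counts", "ncrna_counts", "samples"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise PipelineError(f"input {name!r} not found: {p}")

    genes = read_features(config.genes, config.genes_format, kind_default="gene",
                          label="genes")
    ncrnas = read_features(config.ncrnas, config.ncrnas_format,
                           kind_default="ncRNA_other", label="ncRNAs")
    logger.info("loaded %d genes, %d ncRNAs", len(genes), len(ncrnas))

    catalog = build_pair_catalog(genes, ncrnas)
    write_catalog(catalog, out / "pair_catalog.tsv")
    logger.info("pair catalog: %s", catalog.summary)
    if len(catalog) == 0:
        raise EmptyCatalogError(
            "no opposite-strand overlapping (gene, ncRNA) pairs were found"
        )

    gene_cm = read_count_matrix(config.gene_counts, config.samples)
    nc_cm = read_count_matrix(config.ncrna_counts, config.samples)
    if gene_cm.sample_ids != nc_cm.sample_ids:
        raise PipelineError("gene and ncRNA count matrices list different samples")
    gene_cm, gene_rows_dropped = _restrict_counts(gene_cm, genes, "gene counts")
    nc_cm, nc_rows_dropped = _restrict_counts(nc_cm, ncrnas, "ncRNA counts")

    try:
        de_genes = nb_wald_test(gene_cm)
        de_ncrnas = nb_wald_test(nc_cm)
    except DiffExprError as exc:
        raise PipelineError(f"differential expression failed: {exc}") from exc
    write_de_table(de_genes, out / "de_genes.tsv")
    write_de_table(de_ncrnas, out / "de_ncrnas.tsv")

    result = correlate_pairs(
        catalog, de_genes, de_ncrnas,
        fdr_threshold=config.fdr_threshold,
        require_ncrna_significant=config.require_ncrna_significant,
    )
    result.write(out / "pair_log2fc.tsv")
    if config.make_plot and result.n_pairs >= 1:
        scatter_plot(result, out / "correlation_scatter.png")

    summary = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "n_genes": len(genes),
        "n_ncrnas": len(ncrnas),
        **catalog.summary,
        "gene_count_rows_dropped": gene_rows_dropped,
        "ncrna_count_rows_dropped": nc_rows_dropped,
        "fdr_threshold": config.fdr_threshold,
        "n_pairs_retained": result.n_pairs,
        "n_pairs_dropped_missing_de": result.n_dropped_missing,
        "r": result.r,
        "r_pvalue": result.pvalue,
        "status": result.status,
        "outputs": {
            "pair_catalog": str(out / "pair_catalog.tsv"),
            "de_genes": str(out / "de_genes.tsv"),
            "de_ncrnas": str(out / "de_ncrnas.tsv"),
            "pair_log2fc": str(out / "pair_log2fc.tsv"),
        },
    }
    with open(out / "summary.json", "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("retained %d pairs at FDR < %g: r=%s",
                result.n_pairs, config.fdr_threshold, result.r)
    return summary
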