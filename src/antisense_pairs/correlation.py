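"""Correlation of sense and antisense log2 fold-changes over a pair catalog.

The catalog gives the gene <-> ncRNA pairing; differential-expression tables
for both strands (same contrast orientation, treatment over control) supply
log2 fold-changes.  Pairs are selected by the gene-level BH q-value at an
FDR threshold (strict ``q < threshold``; by default the ncRNA's q-value
plays no role), and the Pearson product-moment correlation of the two
log2FC vectors is computed with a two-sided t-test p-value (n - 2 df).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .pairing import PairCatalog

__all__ = [
    "CorrelationError",
    "PairCorrelationResult",
    "filter_significant",
    "pearson",
    "correlate_pairs",
]


class CorrelationError(Exception):
    pass


@dataclass
class PairCorrelationResult:
    """Pearson r over retained pairs, its p-value, and the per-pair table.

    ``r`` and ``pvalue`` are ``None`` when fewer than 3 pairs survive
    selection or either log2FC vector is constant (``status`` explains).
    """

    n_pairs: int
    r: float | None
    pvalue: float | None
    table: pd.DataFrame
    status: str = "ok"
    n_dropped_missing: int = 0

    def summary_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "r": self.r,
            "pvalue": self.pvalue,
            "status": self.status,
            "n_dropped_missing": self.n_dropped_missing,
        }

    def write(self, table_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.table.to_csv(table_path, sep="\t", index=False, float_format="%.10g")
        if summary_path is not None:
            with open(summary_path, "wt", encoding="utf-8") as fh:
                json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")


def _check_threshold(fdr_threshold: float) -> None:
    if not (0.0 < fdr_threshold <= 1.0):
        raise CorrelationError(
            f"fdr_threshold must lie in (0, 1], got {fdr_threshold}"
        )


def _pair_table(
    catalog: PairCatalog,
    de_genes: pd.DataFrame,
    de_ncrnas: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Join gene/ncRNA log2FC and gene q-value onto the catalog pairs.

    Pairs whose gene or ncRNA is absent from the DE tables are dropped; the
    dropped count is returned for logging.
    """
    gene_lfc = de_genes.set_index("feature_id")
    nc_lfc = de_ncrnas.set_index("feature_id")
    rows = []
    dropped = 0
    for p in catalog:
        if p.gene_id not in gene_lfc.index or p.ncrna_id not in nc_lfc.index:
            dropped += 1
            continue
        g = gene_lfc.loc[p.gene_id]
        n = nc_lfc.loc[p.ncrna_id]
        rows.append(
            {
                "gene_id": p.gene_id,
                "ncrna_id": p.ncrna_id,
                "gene_log2fc": float(g["log2fc"]),
                "ncrna_log2fc": float(n["log2fc"]),
                "gene_qvalue": float(g["qvalue"]),
                "ncrna_qvalue": float(n["qvalue"]),
            }
        )
    cols = ["gene_id", "ncrna_id", "gene_log2fc", "ncrna_log2fc",
            "gene_qvalue", "ncrna_qvalue"]
    return pd.DataFrame(rows, columns=cols), dropped


def filter_significant(
    catalog: PairCatalog,
    de_genes: pd.DataFrame,
    fdr_threshold: float,
    de_ncrnas: pd.DataFrame | None = None,
    require_ncrna_significant: bool = False,
) -> list[str]:
    """Gene ids of catalog pairs significant at the gene-level FDR threshold.

    Selection uses the gene (sense) q-value only — strict ``q < threshold``.
    ``require_ncrna_significant`` additionally constrains the ncRNA q-value
    (a sensitivity-analysis mode, off by default).
    """
    _check_threshold(fdr_threshold)
    gene_q = de_genes.set_index("feature_id")["qvalue"]
    nc_q = (
        de_ncrnas.set_index("feature_id")["qvalue"]
        if de_ncrnas is not None
        else None
    )
    kept = []
    for p in catalog:
        if p.gene_id not in gene_q.index:
            continue
        if not (gene_q[p.gene_id] < fdr_threshold):
            continue
        if require_ncrna_significant:
            if nc_q is None:
                raise CorrelationError(
                    "require_ncrna_significant needs the ncRNA DE table"
                )
            if p.ncrna_id not in nc_q.index or not (nc_q[p.ncrna_id] < fdr_threshold):
                continue
        kept.append(p.gene_id)
    return kept


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment r with a two-sided t-test p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise CorrelationError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CorrelationError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlate_pairs(
    catalog: PairCatalog,
    de_genes: pd.DataFrame,
    de_ncrnas: pd.DataFrame,
    fdr_threshold: float = 0.25,
    require_ncrna_significant: bool = False,
) -> PairCorrelationResult:
    """Join DE onto the catalog, select significant pairs, correlate log2FCs."""
    _check_threshold(fdr_threshold)
    table, dropped = _pair_table(catalog, de_genes, de_ncrnas)
    keep = table["gene_qvalue"] < fdr_threshold
    if require_ncrna_significant:
        keep &= table["ncrna_qvalue"] < fdr_threshold
    retained = table[keep].reset_index(drop=True)
    n = len(retained)
    if n < 3:
        return PairCorrelationResult(
            n_pairs=n, r=None, pvalue=None, table=retained,
            status=f"fewer than 3 pairs retained (n={n}); r undefined",
            n_dropped_missing=dropped,
        )
    x = retained["gene_log2fc"].to_numpy()
    y = retained["ncrna_log2fc"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PairCorrelationResult(
            n_pairs=n, r=None, pvalue=None, table=retained,
            status="a log2FC vector is constant; r undefined",
            n_dropped_missing=dropped,
        )
    r, p = pearson(x, y)
    return PairCorrelationResult(
        n_pairs=n, r=r, pvalue=p, table=retained, n_dropped_missing=dropped
    )


def scatter_plot(result: PairCorrelationResult, path: str | Path) -> None:
    """Scatter of sense vs antisense log2FC with r annotated (one per run)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(
        result.table["gene_log2fc"], result.table["ncrna_log2fc"],
        s=8, alpha=0.4, edgecolors="none",
    )
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("sense (gene) log2 fold-change")
    ax.set_ylabel("antisense (ncRNA) log2 fold-change")
    if result.r is not None:
        stars = ""
        if result.pvalue is not None:
            stars = "***" if result.pvalue < 1e-3 else ("**" if result.pvalue < 1e-2 else ("*" if result.pvalue < 0.05 else ""))
        ax.annotate(
            f"r = {result.r:.2f}{stars}\nn = {result.n_pairs}",
            xy=(0.95, 0.05), xycoords="axes fraction", ha="right", va="bottom",
        )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
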