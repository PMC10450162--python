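"""Two-condition negative-binomial differential expression.

A transparent, self-contained DESeq-style workflow for a simple two-group
contrast (treatment versus control):

* median-of-ratios size factors;
* per-feature method-of-moments dispersion on normalized counts, pooled
  within conditions (no shrinkage toward a mean–dispersion trend);
* Wald test on the log2 fold-change of condition means, with a pseudocount
  and a delta-method standard error under Var = mu + alpha * mu^2;
* Benjamini–Hochberg FDR.

Every constant is an explicit argument (pseudocount ``c0 = 0.5``, dispersion
floor ``1e-8``), so results are fully specified by this module alone.  The
deliberate simplifications relative to shrinkage-based estimators are
documented in the package's methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DiffExprError",
    "PSEUDOCOUNT",
    "ALPHA_FLOOR",
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "run_de",
    "read_count_matrix",
    "write_de_table",
]

PSEUDOCOUNT = 0.5
ALPHA_FLOOR = 1e-8

CONDITIONS = ("control", "treatment")


class DiffExprError(Exception):
    pass


@dataclass
class CountMatrix:
    """Non-negative integer counts, features x samples, with condition labels."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    condition: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DiffExprError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise DiffExprError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise DiffExprError("counts must be non-negative")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DiffExprError("duplicate feature ids in count matrix")
        missing = [s for s in self.sample_ids if s not in self.condition]
        if missing:
            raise DiffExprError(f"samples without condition label: {missing}")
        bad = {s: c for s, c in self.condition.items()
               if s in self.sample_ids and c not in CONDITIONS}
        if bad:
            raise DiffExprError(
                f"condition labels must be in {CONDITIONS}; offending: {bad}"
            )

    def condition_mask(self, cond: str) -> np.ndarray:
        return np.array([self.condition[s] == cond for s in self.sample_ids])

    def n_samples(self, cond: str) -> int:
        return int(self.condition_mask(cond).sum())


def read_count_matrix(
    counts_path: str | Path, samples_path: str | Path
) -> CountMatrix:
    """Read a counts TSV (first column ``feature_id``) and a sample sheet
    TSV (columns ``sample_id``, ``condition``)."""
    cdf = pd.read_csv(counts_path, sep="\t", index_col=0)
    sdf = pd.read_csv(samples_path, sep="\t", dtype=str)
    for col in ("sample_id", "condition"):
        if col not in sdf.columns:
            raise DiffExprError(f"sample sheet missing column {col!r}")
    cond = dict(zip(sdf["sample_id"], sdf["condition"]))
    unknown = [s for s in cdf.columns if s not in cond]
    if unknown:
        raise DiffExprError(f"count columns absent from sample sheet: {unknown}")
    return CountMatrix(
        feature_ids=[str(i) for i in cdf.index],
        sample_ids=list(cdf.columns),
        counts=cdf.to_numpy(),
        condition=cond,
    )


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    For each feature with strictly positive counts in every sample, form the
    ratio of each sample's count to the feature's geometric mean; the size
    factor of a sample is the median ratio.  Factors are not renormalized.
    """
    counts = cm.counts.astype(float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise DiffExprError(
            "no feature has positive counts in every sample; filter low-count "
            "features or use a pseudocount before normalization"
        )
    logc = np.log(counts[all_positive])
    log_geomean = logc.mean(axis=1)
    log_ratios = logc - log_geomean[:, None]
    return np.exp(np.median(log_ratios, axis=0))


def normalized_counts(cm: CountMatrix, sf: np.ndarray | None = None) -> np.ndarray:
    if sf is None:
        sf = size_factors(cm)
    return cm.counts / np.asarray(sf)[None, :]


def estimate_dispersion(
    cm: CountMatrix,
    sf: np.ndarray,
    alpha_floor: float = ALPHA_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature method-of-moments NB dispersion.

    With condition means removed: ``alpha_i = (v_i - m_i) / m_i**2`` floored
    at ``alpha_floor``, where ``m_i`` is the grand mean of normalized counts
    and ``v_i`` the within-condition pooled variance.  Features with zero
    grand mean get the floor and are flagged untestable.

    Returns ``(alpha, untestable)``.
    """
    norm = normalized_counts(cm, sf)
    m = norm.mean(axis=1)
    dof = 0
    parts = []
    for cond in CONDITIONS:
        mask = cm.condition_mask(cond)
        sub = norm[:, mask]
        mu_c = sub.mean(axis=1, keepdims=True)
        parts.append(((sub - mu_c) ** 2).sum(axis=1))
        dof += mask.sum() - 1
    if dof <= 0:
        raise DiffExprError("dispersion estimation needs > 1 sample per condition")
    v = sum(parts) / dof
    untestable = m == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / m**2
    alpha = np.where(untestable, alpha_floor, alpha)
    return np.maximum(alpha, alpha_floor), untestable


def nb_wald_test(
    cm: CountMatrix,
    sf: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Wald test on the log2 fold-change of condition means.

    For feature i with normalized condition means ``mu_T`` and ``mu_C``::

        log2fc = log2((mu_T + c0) / (mu_C + c0))
        Var(mu_c) = (mu_c + alpha * mu_c^2) / n_c
        se = (1/ln 2) * sqrt(Var(mu_T)/(mu_T + c0)^2 + Var(mu_C)/(mu_C + c0)^2)
        z = log2fc / se,  p = 2 * Phi(-|z|)

    Untestable features (zero counts everywhere) get ``log2fc = 0, p = 1``.
    Returns a DataFrame with columns feature_id, base_mean, log2fc, se,
    wald_z, pvalue, qvalue, untestable.
    """
    for cond in CONDITIONS:
        if cm.n_samples(cond) < 2:
            raise DiffExprError(
                f"condition {cond!r} has {cm.n_samples(cond)} samples; need >= 2"
            )
    if sf is None:
        sf = size_factors(cm)
    if dispersions is None:
        alpha, untestable = estimate_dispersion(cm, sf)
    else:
        alpha = np.asarray(dispersions, dtype=float)
        untestable = normalized_counts(cm, sf).mean(axis=1) == 0

    norm = normalized_counts(cm, sf)
    mu = {}
    var_mu = {}
    for cond in CONDITIONS:
        mask = cm.condition_mask(cond)
        n_c = mask.sum()
        mu[cond] = norm[:, mask].mean(axis=1)
        var_mu[cond] = (mu[cond] + alpha * mu[cond] ** 2) / n_c

    c0 = pseudocount
    log2fc = np.log2((mu["treatment"] + c0) / (mu["control"] + c0))
    se = (1.0 / np.log(2)) * np.sqrt(
        var_mu["treatment"] / (mu["treatment"] + c0) ** 2
        + var_mu["control"] / (mu["control"] + c0) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    z = np.where(untestable, 0.0, z)
    log2fc = np.where(untestable, 0.0, log2fc)
    pvalue = np.where(untestable | (se == 0), 1.0, pvalue)
    pvalue = np.minimum(pvalue, 1.0)

    return pd.DataFrame(
        {
            "feature_id": cm.feature_ids,
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "wald_z": z,
            "pvalue": pvalue,
            "qvalue": bh_adjust(pvalue),
            "untestable": untestable,
        }
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, aligned to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DiffExprError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts_path: str | Path, samples_path: str | Path
) -> pd.DataFrame:
    """Convenience wrapper: read counts + sample sheet, run the full test."""
    cm = read_count_matrix(counts_path, samples_path)
    return nb_wald_test(cm)


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False, float_format="%.10g")
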