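"""Minimal negative-binomial two-group differential expression.

This stage is a deliberately small NB Wald test with median-of-ratios
library-size normalization and Benjamini-Hochberg control.  It implements no
dispersion shrinkage, no fold-change shrinkage and no independent filtering,
so it claims calibration properties only — not numeric equality with a full
DE framework.

Per gene: counts are divided by the sample size factors; group means are
estimated on the normalized scale; a single gene-wise dispersion alpha is
estimated by method of moments from mean-centered normalized counts pooled
across the two groups, alpha = max((s^2 - mu)/mu^2, 1e-8); the log2 fold
change uses a zero guard epsilon = 0.5 * (smallest positive normalized group
mean of the dataset); the Wald standard error comes from the NB variance
mu + alpha*mu^2 of the group means; p-values are two-sided normal and BH
adjusted over all tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_DISPERSION = 1e-8


@dataclass
class DEResult:
    gene_id: str
    lfc: float  # log2(group2 / group1)
    mnc: float  # mean of normalized counts across all samples
    se_lfc: float
    wald_p: float
    padj: float
    significant: bool


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq convention).

    The reference is the per-gene geometric mean over samples, using only
    genes with all-nonzero counts; each sample's factor is the median over
    those genes of count/reference.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "size factors need at least one such gene")
    logs = np.log(mat[nonzero])
    log_ref = logs.mean(axis=1, keepdims=True)
    # lower-median convention for even gene counts
    factors = np.exp(np.quantile(logs - log_ref, 0.5, axis=0,
                                 method="lower"))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_de(counts: pd.DataFrame, group_labels: Sequence[str],
               size_factors: pd.Series = None,
               fdr: float = 0.01, lfc_epsilon: float = None) -> pd.DataFrame:
    """Two-group NB Wald differential expression over all genes.

    ``group_labels`` aligns with the columns of ``counts`` and must contain
    exactly two labels; the log2 fold change is group2 over group1 with
    groups in sorted label order.  Returns a DataFrame with one row per gene
    (columns: gene_id, lfc, mnc, se_lfc, wald_p, padj, significant).
    """
    labels = np.asarray(list(group_labels))
    if labels.shape[0] != counts.shape[1]:
        raise ValueError("one group label per sample column required")
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    m1 = labels == groups[0]
    m2 = labels == groups[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("need >= 2 samples per group")
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts)
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)

    mat = counts.to_numpy(dtype=float)
    if mat[:, m1].sum() == 0 or mat[:, m2].sum() == 0:
        raise ValueError("a group has all-zero counts for every gene")
    norm = mat / sf
    mu1 = norm[:, m1].mean(axis=1)
    mu2 = norm[:, m2].mean(axis=1)
    mnc = norm.mean(axis=1)
    n1, n2 = int(m1.sum()), int(m2.sum())

    # pooled method-of-moments dispersion from mean-centered counts
    resid = np.concatenate(
        [norm[:, m1] - mu1[:, None], norm[:, m2] - mu2[:, None]], axis=1)
    df = n1 + n2 - 2
    s2 = (resid ** 2).sum(axis=1) / df
    mu_bar = (n1 * mu1 + n2 * mu2) / (n1 + n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(mu_bar > 0, (s2 - mu_bar) / mu_bar ** 2, 0.0)
    alpha = np.maximum(alpha, MIN_DISPERSION)

    if lfc_epsilon is not None:
        eps = float(lfc_epsilon)
    else:
        # zero-mean guard: half the smallest positive normalized group
        # mean, capped at 0.5 so well-measured genes are not distorted
        positive = np.concatenate([mu1[mu1 > 0], mu2[mu2 > 0]])
        eps = min(0.5, 0.5 * positive.min()) if positive.size else 0.5
    lfc = np.log2((mu2 + eps) / (mu1 + eps))

    # NB variance of the group-mean estimates, delta-method to log2 scale
    var1 = (mu1 + alpha * mu1 ** 2) / n1
    var2 = (mu2 + alpha * mu2 ** 2) / n2
    ln2 = np.log(2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(var1 / (mu1 + eps) ** 2 + var2 / (mu2 + eps) ** 2) / ln2
    se = np.where(se > 0, se, np.inf)
    z = lfc / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    wald_p = np.clip(wald_p, 0.0, 1.0)
    padj = bh_adjust(wald_p)
    out = pd.DataFrame({
        "gene_id": counts.index,
        "lfc": lfc,
        "mnc": mnc,
        "se_lfc": se,
        "wald_p": wald_p,
        "padj": padj,
        "significant": padj < fdr,
    })
    return out.reset_index(drop=True)
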