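"""scRNA normalization, HVG selection and Wilcoxon differential expression.

Normalization is reads-per-million followed by a natural-log transform
with pseudo-count 1. Differential expression follows the
detection-fraction and log-fold-change prefilters, a two-sided Wilcoxon
rank-sum test (exact for small tie-free groups, normal approximation
with continuity and tie correction otherwise) and Benjamini-Hochberg
correction across tested genes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .dap import bh_adjust

_EXACT_MAX = 10  # exact rank-sum distribution when min(m, n) <= this and tie-free


def normalize_rpm_log(counts: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """Entry -> log(1 + scale * count / cell_total), natural log.

    ``scale`` defaults to reads-per-million; the common per-10k variant
    is available by passing ``scale=1e4``. Cells with zero total are an
    error naming the barcode.
    """
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"cells with zero total count: {list(zero.index[:5])}")
    return np.log1p(counts.div(totals, axis=0) * scale)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p; exact for small tie-free samples."""
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and min(len(x), len(y)) <= _EXACT_MAX:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def wilcoxon_de(
    normalized: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    focal: str,
    min_pct: float = 0.25,
    min_logfc: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE of the focal group versus all other cells.

    Genes pass to testing only if detected (value > 0) in at least
    ``min_pct`` of one of the two groups and the absolute natural-log
    fold change of group means is at least ``min_logfc``; logFC is
    log(mean(expm1(x)) + 1) per group, differenced. BH correction runs
    across tested genes only; significant iff adjusted p < alpha.
    """
    labels = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    labels = labels.reindex(normalized.index)
    if labels.isna().any():
        missing = normalized.index[labels.isna()][:5].tolist()
        raise ValueError(f"barcodes without group label: {missing}")
    in_mask = (labels == focal).to_numpy()
    if in_mask.sum() == 0:
        raise ValueError(f"focal label {focal!r} not present")
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise ValueError("need at least 2 cells per compared group")

    X = normalized.to_numpy(dtype=float)
    Xin, Xout = X[in_mask], X[~in_mask]
    pct_in = (Xin > 0).mean(axis=0)
    pct_out = (Xout > 0).mean(axis=0)
    mean_in = np.expm1(Xin).mean(axis=0)
    mean_out = np.expm1(Xout).mean(axis=0)
    logfc = np.log(mean_in + 1.0) - np.log(mean_out + 1.0)

    tested = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(logfc) >= min_logfc)
    genes = normalized.columns.to_numpy()

    pvals = np.full(len(genes), np.nan)
    for j in np.flatnonzero(tested):
        pvals[j] = _rank_sum_p(Xin[:, j], Xout[:, j])
    padj = np.full(len(genes), np.nan)
    if tested.any():
        padj[tested] = bh_adjust(pvals[tested])

    df = pd.DataFrame(
        {
            "gene": genes,
            "group": focal,
            "logfc": logfc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "tested": tested,
            "pvalue": pvals,
            "p_adj": padj,
        }
    )
    df["significant"] = df["p_adj"] < alpha
    df["significant"] = df["significant"].fillna(False)
    return df


def de_all_groups(
    normalized: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    min_pct: float = 0.25,
    min_logfc: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One focal-vs-rest Wilcoxon screen per group, concatenated."""
    labels = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    out = [
        wilcoxon_de(normalized, labels, focal, min_pct=min_pct, min_logfc=min_logfc, alpha=alpha)
        for focal in sorted(labels.unique())
    ]
    return pd.concat(out, ignore_index=True)


def select_hvg(normalized: pd.DataFrame, n: int = 3000, n_bins: int = 20) -> list[str]:
    """Top-n highly variable genes by mean-binned normalized dispersion.

    Dispersion is variance/mean on the de-logged (expm1) scale,
    z-scored within mean-quantile bins so that genes whose variability
    exceeds what their expression level predicts rank first (the
    standard single-cell HVG criterion). Constant genes are never
    selected while any varying gene remains; if fewer than n genes
    exist, all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    X = np.expm1(normalized.to_numpy(dtype=float))
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    genes = normalized.columns.to_numpy()

    varying = var > 0
    n_bins_eff = max(1, min(n_bins, max(1, int(varying.sum()) // 5)))
    score = np.full(len(genes), -np.inf)
    if varying.any():
        ranks = pd.qcut(
            pd.Series(mean[varying]).rank(method="first"), n_bins_eff, labels=False
        ).to_numpy()
        d = disp[varying]
        z = np.empty_like(d)
        # floor the within-bin SD at a tenth of the global dispersion spread
        # so near-constant bins cannot inflate noise genes' scores
        sd_floor = max(0.1 * float(d.std()), 1e-12)
        for b in range(n_bins_eff):
            sel = ranks == b
            sd_b = max(float(d[sel].std()), sd_floor)
            z[sel] = (d[sel] - d[sel].mean()) / sd_b
        score[varying] = z
    order = np.lexsort((genes, -score))
    keep = order[: min(n, int(varying.sum()) or len(genes))]
    if len(keep) < min(n, len(genes)):  # backfill with constant genes
        rest = [i for i in order if i not in set(keep)]
        keep = np.concatenate([keep, rest[: min(n, len(genes)) - len(keep)]])
    return [genes[i] for i in keep]


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene", "group", "logfc", "pct_in", "pct_out", "pvalue", "p_adj", "significant"]
    de[cols].to_csv(path, sep="\t", index=False)
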