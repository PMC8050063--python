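"""Cross-modality agreement: cluster-profile correlations and pseudobulk similarity.

ATAC gene activity and RNA expression are compared at cluster level:
per-cluster means are z-scored per gene across clusters (population-SD
convention) and all cluster pairs are correlated (Pearson) over a
shared highly-variable gene set. Pseudobulk bin profiles are compared
by rank (Spearman, average ranks for ties) or linear correlation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .matrices import PseudobulkProfile


def cluster_mean_zscores(
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    gene_subset: Sequence[str] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-cluster means, then per-gene z-scores across clusters.

    ``ddof=1`` (sample-SD convention, the default: two clusters with
    means 2 and 4 give z-scores of -/+0.707) or ``ddof=0`` (population
    SD). Constant genes map to all-zero columns. Requires at least two
    clusters (z-scores are undefined on one).
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(matrix.index)
    if labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    means = matrix.groupby(labels, observed=True).mean()
    if means.shape[0] < 2:
        raise ValueError("z-scores need at least two clusters")
    if gene_subset is not None:
        if len(gene_subset) == 0:
            raise ValueError("gene_subset must be non-empty")
        means = means[[g for g in gene_subset if g in means.columns]]
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=ddof)
    z = (means - mu).div(sd.replace(0, np.nan), axis=1).fillna(0.0)
    return z


def concordance_matrix(
    rna_profiles: pd.DataFrame,
    atac_profiles: pd.DataFrame,
    hvg: Sequence[str],
) -> pd.DataFrame:
    """Pairwise Pearson correlations of z-scored cluster profiles.

    Rows are RNA clusters, columns ATAC clusters; the correlations run
    over the intersection of ``hvg`` with genes present in both profile
    matrices (at least 3 shared genes required).
    """
    shared = [g for g in hvg if g in rna_profiles.columns and g in atac_profiles.columns]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need at least 3")
    R = rna_profiles[shared].to_numpy(dtype=float)
    A = atac_profiles[shared].to_numpy(dtype=float)

    def _center_norm(M: np.ndarray) -> np.ndarray:
        M = M - M.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(M, axis=1, keepdims=True)
        norms[norms == 0] = np.nan
        return M / norms

    C = _center_norm(R) @ _center_norm(A).T
    return pd.DataFrame(
        np.nan_to_num(C), index=rna_profiles.index, columns=atac_profiles.index
    )


def pseudobulk_correlation(
    profile_a: PseudobulkProfile,
    profile_b: PseudobulkProfile,
    method: str = "spearman",
) -> float:
    """Rank (default) or linear correlation of aligned bin-count vectors."""
    if not profile_a.aligned_with(profile_b):
        raise ValueError("pseudobulk profiles have mismatched bin universes")
    if method == "spearman":
        return float(spearmanr(profile_a.counts, profile_b.counts).statistic)
    if method == "pearson":
        return float(pearsonr(profile_a.counts, profile_b.counts).statistic)
    raise ValueError(f"unknown method {method!r}")


def argmax_match_rate(concordance: pd.DataFrame) -> float:
    """Fraction of RNA clusters whose best-correlated ATAC cluster is
    the identically named one (diagnostic of cross-modality agreement)."""
    hits = 0
    for rna_cluster, row in concordance.iterrows():
        if row.idxmax() == rna_cluster:
            hits += 1
    return hits / len(concordance)


def write_concordance(concordance: pd.DataFrame, path: str | Path) -> None:
    concordance.to_csv(path, sep="\t")
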