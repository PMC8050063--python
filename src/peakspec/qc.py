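"""Per-cell quality control covariates and cell filters.

ATAC cells are kept when their unique-fragment count lies in
[1000, 40000] (inclusive), the mitochondrial fragment ratio is strictly
below 10% and the promoter fragment ratio is at least 20%. RNA cells
are kept with 200-3000 detected genes (inclusive) and a mitochondrial
count percentage of at most 50. Boundary conventions follow a literal
reading of the quoted thresholds and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, GenomeLayout, interval_arrays, merge_intervals
from .genes import GeneModel


@dataclass(frozen=True)
class QcThresholds:
    """QC bounds; defaults are the study's quoted values."""

    atac_min_fragments: int = 1000
    atac_max_fragments: int = 40000
    atac_max_mito_ratio: float = 0.10
    atac_min_promoter_ratio: float = 0.20
    rna_min_genes: int = 200
    rna_max_genes: int = 3000
    rna_max_mito_percent: float = 50.0

    def __post_init__(self) -> None:
        if self.atac_min_fragments >= self.atac_max_fragments:
            raise ValueError("atac fragment bounds inverted")
        if self.rna_min_genes >= self.rna_max_genes:
            raise ValueError("rna gene bounds inverted")


def qc_promoter_windows(
    genes: Sequence[GeneModel], upstream: int = 2000, downstream: int = 2000
) -> list[GenomicInterval]:
    """TSS +/- 2 kb windows (merged) used for the promoter-ratio covariate.

    Distinct from the 5 kb upstream-only promoter definition used for
    genomic element stratification.
    """
    wins = []
    for g in genes:
        w = g.promoter(upstream=upstream, downstream=downstream)
        if w is not None:
            wins.append(w)
    return merge_intervals(wins)


def dedupe_fragments(fragments: pd.DataFrame) -> pd.DataFrame:
    """Unique fragments: identical (chrom, start, end, barcode) count once."""
    return fragments.drop_duplicates(subset=["chrom", "start", "end", "barcode"])


def compute_atac_qc(
    fragments: pd.DataFrame,
    promoters: Sequence[GenomicInterval],
    layout: GenomeLayout,
) -> pd.DataFrame:
    """Per-barcode QC covariates from fragment records.

    Returns a frame with barcode, n_fragments (unique), mito_ratio
    (fraction on the mito chromosome) and promoter_ratio (fraction
    overlapping any promoter window); all ratios use the unique-fragment
    count of the barcode as denominator. Barcodes with zero fragments do
    not appear.
    """
    frags = dedupe_fragments(fragments)
    barcodes, bc_codes = np.unique(frags["barcode"].to_numpy(), return_inverse=True)
    n = np.bincount(bc_codes, minlength=len(barcodes))

    mito = (frags["chrom"].to_numpy() == layout.mito)
    n_mito = np.bincount(bc_codes, weights=mito.astype(float), minlength=len(barcodes))

    in_prom = np.zeros(len(frags), dtype=bool)
    prom = interval_arrays(merge_intervals(promoters))
    chrom_arr = frags["chrom"].to_numpy()
    start_arr = frags["start"].to_numpy()
    end_arr = frags["end"].to_numpy()
    for chrom, (ps, pe, _) in prom.items():
        sel = np.flatnonzero(chrom_arr == chrom)
        if len(sel) == 0:
            continue
        # disjoint sorted windows: candidate = first window with end > start
        j = np.searchsorted(pe, start_arr[sel], side="right")
        ok = j < len(ps)
        jj = np.clip(j, 0, len(ps) - 1)
        in_prom[sel] = ok & (ps[jj] < end_arr[sel])
    n_prom = np.bincount(bc_codes, weights=in_prom.astype(float), minlength=len(barcodes))

    return pd.DataFrame(
        {
            "barcode": barcodes,
            "n_fragments": n.astype(int),
            "promoter_ratio": n_prom / n,
            "mito_ratio": n_mito / n,
        }
    )


def filter_atac_cells(qc: pd.DataFrame, thresholds: QcThresholds | None = None) -> list[str]:
    """Barcodes passing all three ATAC criteria.

    Fragment bounds inclusive; mito exclusion strict (keep iff ratio
    < max); promoter kept iff ratio >= min.
    """
    t = thresholds or QcThresholds()
    keep = (
        (qc["n_fragments"] >= t.atac_min_fragments)
        & (qc["n_fragments"] <= t.atac_max_fragments)
        & (qc["mito_ratio"] < t.atac_max_mito_ratio)
        & (qc["promoter_ratio"] >= t.atac_min_promoter_ratio)
    )
    return qc.loc[keep, "barcode"].tolist()


def compute_rna_qc(
    counts: np.ndarray,
    barcodes: Sequence[str],
    gene_ids: Sequence[str],
    mito_prefixes: tuple[str, ...] = ("mt-", "MT-"),
) -> pd.DataFrame:
    """Detected-gene counts and mitochondrial count percentage per cell."""
    counts = np.asarray(counts)
    mito_mask = np.array([g.startswith(mito_prefixes) for g in gene_ids])
    n_genes = (counts > 0).sum(axis=1)
    total = counts.sum(axis=1)
    mito_sum = counts[:, mito_mask].sum(axis=1) if mito_mask.any() else np.zeros(len(barcodes))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(total > 0, 100.0 * mito_sum / total, 0.0)
    return pd.DataFrame(
        {"barcode": list(barcodes), "n_genes_detected": n_genes.astype(int), "mito_percent": mito_pct}
    )


def filter_rna_cells(qc: pd.DataFrame, thresholds: QcThresholds | None = None) -> list[str]:
    """Barcodes passing the RNA criteria.

    Cells with fewer than min or more than max detected genes, or mito
    percentage strictly above the bound, are excluded — so exactly min,
    max and the mito bound itself are kept.
    """
    t = thresholds or QcThresholds()
    keep = (
        (qc["n_genes_detected"] >= t.rna_min_genes)
        & (qc["n_genes_detected"] <= t.rna_max_genes)
        & (qc["mito_percent"] <= t.rna_max_mito_percent)
    )
    return qc.loc[keep, "barcode"].tolist()


def write_qc_table(qc: pd.DataFrame, path: str | Path, thresholds: QcThresholds | None = None) -> None:
    """QC table with per-criterion pass flags."""
    t = thresholds or QcThresholds()
    out = qc.copy()
    if "n_fragments" in out.columns:
        out["pass_fragments"] = (out["n_fragments"] >= t.atac_min_fragments) & (
            out["n_fragments"] <= t.atac_max_fragments
        )
        out["pass_mito"] = out["mito_ratio"] < t.atac_max_mito_ratio
        out["pass_promoter"] = out["promoter_ratio"] >= t.atac_min_promoter_ratio
        out["pass_all"] = out["pass_fragments"] & out["pass_mito"] & out["pass_promoter"]
    else:
        out["pass_genes"] = (out["n_genes_detected"] >= t.rna_min_genes) & (
            out["n_genes_detected"] <= t.rna_max_genes
        )
        out["pass_mito"] = out["mito_percent"] <= t.rna_max_mito_percent
        out["pass_all"] = out["pass_genes"] & out["pass_mito"]
    out.to_csv(path, sep="\t", index=False)
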