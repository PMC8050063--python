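"""Genomic element stratification, nearest genes, and SNP-to-peak mapping.

Every peak receives exactly one element class under the priority order
exon > 5'-UTR > 3'-UTR > intron > promoter > distal. Promoters are the
strand-aware 5 kb upstream of the TSS (no downstream extension);
introns are transcript span minus the exon union. Disease-associated
SNPs (supplied post-liftover as single-base BED records) are overlapped
with peaks, attributed to cell types through DAP specificity, and
annotated with their nearest gene by TSS distance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, interval_arrays, merge_intervals
from .genes import GeneModel
from .dap import DapCallResult

ELEMENT_PRIORITY = ("exon", "utr5", "utr3", "intron", "promoter", "distal")


def _element_sets(
    genes: Sequence[GeneModel], promoter_upstream: int
) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]]:
    """Merged per-class interval arrays keyed by class then chromosome."""
    pools: dict[str, list[GenomicInterval]] = {k: [] for k in ELEMENT_PRIORITY[:-1]}
    for g in genes:
        pools["exon"].extend(g.exons)
        pools["utr5"].extend(g.utr5)
        pools["utr3"].extend(g.utr3)
        pools["intron"].extend(g.introns())
        prom = g.promoter(upstream=promoter_upstream)
        if prom is not None:
            pools["promoter"].append(prom)
    return {k: interval_arrays(merge_intervals(v)) for k, v in pools.items()}


def _hits_any(arrs, chrom: str, start: int, end: int) -> bool:
    a = arrs.get(chrom)
    if a is None:
        return False
    s, e, _ = a
    j = np.searchsorted(e, start, side="right")
    return bool(j < len(s) and s[j] < end)


def classify_peak_element(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_upstream: int = 5000,
) -> str:
    """Highest-priority element class the peak overlaps; distal if none."""
    sets = _element_sets(genes, promoter_upstream)
    for cls in ELEMENT_PRIORITY[:-1]:
        if _hits_any(sets[cls], peak.chrom, peak.start, peak.end):
            return cls
    return "distal"


def classify_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_upstream: int = 5000,
) -> list[str]:
    """Vector version of :func:`classify_peak_element` (one pass over genes)."""
    sets = _element_sets(genes, promoter_upstream)
    out = []
    for pk in peaks:
        cls_found = "distal"
        for cls in ELEMENT_PRIORITY[:-1]:
            if _hits_any(sets[cls], pk.chrom, pk.start, pk.end):
                cls_found = cls
                break
        out.append(cls_found)
    return out


def nearest_gene(
    chrom: str, position: int, genes: Sequence[GeneModel]
) -> tuple[str | None, int | None]:
    """Gene with the minimal |position - TSS| on the same chromosome.

    The signed distance is negative when the position lies upstream of
    the TSS in the gene's orientation (and positive downstream); ties
    are broken by smaller TSS coordinate, then lexicographic gene id.
    Returns (None, None) when the chromosome carries no gene.
    """
    best_key = None
    best: tuple[str, int] | None = None
    for g in genes:
        if g.chrom != chrom:
            continue
        raw = position - g.tss
        signed = raw if g.strand == "+" else -raw
        key = (abs(raw), g.tss, g.gene_id)
        if best_key is None or key < best_key:
            best_key = key
            best = (g.gene_id, signed)
    if best is None:
        return None, None
    return best


def overlap_snps_with_peaks(
    snps: pd.DataFrame | Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    daps: DapCallResult | None,
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Overlap SNPs with peaks; attribute cell types; annotate nearest genes.

    SNPs arrive as single-base BED intervals (or a frame with chrom /
    start / end / name). Overlap is the half-open point-in-interval
    test; the cell-type column is non-empty only when an overlapping
    peak is a DAP. Peaks must be disjoint (merged).
    """
    if isinstance(snps, pd.DataFrame):
        snp_rows = [
            (str(r.name) if "name" not in snps.columns else r["name"], r["chrom"], int(r["start"]))
            for _, r in snps.iterrows()
        ]
    else:
        snp_rows = [(iv.name or f"snp{i}", iv.chrom, iv.start) for i, iv in enumerate(snps)]

    peak_map: dict[int, str] = daps.peak_type_map() if daps is not None else {}
    arrs = interval_arrays(peaks)

    rows = []
    for snp_id, chrom, pos in snp_rows:
        hit_idx: list[int] = []
        a = arrs.get(chrom)
        if a is not None:
            s, e, idx = a
            j = np.searchsorted(e, pos, side="right")
            if j < len(s) and s[j] <= pos < e[j]:
                hit_idx.append(int(idx[j]))
        cts = sorted({peak_map[i] for i in hit_idx if i in peak_map})
        gid, dist = nearest_gene(chrom, pos, genes)
        rows.append(
            {
                "snp_id": snp_id,
                "chrom": chrom,
                "pos": pos,
                "n_overlapping_peaks": len(hit_idx),
                "peak_indices": ",".join(map(str, hit_idx)),
                "cell_types": ",".join(cts),
                "nearest_gene": gid,
                "tss_distance": dist,
            }
        )
    return pd.DataFrame(rows)


def element_class_counts(classes: Sequence[str]) -> pd.Series:
    """Counts per element class, in priority order (sums to the peak count)."""
    s = pd.Series(classes).value_counts()
    return s.reindex(ELEMENT_PRIORITY, fill_value=0)


def write_snp_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
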