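"""Proximity-based cis-regulatory element prediction.

Links a cell-type-specific peak (DAP) to a cell-type-specific gene
(DEG) when (1) both are specific to the same cell type, (2) the peak
lies within +/-100 kb of the gene's TSS (evaluated at the peak's nearer
edge), and (3) the peak does not directly overlap the TSS (single TSS
base against the half-open peak interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .intervals import GenomicInterval
from .genes import GeneModel
from .dap import DapCallResult


@dataclass(frozen=True)
class CreLink:
    """One predicted gene-enhancer couple.

    ``distance`` is measured from the peak edge nearer the TSS, signed
    by the gene's orientation (positive downstream of the TSS).
    """

    gene_id: str
    peak: GenomicInterval
    peak_index: int
    cell_type: str
    distance: int


def _edge_distance(peak: GenomicInterval, tss: int, strand: str) -> int | None:
    """Signed nearer-edge distance; None when the peak contains the TSS."""
    if peak.start <= tss < peak.end:
        return None
    if tss < peak.start:
        raw = peak.start - tss           # peak downstream of TSS (genomic)
    else:
        raw = (peak.end - 1) - tss       # negative: peak upstream (genomic)
    return raw if strand == "+" else -raw


def link_daps_to_degs(
    daps: DapCallResult,
    degs: pd.DataFrame,
    genes: Sequence[GeneModel],
    window: int = 100_000,
) -> list[CreLink]:
    """Emit every (gene, peak, cell type) satisfying the three predicates.

    ``degs`` is a DE table with gene / group / significant columns; only
    significant rows participate. A gene significant in several types
    may form links per type independently. DEG genes absent from the
    gene models raise an error listing them.
    """
    gene_map = {g.gene_id: g for g in genes}
    sig = degs[degs["significant"]] if "significant" in degs.columns else degs
    missing = sorted(set(sig["gene"]) - set(gene_map))
    if missing:
        raise ValueError(f"DEG genes missing from gene models: {missing[:10]}")

    peak_types = daps.peak_type_map()
    peaks_by_type: dict[str, list[int]] = {}
    for i, ct in peak_types.items():
        peaks_by_type.setdefault(ct, []).append(i)

    links: list[CreLink] = []
    for _, row in sig.iterrows():
        g = gene_map[row["gene"]]
        ct = row["group"]
        for pi in peaks_by_type.get(ct, []):
            pk = daps.peaks[pi]
            if pk.chrom != g.chrom:
                continue
            d = _edge_distance(pk, g.tss, g.strand)
            if d is None or abs(d) > window:
                continue
            links.append(CreLink(g.gene_id, pk, pi, ct, d))
    links.sort(key=lambda l: (l.cell_type, l.gene_id, l.peak.chrom, l.peak.start))
    return links


def links_to_frame(links: Sequence[CreLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": l.gene_id,
                "chrom": l.peak.chrom,
                "peak_start": l.peak.start,
                "peak_end": l.peak.end,
                "peak_index": l.peak_index,
                "cell_type": l.cell_type,
                "distance": l.distance,
            }
            for l in links
        ]
    )


def write_links(links: Sequence[CreLink], path: str | Path) -> None:
    links_to_frame(links).to_csv(path, sep="\t", index=False)
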