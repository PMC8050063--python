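"""Gene models: strand, TSS, transcript span, exon/UTR structure.

The primary on-disk dialect is a flat tab-separated table (one row per
gene, comma-separated exon/UTR block lists, 0-based half-open). A
minimal GTF reader converts 1-based inclusive records at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import GenomicInterval, merge_intervals


@dataclass(frozen=True)
class GeneModel:
    """One gene with a single transcript model.

    ``tss`` is the strand-aware transcription start: span start on the
    plus strand, ``span.end - 1`` on the minus strand. Introns are
    derived (transcript span minus exon union); single-exon genes have
    none.
    """

    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        for blocks, label in ((self.exons, "exon"), (self.utr5, "utr5"), (self.utr3, "utr3")):
            for b in blocks:
                if b.chrom != self.chrom or b.start < self.span.start or b.end > self.span.end:
                    raise ValueError(
                        f"gene {self.gene_id}: {label} block outside transcript span"
                    )

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    def introns(self) -> list[GenomicInterval]:
        """Transcript span minus the exon union."""
        exon_union = merge_intervals(self.exons)
        out: list[GenomicInterval] = []
        cursor = self.span.start
        for ex in exon_union:
            if ex.start > cursor:
                out.append(GenomicInterval(self.chrom, cursor, ex.start))
            cursor = max(cursor, ex.end)
        if cursor < self.span.end:
            out.append(GenomicInterval(self.chrom, cursor, self.span.end))
        return out

    def promoter(self, upstream: int = 5000, downstream: int = 0) -> GenomicInterval | None:
        """Strand-aware window upstream of the TSS (plus optional downstream).

        Truncated at position 0; ``None`` if the window is empty.
        """
        if self.strand == "+":
            start, end = self.tss - upstream, self.tss + downstream
        else:
            start, end = self.tss + 1 - downstream, self.tss + 1 + upstream
        start = max(0, start)
        if start >= end:
            return None
        return GenomicInterval(self.chrom, start, end, name=self.gene_id)

    def scoring_window(self, mode: str = "transcript_overlap", upstream: int = 2000) -> GenomicInterval:
        """Window used for gene activity scoring.

        ``transcript_overlap``: the transcript span itself.
        ``body_plus_upstream``: span extended ``upstream`` bases past the
        strand-aware TSS.
        """
        if mode == "transcript_overlap":
            return GenomicInterval(self.chrom, self.span.start, self.span.end, self.gene_id)
        if mode == "body_plus_upstream":
            if upstream < 0:
                raise ValueError("upstream must be >= 0")
            if self.strand == "+":
                return GenomicInterval(
                    self.chrom, max(0, self.span.start - upstream), self.span.end, self.gene_id
                )
            return GenomicInterval(
                self.chrom, self.span.start, self.span.end + upstream, self.gene_id
            )
        raise ValueError(f"unknown gene activity mode {mode!r}")


def _blocks_to_str(blocks: Sequence[GenomicInterval]) -> str:
    return ",".join(f"{b.start}-{b.end}" for b in blocks) or "."


def _str_to_blocks(chrom: str, s: str) -> tuple[GenomicInterval, ...]:
    if s in (".", ""):
        return ()
    out = []
    for part in s.split(","):
        a, b = part.split("-")
        out.append(GenomicInterval(chrom, int(a), int(b)))
    return tuple(out)


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write the tabular gene-model dialect (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tstart\tend\texons\tutr5\tutr3\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.span.start}\t{g.span.end}\t"
                f"{_blocks_to_str(g.exons)}\t{_blocks_to_str(g.utr5)}\t{_blocks_to_str(g.utr3)}\n"
            )


def read_gene_table(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for line in fh:
            p = line.rstrip("\n").split("\t")
            chrom = p[cols["chrom"]]
            genes.append(
                GeneModel(
                    gene_id=p[cols["gene_id"]],
                    chrom=chrom,
                    strand=p[cols["strand"]],
                    span=GenomicInterval(chrom, int(p[cols["start"]]), int(p[cols["end"]])),
                    exons=_str_to_blocks(chrom, p[cols["exons"]]),
                    utr5=_str_to_blocks(chrom, p[cols["utr5"]]),
                    utr3=_str_to_blocks(chrom, p[cols["utr3"]]),
                )
            )
    return genes


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read a minimal GTF (1-based inclusive, converted here to 0-based half-open).

    Recognised features: transcript (or gene), exon, five_prime_utr,
    three_prime_utr. One model per gene_id; multiple transcripts per gene
    are collapsed into the union span with pooled exon/UTR blocks.
    """
    spans: dict[str, list] = {}
    blocks: dict[str, dict[str, list[GenomicInterval]]] = {}

    def attr(field_str: str, key: str) -> str | None:
        for part in field_str.split(";"):
            part = part.strip()
            if part.startswith(key + " "):
                return part.split(" ", 1)[1].strip('"')
        return None

    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, feature, start1, end1, strand, attrs = f[0], f[2], f[3], f[4], f[6], f[8]
            gid = attr(attrs, "gene_id")
            if gid is None:
                continue
            start, end = int(start1) - 1, int(end1)  # GTF -> half-open
            if feature in ("transcript", "gene"):
                cur = spans.get(gid)
                if cur is None:
                    spans[gid] = [chrom, strand, start, end]
                else:
                    cur[2] = min(cur[2], start)
                    cur[3] = max(cur[3], end)
            elif feature in ("exon", "five_prime_utr", "three_prime_utr"):
                key = {"exon": "exons", "five_prime_utr": "utr5", "three_prime_utr": "utr3"}[feature]
                blocks.setdefault(gid, {"exons": [], "utr5": [], "utr3": []})[key].append(
                    GenomicInterval(chrom, start, end)
                )
    genes = []
    for gid, (chrom, strand, start, end) in spans.items():
        b = blocks.get(gid, {"exons": [], "utr5": [], "utr3": []})
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                span=GenomicInterval(chrom, start, end),
                exons=tuple(merge_intervals(b["exons"])),
                utr5=tuple(merge_intervals(b["utr5"])),
                utr3=tuple(merge_intervals(b["utr3"])),
            )
        )
    return genes
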