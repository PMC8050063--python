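"""Coordinate-convention-safe genomic interval primitives.

All coordinates in this package are 0-based, half-open ``[start, end)``
(the BED convention). 1-based inclusive inputs (GTF-style gene models)
are converted at the reader boundary, never internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    Invariants: ``0 <= start < end`` and a non-empty chromosome name.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, chrom: str, pos: int) -> bool:
        """Half-open point-in-interval test."""
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths plus special chromosome roles.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length)`` pairs. Names must be unique, lengths > 0.
    mito:
        Name of the mitochondrial chromosome (may be absent from
        ``chromosomes`` if the assembly omits it).
    sex:
        Names of sex chromosomes, excluded from pseudobulk profiles.
    """

    chromosomes: tuple[tuple[str, int], ...]
    mito: str = "chrM"
    sex: tuple[str, ...] = ("chrX", "chrY")

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for c, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def autosomes(self) -> list[str]:
        skip = set(self.sex) | {self.mito}
        return [c for c in self.names if c not in skip]


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge to the minimal disjoint set covering the same bases.

    Book-ended intervals (gap 0) are merged, mirroring the default
    behaviour of interval-reduction routines used to build merged peak
    universes. Output is sorted by (chrom, start). Empty input yields [].
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def bin_genome(layout: GenomeLayout, bin_size: int) -> list[GenomicInterval]:
    """Tile every chromosome with contiguous ``bin_size`` windows.

    The final tile of each chromosome is truncated at the chromosome
    length; tile order follows the layout order.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    tiles: list[GenomicInterval] = []
    for chrom, length in layout.chromosomes:
        for start in range(0, length, bin_size):
            tiles.append(GenomicInterval(chrom, start, min(start + bin_size, length)))
    return tiles


@dataclass(frozen=True)
class NearestHit:
    """Result of a nearest-anchor query; ``feature is None`` flags no hit."""

    feature: GenomicInterval | None
    distance: int | None

    @property
    def found(self) -> bool:
        return self.feature is not None


def nearest_feature(
    query: GenomicInterval | tuple[str, int],
    features: Sequence[GenomicInterval],
    anchors: Sequence[int] | None = None,
) -> NearestHit:
    """Feature whose anchor point is closest to the query.

    ``anchors`` gives one anchor position per feature (default: feature
    start, the TSS convention for stranded gene models prepared by the
    caller). Distance is ``query_point - anchor`` for point queries, and 0
    when an interval query contains the anchor; otherwise the signed
    distance from the nearer interval edge. Ties are broken by smaller
    feature start, then lexicographic name.
    """
    if isinstance(query, GenomicInterval):
        chrom, qstart, qend = query.chrom, query.start, query.end
    else:
        chrom, pos = query
        qstart, qend = pos, pos + 1

    if anchors is None:
        anchors = [f.start for f in features]
    if len(anchors) != len(features):
        raise ValueError("anchors must align with features")

    best: tuple[int, int, str] | None = None  # (|d|, start, name) for tie-break
    best_hit: NearestHit | None = None
    for feat, anchor in zip(features, anchors):
        if feat.chrom != chrom:
            continue
        if qstart <= anchor < qend:
            d = 0
        elif anchor < qstart:
            d = qstart - anchor
        else:
            d = (qend - 1) - anchor
        key = (abs(d), feat.start, feat.name or "")
        if best is None or key < best:
            best = key
            best_hit = NearestHit(feat, d)
    if best_hit is None:
        return NearestHit(None, None)
    return best_hit


# --- BED I/O ------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 (tab-separated, no header)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else None
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED3 (or BED4 where a name is present)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# --- vectorized helpers shared by matrix/annotation code ----------------

def interval_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends, original indices), sorted by start."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    out = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        s = np.array([r[0] for r in rows], dtype=np.int64)
        e = np.array([r[1] for r in rows], dtype=np.int64)
        idx = np.array([r[2] for r in rows], dtype=np.int64)
        out[chrom] = (s, e, idx)
    return out


def assert_disjoint_sorted(intervals: Sequence[GenomicInterval]) -> None:
    """Raise if intervals overlap within a chromosome (merge first)."""
    for chrom, (s, e, _) in interval_arrays(intervals).items():
        if len(s) > 1 and np.any(s[1:] < e[:-1]):
            raise ValueError(
                f"intervals on {chrom} overlap; apply merge_intervals first"
            )
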