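"""Binarized accessibility matrices, gene activity scores, pseudobulk bins.

Fragment-to-feature assignment is by any-overlap of the full fragment
interval under half-open semantics (not midpoint or cut site). Matrices
are stored sparsely; the on-disk format is MatrixMarket with sidecar
barcode and feature-BED files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .intervals import (
    GenomicInterval,
    GenomeLayout,
    assert_disjoint_sorted,
    bin_genome,
    interval_arrays,
    read_bed,
    write_bed,
)
from .genes import GeneModel


@dataclass
class AccessibilityMatrix:
    """Cells x genomic features; entries binary (0/1) or counts.

    Rows are cell barcodes, columns are :class:`GenomicInterval`
    features sorted by (chrom, start). ``X`` is a scipy sparse matrix.
    """

    barcodes: list[str]
    features: list[GenomicInterval]
    X: sparse.spmatrix

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.barcodes), len(self.features)):
            raise ValueError("matrix shape does not match labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def is_binary(self) -> bool:
        return bool((self.X.data == 1).all()) if self.X.nnz else True

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel()

    def binarize(self) -> "AccessibilityMatrix":
        B = self.X.copy().tocsr()
        B.data = np.ones_like(B.data)
        return AccessibilityMatrix(self.barcodes, self.features, B)


def _fragment_arrays(fragments: pd.DataFrame):
    return (
        fragments["chrom"].to_numpy(),
        fragments["start"].to_numpy(np.int64),
        fragments["end"].to_numpy(np.int64),
        fragments["barcode"].to_numpy(),
    )


def _overlap_pairs_disjoint(
    fragments: pd.DataFrame, features: Sequence[GenomicInterval]
) -> tuple[np.ndarray, np.ndarray]:
    """(fragment row, feature index) overlap pairs; features disjoint.

    A fragment can hit several consecutive features (e.g. a fragment
    spanning a bin boundary); all hits are returned.
    """
    chrom_a, start_a, end_a, _ = _fragment_arrays(fragments)
    feat = interval_arrays(features)
    rows_out = []
    feats_out = []
    for chrom, (fs, fe, fidx) in feat.items():
        sel = np.flatnonzero(chrom_a == chrom)
        if len(sel) == 0:
            continue
        st, en = start_a[sel], end_a[sel]
        # first candidate: first feature whose end exceeds fragment start
        j = np.searchsorted(fe, st, side="right")
        while True:
            ok = (j < len(fs))
            jj = np.clip(j, 0, len(fs) - 1)
            hit = ok & (fs[jj] < en)
            if not hit.any():
                break
            rows_out.append(sel[hit])
            feats_out.append(fidx[jj[hit]])
            j = np.where(hit, j + 1, len(fs))  # advance only live fragments
    if rows_out:
        return np.concatenate(rows_out), np.concatenate(feats_out)
    return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)


def _build_matrix(
    rows: np.ndarray,
    feats: np.ndarray,
    barcodes: np.ndarray,
    bc_codes: np.ndarray,
    features: Sequence[GenomicInterval],
    binary: bool,
) -> AccessibilityMatrix:
    data = np.ones(len(rows), dtype=np.int64)
    M = sparse.coo_matrix(
        (data, (bc_codes[rows], feats)), shape=(len(barcodes), len(features))
    ).tocsr()
    M.sum_duplicates()
    if binary:
        M.data = np.ones_like(M.data)
    return AccessibilityMatrix(list(barcodes), list(features), M)


def build_cell_bin_matrix(
    fragments: pd.DataFrame,
    layout: GenomeLayout,
    bin_size: int = 5000,
) -> AccessibilityMatrix:
    """Binarized cell-by-bin matrix over genome-wide tiles.

    Fragments on chromosomes absent from the layout, or on the
    mitochondrial chromosome, are dropped; a (cell, bin) entry is 1 iff
    at least one fragment of the cell overlaps the bin.
    """
    known = set(layout.names) - {layout.mito}
    keep = fragments["chrom"].isin(known)
    frags = fragments.loc[keep].reset_index(drop=True)
    bins = [b for b in bin_genome(layout, bin_size) if b.chrom != layout.mito]
    barcodes, bc_codes = np.unique(frags["barcode"].to_numpy(), return_inverse=True)
    rows, feats = _overlap_pairs_disjoint(frags, bins)
    return _build_matrix(rows, feats, barcodes, bc_codes, bins, binary=True)


def filter_bins(
    matrix: AccessibilityMatrix,
    top_fraction: float = 0.05,
    blacklist: Sequence[GenomicInterval] = (),
) -> AccessibilityMatrix:
    """Drop the most accessible bins and blacklist-overlapping bins.

    Exactly ``floor(top_fraction * n_bins)`` bins with the largest
    column sums are removed (ties at the cutoff broken by genomic
    order), plus every bin overlapping a blacklist interval. Rows are
    never removed.
    """
    if not (0 <= top_fraction < 1):
        raise ValueError("top_fraction must be in [0, 1)")
    n_bins = len(matrix.features)
    k = int(np.floor(top_fraction * n_bins))
    colsum = matrix.column_sums()
    # rank by (-colsum, genomic index); features already in genomic order
    order = np.lexsort((np.arange(n_bins), -colsum))
    drop = set(order[:k].tolist())

    if blacklist:
        bl = interval_arrays(blacklist)
        for i, b in enumerate(matrix.features):
            arr = bl.get(b.chrom)
            if arr is None:
                continue
            bs, be, _ = arr
            j = np.searchsorted(be, b.start, side="right")
            if j < len(bs) and bs[j] < b.end:
                drop.add(i)

    keep = np.array([i for i in range(n_bins) if i not in drop], dtype=np.int64)
    return AccessibilityMatrix(
        matrix.barcodes,
        [matrix.features[i] for i in keep],
        matrix.X.tocsc()[:, keep].tocsr(),
    )


def build_cell_peak_matrix(
    fragments: pd.DataFrame, peaks: Sequence[GenomicInterval]
) -> AccessibilityMatrix:
    """Binarized cell-by-peak matrix; peaks must be disjoint (merge first)."""
    assert_disjoint_sorted(peaks)
    peaks_sorted = sorted(peaks, key=lambda p: (p.chrom, p.start))
    barcodes, bc_codes = np.unique(fragments["barcode"].to_numpy(), return_inverse=True)
    rows, feats = _overlap_pairs_disjoint(fragments, peaks_sorted)
    return _build_matrix(rows, feats, barcodes, bc_codes, peaks_sorted, binary=True)


@dataclass
class GeneActivityMatrix:
    """Cells x genes; non-negative integer fragment counts."""

    barcodes: list[str]
    gene_ids: list[str]
    X: sparse.spmatrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X.toarray(), index=self.barcodes, columns=self.gene_ids
        )


def build_gene_activity_matrix(
    fragments: pd.DataFrame,
    genes: Sequence[GeneModel],
    mode: str = "transcript_overlap",
    upstream: int = 2000,
) -> GeneActivityMatrix:
    """Per-cell fragment counts over each gene's scoring window.

    ``transcript_overlap`` counts fragments overlapping the transcript
    span; ``body_plus_upstream`` extends the window ``upstream`` bases
    past the strand-aware TSS. A fragment may count toward several
    genes whose windows it overlaps.
    """
    windows = [g.scoring_window(mode=mode, upstream=upstream) for g in genes]
    chrom_a, start_a, end_a, bc_a = _fragment_arrays(fragments)
    barcodes, bc_codes = np.unique(bc_a, return_inverse=True)

    max_len = int((end_a - start_a).max()) if len(fragments) else 1
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for gi, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end, gi))

    rows_acc: list[np.ndarray] = []
    cols_acc: list[np.ndarray] = []
    vals_acc: list[np.ndarray] = []
    for chrom, wins in by_chrom.items():
        sel = np.flatnonzero(chrom_a == chrom)
        if len(sel) == 0:
            continue
        st = start_a[sel]
        order = np.argsort(st, kind="stable")
        sel = sel[order]
        st = st[order]
        en = end_a[sel]
        for wstart, wend, gi in wins:
            lo = np.searchsorted(st, wstart - max_len, side="left")
            hi = np.searchsorted(st, wend, side="left")
            if hi <= lo:
                continue
            cand = slice(lo, hi)
            hit = en[cand] > wstart
            if not hit.any():
                continue
            codes = bc_codes[sel[cand][hit]]
            counts = np.bincount(codes, minlength=len(barcodes))
            nz = np.flatnonzero(counts)
            rows_acc.append(nz)
            cols_acc.append(np.full(len(nz), gi, dtype=np.int64))
            vals_acc.append(counts[nz])
    if rows_acc:
        M = sparse.coo_matrix(
            (np.concatenate(vals_acc), (np.concatenate(rows_acc), np.concatenate(cols_acc))),
            shape=(len(barcodes), len(genes)),
            dtype=np.int64,
        ).tocsr()
    else:
        M = sparse.csr_matrix((len(barcodes), len(genes)), dtype=np.int64)
    return GeneActivityMatrix(list(barcodes), [g.gene_id for g in genes], M)


@dataclass
class PseudobulkProfile:
    """Aggregated fragment counts per genomic bin (excluded chroms absent)."""

    bins: list[GenomicInterval]
    counts: np.ndarray
    excluded: tuple[str, ...]

    def aligned_with(self, other: "PseudobulkProfile") -> bool:
        return self.bins == other.bins


def build_pseudobulk_profile(
    fragments: pd.DataFrame,
    layout: GenomeLayout,
    bin_size: int = 10000,
    exclude: Sequence[str] | None = None,
) -> PseudobulkProfile:
    """Total fragment counts per 10 kb bin across all cells.

    Sex and mitochondrial chromosomes are excluded by default. A
    fragment spanning a bin boundary contributes to both bins
    (any-overlap assignment).
    """
    if exclude is None:
        exclude = tuple(layout.sex) + (layout.mito,)
    exclude = tuple(exclude)
    bins = [b for b in bin_genome(layout, bin_size) if b.chrom not in exclude]
    keep = fragments["chrom"].isin({b.chrom for b in bins})
    frags = fragments.loc[keep].reset_index(drop=True)
    rows, feats = _overlap_pairs_disjoint(frags, bins)
    counts = np.bincount(feats, minlength=len(bins)).astype(np.int64)
    return PseudobulkProfile(bins, counts, exclude)


# ----------------------------------------------------------------------
# MTX I/O with sidecars
# ----------------------------------------------------------------------

def write_matrix(matrix: AccessibilityMatrix, prefix: str | Path) -> None:
    """Write <prefix>.mtx with <prefix>.barcodes.txt and <prefix>.features.bed."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), matrix.X.tocoo())
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.parent / (prefix.name + ".barcodes.txt"), "w") as fh:
        fh.write("\n".join(matrix.barcodes) + "\n")
    write_bed(matrix.features, prefix.parent / (prefix.name + ".features.bed"))


def read_matrix(prefix: str | Path) -> AccessibilityMatrix:
    prefix = Path(prefix)
    X = sparse.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
    with open(prefix.parent / (prefix.name + ".barcodes.txt")) as fh:
        barcodes = [l.strip() for l in fh if l.strip()]
    features = read_bed(prefix.parent / (prefix.name + ".features.bed"))
    return AccessibilityMatrix(barcodes, features, X)


def write_counts_mtx(
    counts: np.ndarray, barcodes: Sequence[str], gene_ids: Sequence[str], prefix: str | Path
) -> None:
    """RNA counts as MTX plus barcode/feature name sidecars."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), sparse.coo_matrix(np.asarray(counts)))
    with open(prefix.parent / (prefix.name + ".barcodes.txt"), "w") as fh:
        fh.write("\n".join(barcodes) + "\n")
    with open(prefix.parent / (prefix.name + ".genes.txt"), "w") as fh:
        fh.write("\n".join(gene_ids) + "\n")
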