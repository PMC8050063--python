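"""Matrix builders against brute-force overlap oracles."""

import numpy as np
import pandas as pd
import pytest

from peakspec.intervals import GenomicInterval, GenomeLayout
from peakspec.genes import GeneModel
from peakspec.matrices import (
    build_cell_bin_matrix,
    build_cell_peak_matrix,
    build_gene_activity_matrix,
    build_pseudobulk_profile,
    filter_bins,
    read_matrix,
    write_matrix,
)

LAYOUT = GenomeLayout((("chr1", 30_000), ("chr2", 12_000), ("chrX", 8_000),
                       ("chrY", 4_000), ("chrM", 1_000)))


def frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode"])


def random_fragments(rng, n=400, barcodes=("a", "b", "c")):
    rows = []
    lengths = dict(LAYOUT.chromosomes)
    chroms = list(lengths)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, lengths[chrom] - 150))
        rows.append((chrom, start, start + int(rng.integers(20, 150)), barcodes[rng.integers(len(barcodes))]))
    return frame(rows)


def brute_overlap(frag_row, feature):
    return (
        frag_row.chrom == feature.chrom
        and frag_row.start < feature.end
        and feature.start < frag_row.end
    )


class TestCellBinMatrix:
    def test_multiple_fragments_binarized(self):
        rows = [("chr1", 100, 200, "a")] * 3
        m = build_cell_bin_matrix(frame(rows), LAYOUT, bin_size=5000)
        assert m.X.sum() == 1  # three fragments, one bin, entry 1

    def test_boundary_spanning_fragment_sets_both_bins(self):
        m = build_cell_bin_matrix(frame([("chr1", 4998, 5010, "a")]), LAYOUT, 5000)
        hit_bins = [m.features[j] for j in m.X.nonzero()[1]]
        assert {(b.start, b.end) for b in hit_bins} == {(0, 5000), (5000, 10000)}

    def test_mito_and_unknown_chrom_dropped(self):
        rows = [("chrM", 0, 100, "a"), ("chrUn", 0, 100, "a"), ("chr1", 0, 100, "a")]
        m = build_cell_bin_matrix(frame(rows), LAYOUT, 5000)
        assert m.X.sum() == 1
        assert all(b.chrom != "chrM" for b in m.features)

    def test_matches_brute_force(self, rng):
        frags = random_fragments(rng, n=200)
        m = build_cell_bin_matrix(frags, LAYOUT, 5000)
        keep = frags[(frags.chrom != "chrM") & frags.chrom.isin(LAYOUT.names)]
        dense = np.zeros(m.shape, dtype=int)
        row_of = {bc: i for i, bc in enumerate(m.barcodes)}
        for r in keep.itertuples():
            for j, b in enumerate(m.features):
                if brute_overlap(r, b):
                    dense[row_of[r.barcode], j] = 1
        assert np.array_equal(m.X.toarray(), dense)


class TestFilterBins:
    def test_top_fraction_count_via_sort_oracle(self, rng):
        frags = random_fragments(rng, n=600)
        m = build_cell_bin_matrix(frags, LAYOUT, 1000)
        filtered = filter_bins(m, top_fraction=0.05, blacklist=[])
        k = int(np.floor(0.05 * len(m.features)))
        assert len(filtered.features) == len(m.features) - k
        # the k removed bins have column sums >= every kept bin's sum
        removed = set(m.features) - set(filtered.features)
        sums = dict(zip(m.features, m.column_sums()))
        if removed:
            assert min(sums[b] for b in removed) >= max(
                sums[b] for b in filtered.features
            ) - 0  # ties broken by genomic order, so >= holds on the boundary

    def test_blacklist_bin_removed_regardless_of_accessibility(self):
        frags = frame([("chr1", 100, 150, "a")])
        m = build_cell_bin_matrix(frags, LAYOUT, 5000)
        filtered = filter_bins(m, top_fraction=0.0, blacklist=[GenomicInterval("chr1", 0, 10)])
        assert all(not (b.chrom == "chr1" and b.start == 0) for b in filtered.features)

    def test_rows_never_removed(self, study):
        from peakspec.matrices import build_cell_bin_matrix as bcb

        m = bcb(study.frags_kept.iloc[:5000], study.cfg.genome, 5000)
        filtered = filter_bins(m, 0.05, study.truth.blacklist)
        assert filtered.barcodes == m.barcodes


class TestCellPeakMatrix:
    PEAKS = [GenomicInterval("chr1", 1000, 1500), GenomicInterval("chr1", 3000, 3200)]

    def test_abutting_fragment_is_zero(self):
        m = build_cell_peak_matrix(frame([("chr1", 1500, 1600, "a")]), self.PEAKS)
        assert m.X.sum() == 0

    def test_containing_fragment_is_one(self):
        m = build_cell_peak_matrix(frame([("chr1", 900, 1600, "a")]), self.PEAKS)
        assert m.X.toarray()[0].tolist() == [1, 0]

    def test_overlapping_peaks_rejected(self):
        bad = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)]
        with pytest.raises(ValueError, match="merge"):
            build_cell_peak_matrix(frame([("chr1", 0, 10, "a")]), bad)

    def test_matches_brute_force(self, rng):
        peaks = sorted(
            (GenomicInterval("chr1", s, s + 200) for s in range(0, 29_000, 700)),
            key=lambda p: p.start,
        )
        frags = random_fragments(rng, n=300)
        m = build_cell_peak_matrix(frags, peaks)
        row_of = {bc: i for i, bc in enumerate(m.barcodes)}
        dense = np.zeros(m.shape, dtype=int)
        for r in frags.itertuples():
            for j, p in enumerate(m.features):
                if brute_overlap(r, p):
                    dense[row_of[r.barcode], j] = 1
        assert np.array_equal(m.X.toarray(), dense)
        # column sums = number of cells with >= 1 overlapping fragment
        assert np.array_equal(m.column_sums(), dense.sum(axis=0))


def make_gene(gene_id, strand, start=10_000, length=2_000, chrom="chr1"):
    span = GenomicInterval(chrom, start, start + length)
    return GeneModel(gene_id, chrom, strand, span, exons=(span,))


class TestGeneActivity:
    def test_upstream_fragment_counted_only_in_extended_mode(self):
        g = make_gene("g", "+")
        frags = frame([("chr1", 9000, 9100, "a")])  # 1 kb upstream of TSS
        m1 = build_gene_activity_matrix(frags, [g], mode="transcript_overlap")
        m2 = build_gene_activity_matrix(frags, [g], mode="body_plus_upstream", upstream=2000)
        assert m1.X.sum() == 0 and m2.X.sum() == 1

    def test_far_upstream_not_counted(self):
        g = make_gene("g", "+")
        frags = frame([("chr1", 6900, 7000, "a")])  # 3 kb upstream
        m = build_gene_activity_matrix(frags, [g], mode="body_plus_upstream", upstream=2000)
        assert m.X.sum() == 0

    def test_minus_strand_upstream_is_rightward(self):
        g = make_gene("g", "-")
        frags = frame([("chr1", 12_500, 12_600, "a")])  # 0.5 kb past span end
        m = build_gene_activity_matrix(frags, [g], mode="body_plus_upstream", upstream=2000)
        assert m.X.sum() == 1

    def test_fragment_may_count_toward_multiple_genes(self):
        g1 = make_gene("g1", "+", start=10_000)
        g2 = make_gene("g2", "+", start=11_000)
        frags = frame([("chr1", 11_200, 11_300, "a")])
        m = build_gene_activity_matrix(frags, [g1, g2])
        assert m.X.sum() == 2

    def test_matches_brute_force(self, rng):
        genes = [
            make_gene(f"g{i}", "+" if i % 2 else "-", start=2000 + 2500 * i, length=1500)
            for i in range(8)
        ]
        frags = random_fragments(rng, n=300)
        m = build_gene_activity_matrix(frags, genes, mode="body_plus_upstream")
        row_of = {bc: i for i, bc in enumerate(m.barcodes)}
        dense = np.zeros(m.X.shape, dtype=int)
        for r in frags.itertuples():
            for j, g in enumerate(genes):
                w = g.scoring_window("body_plus_upstream", 2000)
                if brute_overlap(r, w):
                    dense[row_of[r.barcode], j] += 1
        assert np.array_equal(m.X.toarray(), dense)


class TestPseudobulk:
    def test_excluded_chromosomes_absent(self, rng):
        p = build_pseudobulk_profile(random_fragments(rng), LAYOUT)
        assert {b.chrom for b in p.bins} == {"chr1", "chr2"}

    def test_counts_match_brute_force(self, rng):
        frags = random_fragments(rng, n=250)
        p = build_pseudobulk_profile(frags, LAYOUT, bin_size=1000)
        brute = np.zeros(len(p.bins), dtype=int)
        for r in frags.itertuples():
            for j, b in enumerate(p.bins):
                if brute_overlap(r, b):
                    brute[j] += 1
        assert np.array_equal(p.counts, brute)


def test_mtx_round_trip(tmp_path, rng):
    frags = random_fragments(rng, n=120)
    m = build_cell_bin_matrix(frags, LAYOUT, 5000)
    write_matrix(m, tmp_path / "mat")
    back = read_matrix(tmp_path / "mat")
    assert back.barcodes == m.barcodes
    assert [(f.chrom, f.start, f.end) for f in back.features] == [
        (f.chrom, f.start, f.end) for f in m.features
    ]
    assert (back.X != m.X).nnz == 0
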