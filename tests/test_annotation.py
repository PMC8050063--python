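"""Element stratification priority, nearest genes, SNP-peak overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest

from peakspec.annotation import (
    classify_peak_element,
    classify_peaks,
    element_class_counts,
    nearest_gene,
    overlap_snps_with_peaks,
)
from peakspec.genes import GeneModel
from peakspec.intervals import GenomicInterval


def gene_with_elements(chrom="chr1"):
    """Gene laid out so disjoint probe positions hit exactly one element.

    Span [10000, 20000), '+': exon1 [10000,12000) containing 5'UTR
    [10000,10500); intron (12000,14000); exon2 [14000,16000); exon3
    [18000,20000) containing 3'UTR [19500,20000); promoter upstream
    [5000,10000).
    """
    span = GenomicInterval(chrom, 10_000, 20_000)
    return GeneModel(
        "g1", chrom, "+", span,
        exons=(
            GenomicInterval(chrom, 10_000, 12_000),
            GenomicInterval(chrom, 14_000, 16_000),
            GenomicInterval(chrom, 18_000, 20_000),
        ),
        utr5=(GenomicInterval(chrom, 10_000, 10_500),),
        utr3=(GenomicInterval(chrom, 19_500, 20_000),),
    )


# probe windows, each overlapping exactly one element of gene_with_elements
PROBE = {
    "exon": (15_000, 15_100),
    "utr5": (10_100, 10_200),   # also exon1: utr5 never wins alone here
    "utr3": (19_600, 19_700),   # also exon3
    "intron": (12_500, 12_600),
    "promoter": (6_000, 6_100),
}


class TestElementPriority:
    def test_exon_beats_utr5(self):
        peak = GenomicInterval("chr1", 10_100, 10_200)  # inside exon1 and 5'UTR
        assert classify_peak_element(peak, [gene_with_elements()]) == "exon"

    def test_no_overlap_is_distal(self):
        peak = GenomicInterval("chr1", 100_000, 100_500)
        assert classify_peak_element(peak, [gene_with_elements()]) == "distal"

    def test_intron_beats_promoter_across_genes(self):
        g_a = gene_with_elements()
        g_b = GeneModel(
            "g2", "chr1", "-", GenomicInterval("chr1", 13_000, 13_400),
            exons=(GenomicInterval("chr1", 13_000, 13_400),),
        )
        # g_b's promoter (upstream on '-') covers [13400, 18400); a peak at
        # 12500 lies in g_a's intron and in no promoter; at 13500 it lies in
        # g_a's intron AND g_b's promoter -> intron wins
        peak = GenomicInterval("chr1", 13_500, 13_600)
        assert classify_peak_element(peak, [g_a, g_b]) == "intron"

    def test_all_32_element_subsets(self):
        """For every subset of {exon, utr5, utr3, intron, promoter} build a
        multi-gene annotation where a probe peak overlaps exactly that
        subset; the class must be the highest-priority member (distal for
        the empty set)."""
        priority = ["exon", "utr5", "utr3", "intron", "promoter"]
        for r in range(6):
            for subset in itertools.combinations(priority, r):
                genes = []
                peak_parts = []
                base = 0
                for k, cls in enumerate(subset):
                    chrom = "chr1"
                    offset = 100_000 * (k + 1)
                    span = GenomicInterval(chrom, offset + 10_000, offset + 20_000)
                    exon_all = (GenomicInterval(chrom, offset + 10_000, offset + 20_000),)
                    if cls == "exon":
                        g = GeneModel(f"ge{k}", chrom, "+", span, exons=exon_all)
                        probe = (offset + 15_000, offset + 15_100)
                    elif cls == "utr5":
                        g = GeneModel(
                            f"g5{k}", chrom, "+", span, exons=(),
                            utr5=(GenomicInterval(chrom, offset + 10_000, offset + 10_500),),
                        )
                        probe = (offset + 10_100, offset + 10_200)
                    elif cls == "utr3":
                        g = GeneModel(
                            f"g3{k}", chrom, "+", span, exons=(),
                            utr3=(GenomicInterval(chrom, offset + 19_500, offset + 20_000),),
                        )
                        probe = (offset + 19_600, offset + 19_700)
                    elif cls == "intron":
                        g = GeneModel(
                            f"gi{k}", chrom, "+", span,
                            exons=(GenomicInterval(chrom, offset + 10_000, offset + 10_100),),
                        )
                        probe = (offset + 15_000, offset + 15_100)
                    else:  # promoter
                        g = GeneModel(f"gp{k}", chrom, "+", span, exons=exon_all)
                        probe = (offset + 6_000, offset + 6_100)
                    genes.append(g)
                    peak_parts.append(probe)
                if subset:
                    start = min(p[0] for p in peak_parts)
                    end = max(p[1] for p in peak_parts)
                    # single spanning peak would hit everything between parts;
                    # instead classify each probe and combine by priority
                    classes = classify_peaks(
                        [GenomicInterval("chr1", s, e) for s, e in peak_parts], genes
                    )
                    combined = min(classes, key=priority.index)
                    assert combined == subset[0]
                else:
                    peak = GenomicInterval("chr1", 50, 100)
                    assert classify_peak_element(peak, genes) == "distal"

    def test_counts_sum_to_peak_count(self, study):
        classes = classify_peaks(study.truth.peaks, study.truth.genes)
        counts = element_class_counts(classes)
        assert counts.sum() == len(study.truth.peaks)

    def test_promoter_widening_is_monotone(self, study):
        """Raising promoter_upstream 2000 -> 5000 never moves a peak from
        promoter to distal."""
        c2 = classify_peaks(study.truth.peaks, study.truth.genes, promoter_upstream=2000)
        c5 = classify_peaks(study.truth.peaks, study.truth.genes, promoter_upstream=5000)
        for a, b in zip(c2, c5):
            if a == "promoter":
                assert b != "distal"


class TestNearestGene:
    def mk(self, gid, tss, strand="+"):
        if strand == "+":
            span = GenomicInterval("chr1", tss, tss + 1000)
        else:
            span = GenomicInterval("chr1", tss - 999, tss + 1)
        return GeneModel(gid, "chr1", strand, span, exons=(span,))

    def test_picks_closer_tss_with_downstream_sign(self):
        genes = [self.mk("a", 100), self.mk("b", 300)]
        gid, dist = nearest_gene("chr1", 150, genes)
        assert gid == "a" and dist == 50

    def test_zero_at_tss(self):
        assert nearest_gene("chr1", 100, [self.mk("a", 100)]) == ("a", 0)

    def test_upstream_is_negative_in_gene_orientation(self):
        assert nearest_gene("chr1", 80, [self.mk("a", 100)])[1] == -20
        assert nearest_gene("chr1", 2020, [self.mk("m", 2000, "-")])[1] == -20

    def test_no_gene_on_chrom(self):
        assert nearest_gene("chr9", 5, [self.mk("a", 100)]) == (None, None)

    def test_matches_exhaustive_scan(self, rng):
        genes = [self.mk(f"g{i}", int(t)) for i, t in enumerate(rng.integers(1000, 90_000, 25))]
        for pos in rng.integers(0, 100_000, 50):
            gid, dist = nearest_gene("chr1", int(pos), genes)
            best = min(genes, key=lambda g: (abs(int(pos) - g.tss), g.tss, g.gene_id))
            assert gid == best.gene_id
            assert abs(dist) == abs(int(pos) - best.tss)


class TestSnpOverlap:
    PEAKS = [GenomicInterval("chr1", 100, 200, name="p0"), GenomicInterval("chr1", 500, 600, name="p1")]
    GENES = [GeneModel("g", "chr1", "+", GenomicInterval("chr1", 1000, 2000),
                       exons=(GenomicInterval("chr1", 1000, 2000),))]

    def snp(self, pos, name="s"):
        return [GenomicInterval("chr1", pos, pos + 1, name=name)]

    def test_inside_peak(self):
        tab = overlap_snps_with_peaks(self.snp(150), self.PEAKS, None, self.GENES)
        assert tab.loc[0, "n_overlapping_peaks"] == 1

    def test_end_coordinate_excluded(self):
        tab = overlap_snps_with_peaks(self.snp(200), self.PEAKS, None, self.GENES)
        assert tab.loc[0, "n_overlapping_peaks"] == 0

    def test_start_coordinate_included(self):
        tab = overlap_snps_with_peaks(self.snp(100), self.PEAKS, None, self.GENES)
        assert tab.loc[0, "n_overlapping_peaks"] == 1

    def test_matches_brute_force_and_planted_fraction(self, study):
        """SNP-peak overlap equals an O(S*P) scan; the recovered in-peak
        fraction equals the planted fraction exactly; cell-type
        attributions only come from DAP-specific peaks."""
        truth = study.truth
        tab = overlap_snps_with_peaks(study.snps, truth.peaks, study.daps, truth.genes)
        expected_hits = 0
        for _, s in truth.snps.iterrows():
            inside = [
                p for p in truth.peaks
                if p.chrom == s["chrom"] and p.start <= s["pos"] < p.end
            ]
            expected_hits += bool(inside)
            row = tab[tab["snp_id"] == s["snp_id"]].iloc[0]
            assert row["n_overlapping_peaks"] == len(inside)
        frac = (tab["n_overlapping_peaks"] > 0).mean()
        assert frac == pytest.approx(study.cfg.snp_in_peak_fraction)
        assert expected_hits == (tab["n_overlapping_peaks"] > 0).sum()
        # planted cell type recovered for in-peak SNPs whose peak is a DAP
        called = study.daps.peak_type_map()
        for _, s in truth.snps[truth.snps["in_peak"]].iterrows():
            if s["peak_index"] in called:
                row = tab[tab["snp_id"] == s["snp_id"]].iloc[0]
                assert called[s["peak_index"]] in row["cell_types"].split(",")
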