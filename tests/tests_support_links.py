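"""Brute-force CRE-link fixture check shared by link and acceptance tests."""

import numpy as np
import pandas as pd

from peakspec.dap import DapCallResult
from peakspec.genes import GeneModel
from peakspec.intervals import GenomicInterval
from peakspec.links import link_daps_to_degs


def _gene(gid, tss, strand):
    if strand == "+":
        span = GenomicInterval("chr1", tss, tss + 5000)
    else:
        span = GenomicInterval("chr1", tss - 4999, tss + 1)
    return GeneModel(gid, "chr1", strand, span, exons=(span,))


def random_fixture_check(seed: int) -> None:
    """Assert linker output equals a literal all-pairs predicate scan."""
    r = np.random.default_rng(seed)
    types = ["A", "B", "C"]
    genes = [
        _gene(f"g{i}", int(t), "+-"[r.integers(2)])
        for i, t in enumerate(r.integers(200_000, 2_000_000, 12))
    ]
    peaks = [
        GenomicInterval("chr1", int(s) + i * 600, int(s) + i * 600 + 500)
        for i, s in enumerate(sorted(r.integers(0, 2_200_000, 30)))
    ]
    peak_types = [types[r.integers(3)] for _ in peaks]
    degs = pd.DataFrame(
        [(g.gene_id, types[r.integers(3)], bool(r.integers(2))) for g in genes],
        columns=["gene", "group", "significant"],
    )
    specific = {ct: np.array([t == ct for t in peak_types]) for ct in types}
    daps = DapCallResult(
        peaks=peaks, cell_types=types, padj={}, pvals={},
        fractions={}, specific=specific, alpha=0.05,
    )
    got = {
        (l.gene_id, l.peak_index, l.cell_type)
        for l in link_daps_to_degs(daps, degs, genes)
    }
    expected = set()
    for _, row in degs[degs["significant"]].iterrows():
        g = next(x for x in genes if x.gene_id == row["gene"])
        for pi, (pk, ct) in enumerate(zip(peaks, peak_types)):
            if ct != row["group"]:
                continue
            if pk.start <= g.tss < pk.end:
                continue
            gap = pk.start - g.tss if g.tss < pk.start else g.tss - (pk.end - 1)
            if abs(gap) <= 100_000:
                expected.add((g.gene_id, pi, ct))
    assert got == expected
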