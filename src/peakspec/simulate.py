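"""Synthetic single-cell multi-omic kidney study with planted ground truth.

Generates everything downstream stages consume — per-cell ATAC fragment
records, negative-binomial RNA counts, gene models, peak/blacklist BEDs,
a branching differentiation trajectory, and GWAS-style SNPs — while
recording exactly what was planted (cell-type-specific peaks, marker
genes, peak–gene couples, stage-transition events, in-peak SNPs) so that
recovery rates against the truth are measurable.

The accessibility model is Bernoulli per (cell, peak): a peak planted
for a cell's type (or open in its trajectory stage) emits at least one
fragment with probability ``p1``, any other peak with probability
``p0``. Background fragments are placed uniformly outside all peaks;
mitochondrial and promoter-region fragments are injected to realise the
configured per-cell QC covariates. Identical seeds produce
byte-identical output files.
"""

from __future__ import annotations

import gzip
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, GenomeLayout
from .genes import GeneModel, write_gene_table
from .trajectory import StageGraph, default_kidney_graph

KIDNEY_TYPES = ("NP", "Podo", "PT", "LOH", "DCT", "IC", "PC", "Endo", "Immune", "Stroma")

_QC_RULES = ("low_fragments", "high_fragments", "high_mito", "low_promoter")
_RNA_RULES = ("low_genes", "high_mito_pct")


def default_genome() -> GenomeLayout:
    """Five 20-Mb autosomes plus scaled-down sex and mito chromosomes."""
    chroms = tuple((f"chr{i}", 20_000_000) for i in range(1, 6))
    chroms += (("chrX", 10_000_000), ("chrY", 5_000_000), ("chrM", 16_299))
    return GenomeLayout(chroms, mito="chrM", sex=("chrX", "chrY"))


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable constants of the emulated study design.

    Accessibility rates follow the planted two-rate model: baseline
    ``p0`` everywhere, elevated ``p1`` in a peak's own cell type (or
    trajectory stage). Per-cell fragment totals are drawn log-normally
    and clipped inside the QC-passing window so that only deliberately
    planted violator cells fail quality control.
    """

    n_cell_types: int = 5
    n_cells_per_type: int = 200
    n_peaks: int = 1000
    n_specific_peaks_per_type: int = 50
    p0: float = 0.05
    p1: float = 0.6
    background_fragments_per_cell: int = 1500
    mito_fraction: float = 0.02
    promoter_fragment_fraction: float = 0.30
    rna_nb_mean: float = 6.0
    rna_nb_dispersion: float = 2.0
    marker_log2_fold_change: float = 2.0
    n_marker_genes_per_type: int = 10
    n_genes: int = 300
    n_mito_genes: int = 10
    stage_graph: StageGraph | None = None
    n_cells_per_stage: int = 150
    n_transition_peaks_per_edge: int = 10
    snp_in_peak_fraction: float = 0.5
    n_snps: int = 200
    n_qc_violators_per_rule: int = 5
    peak_width: int = 500
    fragment_length: int = 200
    unpaired_rna: bool = False
    genome: GenomeLayout = field(default_factory=default_genome)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 < self.p1 <= 1.0):
            raise ValueError("require 0 <= p0 < p1 <= 1")
        for name in ("mito_fraction", "promoter_fragment_fraction", "snp_in_peak_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "n_cell_types", "n_cells_per_type", "n_peaks", "n_specific_peaks_per_type",
            "n_marker_genes_per_type", "n_genes", "n_snps", "n_qc_violators_per_rule",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cell_types * self.n_specific_peaks_per_type > self.n_peaks:
            raise ValueError("more planted specific peaks requested than peaks")
        if self.n_marker_genes_per_type > self.n_specific_peaks_per_type:
            raise ValueError("each marker gene needs a coupled specific peak")
        if self.n_cell_types * self.n_marker_genes_per_type > self.n_genes:
            raise ValueError("more marker genes requested than genes")
        if self.rna_nb_mean <= 0 or self.rna_nb_dispersion <= 0:
            raise ValueError("NB mean and dispersion must be positive")

    def cell_type_names(self) -> list[str]:
        if self.n_cell_types <= len(KIDNEY_TYPES):
            return list(KIDNEY_TYPES[: self.n_cell_types])
        return [f"type{i}" for i in range(self.n_cell_types)]


@dataclass
class SyntheticTruth:
    """Ground truth bundle recorded while simulating."""

    config: SimulationConfig
    peaks: list[GenomicInterval]
    genes: list[GeneModel]
    blacklist: list[GenomicInterval]
    cell_types: dict[str, str]
    specific_peaks: dict[str, set[int]]
    marker_genes: dict[str, list[str]]
    links: list[tuple[str, int, str]]            # (gene_id, peak index, cell type)
    qc_violators: dict[str, str]
    stage: dict[str, str] | None = None
    lineage: dict[str, str] | None = None
    pseudotime: dict[str, float] | None = None
    transition_events: dict[tuple[str, str], tuple[list[int], list[int]]] | None = None
    snps: pd.DataFrame | None = None
    rna_violators: dict[str, str] | None = None

    def planted_peak_types(self) -> dict[int, str]:
        """Peak index -> the unique cell type it was planted for."""
        out: dict[int, str] = {}
        for ct, idxs in self.specific_peaks.items():
            for i in idxs:
                out[i] = ct
        return out


@dataclass
class TrajectorySimulation:
    """Per-cell stage/lineage/pseudotime plus planted transition events."""

    graph: StageGraph
    stage: dict[str, str]
    lineage: dict[str, str]
    pseudotime: dict[str, float]
    events: dict[tuple[str, str], tuple[list[int], list[int]]]
    stage_open_peaks: dict[str, set[int]]


# ----------------------------------------------------------------------
# annotation scaffolding
# ----------------------------------------------------------------------

def _make_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    autosomes = config.genome.autosomes()
    lengths = config.genome.lengths
    gene_len = 10_000
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // len(autosomes)] * len(autosomes)
    for i in range(config.n_genes % len(autosomes)):
        per_chrom[i] += 1
    gid = 0
    for chrom, n_here in zip(autosomes, per_chrom):
        if n_here == 0:
            continue
        slot = lengths[chrom] // n_here
        if slot < gene_len + 40_000:
            raise ValueError("genome too small for requested gene count")
        for j in range(n_here):
            lo = j * slot + 15_000
            hi = (j + 1) * slot - gene_len - 15_000
            start = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            span = GenomicInterval(chrom, start, start + gene_len)
            exons = (
                GenomicInterval(chrom, start, start + 1500),
                GenomicInterval(chrom, start + 4000, start + 5500),
                GenomicInterval(chrom, start + 8500, start + gene_len),
            )
            if strand == "+":
                utr5 = (GenomicInterval(chrom, start, start + 300),)
                utr3 = (GenomicInterval(chrom, start + gene_len - 300, start + gene_len),)
            else:
                utr5 = (GenomicInterval(chrom, start + gene_len - 300, start + gene_len),)
                utr3 = (GenomicInterval(chrom, start, start + 300),)
            genes.append(GeneModel(f"gene{gid:04d}", chrom, strand, span, exons, utr5, utr3))
            gid += 1
    return genes


def _allowed_window_sampler(
    config: SimulationConfig,
    forbidden: Sequence[GenomicInterval],
    item_len: int,
) -> Callable[[int, np.random.Generator], tuple[list[str], np.ndarray]]:
    """Uniform sampler of item start positions avoiding forbidden intervals.

    An item of length ``item_len`` starting at s occupies [s, s+item_len);
    starts within ``item_len - 1`` bases upstream of a forbidden interval
    are excluded so sampled items never overlap it. Mito chromosome is
    never sampled.
    """
    lengths = config.genome.lengths
    chrom_ok = [c for c in config.genome.names if c != config.genome.mito]
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_ok}
    for iv in forbidden:
        if iv.chrom in by_chrom:
            by_chrom[iv.chrom].append((max(0, iv.start - item_len + 1), iv.end))
    win_chrom: list[str] = []
    win_start: list[int] = []
    win_len: list[int] = []
    for chrom in chrom_ok:
        bounds = sorted(by_chrom[chrom])
        cursor = 0
        limit = lengths[chrom] - item_len
        for s, e in bounds + [(limit + 1, limit + 1)]:
            if s > cursor:
                w = min(s, limit + 1) - cursor
                if w > 0:
                    win_chrom.append(chrom)
                    win_start.append(cursor)
                    win_len.append(w)
            cursor = max(cursor, e)
            if cursor > limit:
                break
    win_start_a = np.array(win_start, dtype=np.int64)
    win_len_a = np.array(win_len, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(win_len_a)])
    total = int(cum[-1])
    if total <= 0:
        raise ValueError("no free genomic space left to place items")

    def sample(n: int, rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
        u = rng.integers(0, total, size=n)
        idx = np.searchsorted(cum, u, side="right") - 1
        starts = win_start_a[idx] + (u - cum[idx])
        chroms = [win_chrom[i] for i in idx]
        return chroms, starts

    return sample


def _place_peaks(
    config: SimulationConfig,
    genes: list[GeneModel],
    markers_by_type: dict[str, list[int]],
    rng: np.random.Generator,
) -> tuple[list[GenomicInterval], dict[str, set[int]], list[tuple[str, int, str]]]:
    """Place peaks: one coupled peak inside each marker gene's body, the
    rest intergenic (clear of gene territories and of each other)."""
    w = config.peak_width
    peaks: list[tuple[str, int, int]] = []
    links: list[tuple[str, int, str]] = []
    specific: dict[str, set[int]] = {ct: set() for ct in markers_by_type}

    for ct, gene_idxs in markers_by_type.items():
        for gi in gene_idxs:
            g = genes[gi]
            # strand-aware: 3 kb downstream of the TSS, inside the gene body,
            # clear of the TSS and of the +/-2 kb QC promoter window
            if g.strand == "+":
                s = g.tss + 3000
            else:
                s = g.tss - 3000 - w
            idx = len(peaks)
            peaks.append((g.chrom, s, s + w))
            specific[ct].add(idx)
            links.append((g.gene_id, idx, ct))

    n_rest = config.n_peaks - len(peaks)
    territory = [
        GenomicInterval(g.chrom, max(0, g.span.start - 6000), g.span.end + 6000)
        for g in genes
    ]
    sampler = _allowed_window_sampler(config, territory, w)
    placed: list[tuple[str, int]] = []
    guard = 0
    while len(placed) < n_rest:
        guard += 1
        if guard > 50:
            raise ValueError("could not place peaks in free genomic space")
        chroms, starts = sampler(2 * (n_rest - len(placed)) + 8, rng)
        cand = sorted(set(zip(chroms, (int(s) for s in starts))))
        rng.shuffle(cand)
        occupied = sorted(placed + [(c, s) for c, s, _ in peaks])
        for c, s in cand:
            if len(placed) >= n_rest:
                break
            import bisect

            i = bisect.bisect_left(occupied, (c, s))
            ok = True
            if i > 0 and occupied[i - 1][0] == c and occupied[i - 1][1] + w > s:
                ok = False
            if i < len(occupied) and occupied[i][0] == c and occupied[i][1] < s + w:
                ok = False
            if ok:
                bisect.insort(occupied, (c, s))
                placed.append((c, s))
    for c, s in placed:
        peaks.append((c, s, s + w))

    # canonical genomic order; remap planted indices through the sort
    order = sorted(range(len(peaks)), key=lambda i: peaks[i])
    remap = {old: new for new, old in enumerate(order)}
    out_peaks = [
        GenomicInterval(*peaks[old], name=f"peak{new:05d}")
        for new, old in enumerate(order)
    ]
    specific = {ct: {remap[i] for i in idxs} for ct, idxs in specific.items()}
    links = [(g, remap[i], ct) for g, i, ct in links]
    return out_peaks, specific, links


def _place_blacklist(
    config: SimulationConfig,
    genes: list[GeneModel],
    peaks: list[GenomicInterval],
    rng: np.random.Generator,
    n_regions: int = 10,
    region_len: int = 5000,
) -> list[GenomicInterval]:
    forbidden = [GenomicInterval(g.chrom, max(0, g.span.start - 6000), g.span.end + 6000) for g in genes]
    forbidden += [GenomicInterval(p.chrom, p.start, p.end) for p in peaks]
    sampler = _allowed_window_sampler(config, forbidden, region_len)
    chroms, starts = sampler(n_regions, rng)
    out = sorted(
        GenomicInterval(c, int(s), int(s) + region_len) for c, s in zip(chroms, starts)
    )
    return out


# ----------------------------------------------------------------------
# trajectory
# ----------------------------------------------------------------------

def simulate_trajectory(config: SimulationConfig) -> TrajectorySimulation:
    """Assign cells to stages along a rooted stage tree and plant
    opening/closing chromatin events on every edge.

    Pseudotime is uniform within a stage's depth band, so it increases in
    expectation from every stage to its descendants. For each edge, half
    the planted peaks open (p0 -> p1 in the descendant subtree) and half
    close (p1 outside the subtree -> p0 inside).
    """
    graph = config.stage_graph or default_kidney_graph()
    graph.validate()
    rng = np.random.default_rng(_subseed(config.seed, "trajectory"))

    depth = graph.depths()
    max_depth = max(depth.values())
    stage_list = graph.topological_order()

    stage: dict[str, str] = {}
    lineage: dict[str, str] = {}
    pseudotime: dict[str, float] = {}
    i = 0
    for st in stage_list:
        lin = graph.lineage_of(st)
        lo = depth[st] / (max_depth + 1)
        hi = (depth[st] + 1) / (max_depth + 1)
        for _ in range(config.n_cells_per_stage):
            bc = f"TBC{i:06d}"
            stage[bc] = st
            lineage[bc] = lin
            pseudotime[bc] = float(lo + (hi - lo) * rng.random())
            i += 1

    # plant transition events on edges using peaks not coupled to markers
    n_coupled = config.n_cell_types * config.n_marker_genes_per_type
    pool = list(range(n_coupled, config.n_peaks))
    rng.shuffle(pool)
    k = config.n_transition_peaks_per_edge
    if len(pool) < k * len(graph.edges):
        raise ValueError("not enough peaks to plant transition events")
    events: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
    pos = 0
    for edge in graph.edges:
        chunk = pool[pos: pos + k]
        pos += k
        half = k // 2
        events[edge] = (sorted(chunk[:half]), sorted(chunk[half:]))

    # open-peak set per stage by walking the tree
    stage_open: dict[str, set[int]] = {}
    for st in stage_list:
        sub = graph.subtree(st)
        open_here: set[int] = set()
        for (u, v), (opened, closed) in events.items():
            in_sub = st in graph.subtree(v)
            if in_sub:
                open_here.update(opened)
            else:
                open_here.update(closed)
        stage_open[st] = open_here

    return TrajectorySimulation(graph, stage, lineage, pseudotime, events, stage_open)


# ----------------------------------------------------------------------
# ATAC fragments
# ----------------------------------------------------------------------

def _subseed(seed: int, label: str) -> int:
    # process-stable label hash (Python's str hash is salted per process)
    tag = zlib.crc32(label.encode()) % (2**31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def simulate_atac_fragments(
    config: SimulationConfig,
    trajectory: TrajectorySimulation | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate per-cell fragment records plus the recorded truth.

    Returns a fragments DataFrame (chrom, start, end, barcode) sorted by
    genomic position, and the :class:`SyntheticTruth`. When a
    ``trajectory`` is supplied, cells are the trajectory's cells and peak
    accessibility follows the per-stage open sets instead of flat
    cell-type planting.
    """
    rng = np.random.default_rng(_subseed(config.seed, "atac"))
    genes = _make_genes(config, rng)

    type_names = config.cell_type_names()
    gene_order = rng.permutation(len(genes))
    markers_by_type: dict[str, list[int]] = {}
    cursor = 0
    for ct in type_names:
        markers_by_type[ct] = [int(g) for g in gene_order[cursor: cursor + config.n_marker_genes_per_type]]
        cursor += config.n_marker_genes_per_type

    peaks, specific, links = _place_peaks(config, genes, markers_by_type, rng)

    # top up each type's specific set with intergenic peaks
    planted = set().union(*specific.values()) if specific else set()
    free = [i for i in range(len(peaks)) if i not in planted]
    if trajectory is not None:
        # reserve transition-event peaks: they must stay unplanted
        reserved = set()
        for opened, closed in trajectory.events.values():
            reserved.update(opened, closed)
        free = [i for i in free if i not in reserved]
    rng.shuffle(free)
    fi = 0
    for ct in type_names:
        need = config.n_specific_peaks_per_type - len(specific[ct])
        specific[ct].update(free[fi: fi + need])
        fi += need

    blacklist = _place_blacklist(config, genes, peaks, rng)

    # --- cells -------------------------------------------------------
    if trajectory is None:
        barcodes = [f"BC{i:06d}" for i in range(config.n_cell_types * config.n_cells_per_type)]
        cell_types = {bc: type_names[i // config.n_cells_per_type] for i, bc in enumerate(barcodes)}
        groups = {bc: cell_types[bc] for bc in barcodes}
        group_open = {ct: specific[ct] for ct in type_names}
        # planted QC violators, appended after the clean cells
        qc_violators: dict[str, str] = {}
        v = 0
        for rule in _QC_RULES:
            for _ in range(config.n_qc_violators_per_rule):
                bc = f"QCV{v:04d}"
                qc_violators[bc] = rule
                cell_types[bc] = type_names[v % len(type_names)]
                groups[bc] = cell_types[bc]
                barcodes.append(bc)
                v += 1
    else:
        barcodes = sorted(trajectory.stage)
        cell_types = {bc: trajectory.stage[bc] for bc in barcodes}
        groups = dict(cell_types)
        group_open = {st: open_set for st, open_set in trajectory.stage_open_peaks.items()}
        qc_violators = {}

    n_cells = len(barcodes)
    flen = config.fragment_length

    # per-cell fragment budget
    totals = np.clip(
        np.round(rng.lognormal(np.log(config.background_fragments_per_cell), 0.3, n_cells)),
        1100, 38000,
    ).astype(np.int64)
    mito_frac = np.full(n_cells, config.mito_fraction)
    prom_frac = np.full(n_cells, config.promoter_fragment_fraction)
    for i, bc in enumerate(barcodes):
        rule = qc_violators.get(bc)
        if rule == "low_fragments":
            totals[i] = 300
        elif rule == "high_fragments":
            totals[i] = 45_000
        elif rule == "high_mito":
            mito_frac[i] = 0.30
        elif rule == "low_promoter":
            prom_frac[i] = 0.05

    # --- peak fragments: Bernoulli accessibility per (cell, peak) -----
    n_peaks = len(peaks)
    rates_by_group: dict[str, np.ndarray] = {}
    for gname, open_set in group_open.items():
        r = np.full(n_peaks, config.p0)
        if open_set:
            r[sorted(open_set)] = config.p1
        rates_by_group[gname] = r

    peak_start = np.array([p.start for p in peaks], dtype=np.int64)
    peak_chrom = [p.chrom for p in peaks]
    chrom_codes = {c: i for i, c in enumerate(config.genome.names)}
    peak_chrom_code = np.array([chrom_codes[c] for c in peak_chrom], dtype=np.int32)

    cell_code = {bc: i for i, bc in enumerate(barcodes)}
    frag_cell: list[np.ndarray] = []
    frag_chromcode: list[np.ndarray] = []
    frag_start: list[np.ndarray] = []
    peak_counts_per_cell = np.zeros(n_cells, dtype=np.int64)

    by_group: dict[str, list[int]] = {}
    for bc in barcodes:
        by_group.setdefault(groups[bc], []).append(cell_code[bc])
    for gname in sorted(by_group):
        members = np.array(by_group[gname], dtype=np.int64)
        rates = rates_by_group[gname]
        open_mask = rng.random((len(members), n_peaks)) < rates[None, :]
        counts = np.where(open_mask, 1 + rng.poisson(0.7, size=open_mask.shape), 0)
        cell_idx, pk_idx = np.nonzero(counts)
        reps = counts[cell_idx, pk_idx]
        cells_f = np.repeat(members[cell_idx], reps)
        pks_f = np.repeat(pk_idx, reps)
        offs = rng.integers(0, config.peak_width - flen + 1, size=len(pks_f))
        frag_cell.append(cells_f)
        frag_chromcode.append(peak_chrom_code[pks_f])
        frag_start.append(peak_start[pks_f] + offs)
        np.add.at(peak_counts_per_cell, members, counts.sum(axis=1))

    # --- mito / promoter / background budgets -------------------------
    n_mito = np.round(mito_frac * totals).astype(np.int64)
    n_prom = np.round(prom_frac * totals).astype(np.int64)
    n_bg = np.maximum(totals - peak_counts_per_cell - n_mito - n_prom, 0)

    mito_len = config.genome.lengths[config.genome.mito]
    tot_mito = int(n_mito.sum())
    frag_cell.append(np.repeat(np.arange(n_cells), n_mito))
    frag_chromcode.append(np.full(tot_mito, chrom_codes[config.genome.mito], dtype=np.int32))
    frag_start.append(rng.integers(0, mito_len - flen, size=tot_mito))

    tss = np.array([g.tss for g in genes], dtype=np.int64)
    gene_chrom_code = np.array([chrom_codes[g.chrom] for g in genes], dtype=np.int32)
    tot_prom = int(n_prom.sum())
    pick = rng.integers(0, len(genes), size=tot_prom)
    frag_cell.append(np.repeat(np.arange(n_cells), n_prom))
    frag_chromcode.append(gene_chrom_code[pick])
    frag_start.append(
        np.maximum(0, tss[pick] - 2000) + rng.integers(0, 4000 - flen, size=tot_prom)
    )

    bg_sampler = _allowed_window_sampler(config, peaks, flen)
    tot_bg = int(n_bg.sum())
    bg_chroms, bg_starts = bg_sampler(tot_bg, rng)
    frag_cell.append(np.repeat(np.arange(n_cells), n_bg))
    frag_chromcode.append(np.array([chrom_codes[c] for c in bg_chroms], dtype=np.int32))
    frag_start.append(bg_starts)

    cell_a = np.concatenate(frag_cell)
    chrom_a = np.concatenate(frag_chromcode)
    start_a = np.concatenate(frag_start).astype(np.int64)

    order = np.lexsort((cell_a, start_a, chrom_a))
    inv_chrom = config.genome.names
    frags = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(chrom_a[order], categories=inv_chrom),
            "start": start_a[order],
            "end": start_a[order] + flen,
            "barcode": pd.Categorical.from_codes(cell_a[order].astype(np.int32), categories=barcodes),
        }
    )
    frags["chrom"] = frags["chrom"].astype(str)
    frags["barcode"] = frags["barcode"].astype(str)

    truth = SyntheticTruth(
        config=config,
        peaks=peaks,
        genes=genes,
        blacklist=blacklist,
        cell_types=cell_types,
        specific_peaks=specific,
        marker_genes={ct: [genes[i].gene_id for i in idxs] for ct, idxs in markers_by_type.items()},
        links=links,
        qc_violators=qc_violators,
        stage=None if trajectory is None else dict(trajectory.stage),
        lineage=None if trajectory is None else dict(trajectory.lineage),
        pseudotime=None if trajectory is None else dict(trajectory.pseudotime),
        transition_events=None if trajectory is None else dict(trajectory.events),
    )
    return frags, truth


# ----------------------------------------------------------------------
# RNA counts
# ----------------------------------------------------------------------

@dataclass
class RnaCounts:
    """Raw cell x gene count matrix with labels (dense; desk scale)."""

    barcodes: list[str]
    gene_ids: list[str]
    counts: np.ndarray          # shape (cells, genes), non-negative ints
    mito_genes: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.barcodes, columns=self.gene_ids)


def simulate_rna_counts(config: SimulationConfig, truth: SyntheticTruth) -> RnaCounts:
    """Negative-binomial RNA counts coupled to the planted ATAC truth.

    Marker genes of a cell type have their mean scaled by
    ``2**marker_log2_fold_change`` in that type; mitochondrial genes
    (``mt-*``, outside the gene models) carry ~5% of counts so the RNA QC
    covariates are realistic. Planted RNA QC violators (too few detected
    genes; mito percentage above 50) are appended with ``RNAV`` barcodes.
    """
    rng = np.random.default_rng(_subseed(config.seed, "rna"))
    type_names = config.cell_type_names()

    atac_cells = [bc for bc in sorted(truth.cell_types) if bc not in truth.qc_violators]
    suffix = "-rna" if config.unpaired_rna else ""
    barcodes = [bc + suffix for bc in atac_cells]
    ctype = [truth.cell_types[bc] for bc in atac_cells]

    gene_ids = [g.gene_id for g in truth.genes]
    mito_genes = [f"mt-gene{i}" for i in range(config.n_mito_genes)]
    all_genes = gene_ids + mito_genes
    n_g = len(all_genes)

    base_mu = rng.gamma(2.0, config.rna_nb_mean / 2.0, size=len(gene_ids))
    base_mu = np.maximum(base_mu, 0.05)
    mito_mu = np.full(
        config.n_mito_genes,
        0.05 / 0.95 * base_mu.sum() / max(config.n_mito_genes, 1),
    )
    mu0 = np.concatenate([base_mu, mito_mu])

    gene_pos = {g: i for i, g in enumerate(all_genes)}
    fc = 2.0 ** config.marker_log2_fold_change
    mu_by_type: dict[str, np.ndarray] = {}
    for ct in type_names:
        mu = mu0.copy()
        for gid in truth.marker_genes.get(ct, []):
            mu[gene_pos[gid]] *= fc
        mu_by_type[ct] = mu

    # planted RNA QC violators
    rna_violators: dict[str, str] = {}
    v = 0
    for rule in _RNA_RULES:
        for _ in range(config.n_qc_violators_per_rule):
            bc = f"RNAV{v:04d}"
            rna_violators[bc] = rule
            barcodes.append(bc)
            ctype.append(type_names[v % len(type_names)])
            v += 1

    r = config.rna_nb_dispersion
    size_factor = rng.lognormal(0.0, 0.2, size=len(barcodes))
    counts = np.zeros((len(barcodes), n_g), dtype=np.int64)
    for i, (bc, ct) in enumerate(zip(barcodes, ctype)):
        mu = mu_by_type[ct] * size_factor[i]
        rule = rna_violators.get(bc)
        if rule == "low_genes":
            mu = mu * 0.02
        elif rule == "high_mito_pct":
            mu = mu.copy()
            mu[len(gene_ids):] *= 40.0
        counts[i] = rng.negative_binomial(r, r / (r + mu))

    truth.rna_violators = rna_violators
    return RnaCounts(barcodes, all_genes, counts, mito_genes)


# ----------------------------------------------------------------------
# GWAS SNPs
# ----------------------------------------------------------------------

def simulate_gwas_snps(config: SimulationConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Place SNPs inside planted cell-type-specific peaks and outside all peaks.

    The in-peak count is ``round(snp_in_peak_fraction * n_snps)`` exactly
    (deterministic allocation). Returns a BED-like frame (chrom, start,
    end, name) and records placement in ``truth.snps``.
    """
    rng = np.random.default_rng(_subseed(config.seed, "snps"))
    n_in = int(round(config.snp_in_peak_fraction * config.n_snps))
    n_out = config.n_snps - n_in

    planted = truth.planted_peak_types()
    planted_idx = sorted(planted)
    rows = []
    if n_in and not planted_idx:
        raise ValueError("no planted peaks to host in-peak SNPs")
    pick = rng.choice(planted_idx, size=n_in, replace=True) if n_in else []
    for j, pi in enumerate(pick):
        p = truth.peaks[pi]
        pos = int(rng.integers(p.start, p.end))
        rows.append((f"snp{j:05d}", p.chrom, pos, True, int(pi), planted[int(pi)]))

    sampler = _allowed_window_sampler(config, truth.peaks, 1)
    chroms, starts = sampler(n_out, rng)
    for j, (c, s) in enumerate(zip(chroms, starts), start=n_in):
        rows.append((f"snp{j:05d}", c, int(s), False, -1, ""))

    truth.snps = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "in_peak", "peak_index", "cell_type"]
    )
    bed = pd.DataFrame(
        {
            "chrom": truth.snps["chrom"],
            "start": truth.snps["pos"],
            "end": truth.snps["pos"] + 1,
            "name": truth.snps["snp_id"],
        }
    )
    return bed


# ----------------------------------------------------------------------
# writers / readers
# ----------------------------------------------------------------------

def write_fragments(frags: pd.DataFrame, path: str | Path) -> None:
    """Write fragments in the 10x dialect (chrom, start, end, barcode, count).

    A ``.gz`` suffix triggers gzip compression.
    """
    path = Path(path)
    df = frags.copy()
    if "count" not in df.columns:
        df["count"] = 1
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a fragments TSV (4 or 5 columns, plain or gzip)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "barcode", "count"][: _ncols(path)],
    )
    return df[["chrom", "start", "end", "barcode"]]


def _ncols(path: str | Path) -> int:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.readline()
    return len(first.rstrip("\n").split("\t"))


def write_truth_bundle(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialize the truth (JSON; SNP table embedded as records)."""
    d = {
        "cell_types": truth.cell_types,
        "specific_peaks": {ct: sorted(v) for ct, v in truth.specific_peaks.items()},
        "marker_genes": truth.marker_genes,
        "links": [[g, i, ct] for g, i, ct in truth.links],
        "qc_violators": truth.qc_violators,
        "stage": truth.stage,
        "lineage": truth.lineage,
        "pseudotime": truth.pseudotime,
        "transition_events": None
        if truth.transition_events is None
        else {f"{u}->{v}": [a, b] for (u, v), (a, b) in truth.transition_events.items()},
        "snps": None if truth.snps is None else truth.snps.to_dict(orient="list"),
        "rna_violators": truth.rna_violators,
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, sort_keys=True)
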