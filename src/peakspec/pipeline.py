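"""End-to-end orchestration with deterministic seeding and a run manifest.

The pipeline simulates (or loads) a study, then runs QC -> matrices ->
RNA DE -> cell-type-specific DAP calling -> element stratification ->
CRE linking -> cross-modality concordance -> trajectory stage dynamics
-> GWAS SNP mapping, writing every tabular output plus a manifest of
parameter values and SHA-256 output digests. Re-running with the same
config and seed reproduces every output byte for byte; the manifest is
deliberately free of wall-clock information so manifests are identical
too.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import classify_peaks, element_class_counts, overlap_snps_with_peaks, write_snp_table
from .concordance import (
    argmax_match_rate,
    cluster_mean_zscores,
    concordance_matrix,
    write_concordance,
)
from .dap import call_cell_type_specific_peaks, write_dap_table
from .genes import write_gene_table
from .intervals import write_bed
from .links import link_daps_to_degs, write_links
from .matrices import (
    build_cell_bin_matrix,
    build_cell_peak_matrix,
    build_gene_activity_matrix,
    build_pseudobulk_profile,
    filter_bins,
    write_counts_mtx,
    write_matrix,
)
from .qc import (
    QcThresholds,
    compute_atac_qc,
    compute_rna_qc,
    filter_atac_cells,
    filter_rna_cells,
    qc_promoter_windows,
    write_qc_table,
)
from .rna import de_all_groups, normalize_rpm_log, select_hvg, write_de_table
from .simulate import (
    SimulationConfig,
    simulate_atac_fragments,
    simulate_gwas_snps,
    simulate_rna_counts,
    simulate_trajectory,
    write_fragments,
    write_truth_bundle,
)
from .trajectory import bin_cells_into_stages, stage_transition_daps


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the study's quoted constants."""

    out_dir: str = "peakspec_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    atac_bin_size: int = 5000
    pseudobulk_bin_size: int = 10000
    top_bin_fraction: float = 0.05
    promoter_upstream_stratification: int = 5000
    promoter_window_qc: int = 2000
    dap_alpha: float = 0.05
    de_min_pct: float = 0.25
    de_min_logfc: float = 0.25
    de_alpha: float = 0.05
    n_hvg: int = 3000
    cre_window: int = 100_000
    gene_activity_mode: str = "body_plus_upstream"
    gene_activity_upstream: int = 2000
    run_trajectory: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["genome"] = {
            "chromosomes": list(map(list, self.simulation.genome.chromosomes)),
            "mito": self.simulation.genome.mito,
            "sex": list(self.simulation.genome.sex),
        }
        sg = self.simulation.stage_graph
        d["simulation"]["stage_graph"] = None if sg is None else list(map(list, sg.edges))
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        from .intervals import GenomeLayout
        from .trajectory import StageGraph

        with open(path) as fh:
            d = json.load(fh)
        sim = d.pop("simulation", {})
        if "genome" in sim and isinstance(sim["genome"], dict):
            g = sim["genome"]
            sim["genome"] = GenomeLayout(
                tuple((c, int(l)) for c, l in g["chromosomes"]),
                mito=g.get("mito", "chrM"),
                sex=tuple(g.get("sex", ("chrX", "chrY"))),
            )
        if sim.get("stage_graph"):
            sim["stage_graph"] = StageGraph(tuple((u, v) for u, v in sim["stage_graph"]))
        thr = d.pop("thresholds", {})
        return cls(
            simulation=SimulationConfig(**sim),
            thresholds=QcThresholds(**thr),
            **d,
        )


def validate_config(config: PipelineConfig) -> list[str]:
    """Empty list iff all invariants hold; each violation names the field."""
    v: list[str] = []
    for name in ("atac_bin_size", "pseudobulk_bin_size", "n_hvg", "cre_window",
                 "promoter_upstream_stratification", "promoter_window_qc",
                 "gene_activity_upstream"):
        if getattr(config, name) <= 0:
            v.append(f"{name}: must be positive")
    for name in ("dap_alpha", "de_alpha"):
        a = getattr(config, name)
        if not (0 < a < 1):
            v.append(f"{name}: must lie in (0, 1)")
    if not (0 <= config.top_bin_fraction < 1):
        v.append("top_bin_fraction: must lie in [0, 1)")
    if not (0 <= config.de_min_pct <= 1):
        v.append("de_min_pct: must lie in [0, 1]")
    if config.gene_activity_mode not in ("transcript_overlap", "body_plus_upstream"):
        v.append("gene_activity_mode: unknown mode")
    try:
        dataclasses.replace(config.simulation, seed=config.seed)
    except ValueError as err:
        v.append(f"simulation: {err}")
    return v


@dataclass
class RunManifest:
    """Parameter snapshot plus SHA-256 digests of every written output."""

    parameters: dict
    outputs: dict[str, str]
    counts: dict[str, int]
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage end to end; returns the run manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    counts: dict[str, int] = {}

    # --- simulate -----------------------------------------------------
    frags, truth = simulate_atac_fragments(sim)
    rna = simulate_rna_counts(sim, truth)
    snp_bed = simulate_gwas_snps(sim, truth)
    write_fragments(frags, out / "fragments.tsv")
    write_bed(truth.peaks, out / "peaks.bed")
    write_bed(truth.blacklist, out / "blacklist.bed")
    write_gene_table(truth.genes, out / "genes.tsv")
    write_counts_mtx(rna.counts, rna.barcodes, rna.gene_ids, out / "rna_counts")
    snp_bed.to_csv(out / "snps.bed", sep="\t", header=False, index=False)
    write_truth_bundle(truth, out / "truth.json")
    counts["fragments"] = len(frags)
    counts["peaks"] = len(truth.peaks)

    # --- QC -----------------------------------------------------------
    promoters = qc_promoter_windows(
        truth.genes, upstream=config.promoter_window_qc, downstream=config.promoter_window_qc
    )
    qc = compute_atac_qc(frags, promoters, sim.genome)
    write_qc_table(qc, out / "atac_qc.tsv", config.thresholds)
    kept = set(filter_atac_cells(qc, config.thresholds))
    counts["atac_cells_kept"] = len(kept)
    frags_kept = frags[frags["barcode"].isin(kept)].reset_index(drop=True)

    rna_qc = compute_rna_qc(rna.counts, rna.barcodes, rna.gene_ids)
    write_qc_table(rna_qc, out / "rna_qc.tsv", config.thresholds)
    rna_kept = filter_rna_cells(rna_qc, config.thresholds)
    counts["rna_cells_kept"] = len(rna_kept)

    # --- matrices -----------------------------------------------------
    bin_matrix = filter_bins(
        build_cell_bin_matrix(frags_kept, sim.genome, config.atac_bin_size),
        top_fraction=config.top_bin_fraction,
        blacklist=truth.blacklist,
    )
    counts["bins_kept"] = len(bin_matrix.features)
    peak_matrix = build_cell_peak_matrix(frags_kept, truth.peaks)
    write_matrix(peak_matrix, out / "cell_peak")
    activity = build_gene_activity_matrix(
        frags_kept, truth.genes, mode=config.gene_activity_mode,
        upstream=config.gene_activity_upstream,
    )
    pseudobulk = build_pseudobulk_profile(frags_kept, sim.genome, config.pseudobulk_bin_size)
    counts["pseudobulk_bins"] = len(pseudobulk.bins)

    # --- RNA DE -------------------------------------------------------
    rna_df = pd.DataFrame(rna.counts, index=rna.barcodes, columns=rna.gene_ids)
    rna_df = rna_df.loc[rna_kept]
    norm = normalize_rpm_log(rna_df)
    rna_labels = pd.Series(
        {bc: truth.cell_types[bc.removesuffix("-rna")] for bc in rna_kept}
    )
    de = de_all_groups(
        norm, rna_labels, min_pct=config.de_min_pct,
        min_logfc=config.de_min_logfc, alpha=config.de_alpha,
    )
    write_de_table(de, out / "deg.tsv")
    counts["degs"] = int(de["significant"].sum())

    # --- DAP calling --------------------------------------------------
    atac_labels = {bc: truth.cell_types[bc] for bc in peak_matrix.barcodes}
    daps = call_cell_type_specific_peaks(peak_matrix, atac_labels, alpha=config.dap_alpha)
    write_dap_table(daps, out / "daps.tsv")
    counts["daps"] = sum(len(daps.specific_peaks(ct)) for ct in daps.cell_types)

    # --- element stratification ---------------------------------------
    classes = classify_peaks(
        truth.peaks, truth.genes, promoter_upstream=config.promoter_upstream_stratification
    )
    pd.DataFrame(
        {
            "chrom": [p.chrom for p in truth.peaks],
            "start": [p.start for p in truth.peaks],
            "end": [p.end for p in truth.peaks],
            "element_class": classes,
        }
    ).to_csv(out / "peak_elements.tsv", sep="\t", index=False)
    counts.update({f"class_{k}": int(n) for k, n in element_class_counts(classes).items()})

    # --- CRE links ----------------------------------------------------
    # cell-type-specific genes are the up-regulated significant ones;
    # mitochondrial transcripts carry no genomic model and cannot be linked
    model_ids = {g.gene_id for g in truth.genes}
    de_sig = de[de["significant"] & (de["logfc"] > 0) & de["gene"].isin(model_ids)]
    links = link_daps_to_degs(daps, de_sig, truth.genes, window=config.cre_window)
    write_links(links, out / "cre_links.tsv")
    counts["cre_links"] = len(links)

    # --- concordance --------------------------------------------------
    act_df = activity.to_frame()
    act_df = act_df[act_df.sum(axis=1) > 0]
    act_norm = normalize_rpm_log(act_df)
    act_labels = pd.Series({bc: truth.cell_types[bc] for bc in act_df.index})
    rna_prof = cluster_mean_zscores(norm, rna_labels)
    act_prof = cluster_mean_zscores(act_norm, act_labels)
    hvg = select_hvg(norm, n=config.n_hvg)
    conc = concordance_matrix(rna_prof, act_prof, hvg)
    write_concordance(conc, out / "concordance.tsv")
    counts["concordance_argmax_hits"] = int(round(argmax_match_rate(conc) * len(conc)))

    # --- trajectory stage dynamics ------------------------------------
    if config.run_trajectory:
        traj = simulate_trajectory(sim)
        traj_frags, traj_truth = simulate_atac_fragments(sim, trajectory=traj)
        traj_matrix = build_cell_peak_matrix(traj_frags, traj_truth.peaks)
        assignment = bin_cells_into_stages(
            traj.pseudotime, traj.lineage, traj.graph
        )
        transitions = stage_transition_daps(traj_matrix, assignment, traj.graph,
                                            alpha=config.dap_alpha)
        rows = []
        for t in transitions:
            for direction, idxs in (("opened", t.opened), ("closed", t.closed)):
                for i in idxs:
                    pk = traj_truth.peaks[i]
                    rows.append(
                        {
                            "ancestor": t.edge[0],
                            "descendant": t.edge[1],
                            "direction": direction,
                            "chrom": pk.chrom,
                            "start": pk.start,
                            "end": pk.end,
                            "peak_index": i,
                        }
                    )
        pd.DataFrame(rows).to_csv(out / "stage_transitions.tsv", sep="\t", index=False)
        counts["stage_transition_daps"] = len(rows)

    # --- GWAS SNP mapping ---------------------------------------------
    snp_table = overlap_snps_with_peaks(snp_bed, truth.peaks, daps, truth.genes)
    write_snp_table(snp_table, out / "snp_overlap.tsv")
    counts["snps_in_peaks"] = int((snp_table["n_overlapping_peaks"] > 0).sum())

    outputs = {
        p.name: _digest(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(parameters=config.to_dict(), outputs=outputs, counts=counts)
    manifest.to_json(out / "manifest.json")
    return manifest
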