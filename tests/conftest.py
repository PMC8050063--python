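"""Shared fixtures: one synthetic study, reused across test modules."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from peakspec.simulate import (
    SimulationConfig,
    simulate_atac_fragments,
    simulate_gwas_snps,
    simulate_rna_counts,
)
from peakspec.qc import (
    compute_atac_qc,
    compute_rna_qc,
    filter_atac_cells,
    filter_rna_cells,
    qc_promoter_windows,
)
from peakspec.matrices import build_cell_peak_matrix, build_gene_activity_matrix
from peakspec.dap import call_cell_type_specific_peaks
from peakspec.rna import de_all_groups, normalize_rpm_log


@pytest.fixture(scope="session")
def study():
    """One fully processed synthetic study (seed 1): fragments through DAPs."""
    cfg = SimulationConfig(seed=1)
    frags, truth = simulate_atac_fragments(cfg)
    promoters = qc_promoter_windows(truth.genes)
    qc = compute_atac_qc(frags, promoters, cfg.genome)
    kept = set(filter_atac_cells(qc))
    frags_kept = frags[frags["barcode"].isin(kept)].reset_index(drop=True)
    peak_matrix = build_cell_peak_matrix(frags_kept, truth.peaks)
    labels = {bc: truth.cell_types[bc] for bc in peak_matrix.barcodes}
    daps = call_cell_type_specific_peaks(peak_matrix, labels)
    snps = simulate_gwas_snps(cfg, truth)
    return SimpleNamespace(
        cfg=cfg,
        frags=frags,
        truth=truth,
        promoters=promoters,
        qc=qc,
        kept=kept,
        frags_kept=frags_kept,
        peak_matrix=peak_matrix,
        labels=labels,
        daps=daps,
        snps=snps,
    )


@pytest.fixture(scope="session")
def rna_study(study):
    """RNA side of the same study: counts, QC, normalization, DE tables."""
    cfg, truth = study.cfg, study.truth
    rna = simulate_rna_counts(cfg, truth)
    rqc = compute_rna_qc(rna.counts, rna.barcodes, rna.gene_ids)
    kept = filter_rna_cells(rqc)
    norm = normalize_rpm_log(rna.to_frame().loc[kept])
    labels = pd.Series({bc: truth.cell_types[bc] for bc in kept})
    de = de_all_groups(norm, labels)
    return SimpleNamespace(rna=rna, rqc=rqc, kept=kept, norm=norm, labels=labels, de=de)


@pytest.fixture(scope="session")
def activity_study(study):
    """Gene activity matrix of the QC-passing cells."""
    act = build_gene_activity_matrix(
        study.frags_kept, study.truth.genes, mode="body_plus_upstream"
    )
    adf = act.to_frame()
    adf = adf[adf.sum(axis=1) > 0]
    labels = pd.Series({bc: study.truth.cell_types[bc] for bc in adf.index})
    return SimpleNamespace(activity=act, frame=adf, labels=labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
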