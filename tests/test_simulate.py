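"""Synthetic-study generator: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from peakspec.intervals import GenomicInterval
from peakspec.simulate import (
    SimulationConfig,
    read_fragments,
    simulate_atac_fragments,
    simulate_gwas_snps,
    simulate_rna_counts,
    simulate_trajectory,
    write_fragments,
)

SMALL = dict(
    n_cell_types=3,
    n_cells_per_type=40,
    n_peaks=200,
    n_specific_peaks_per_type=20,
    n_genes=60,
    n_marker_genes_per_type=5,
    background_fragments_per_cell=1500,
    n_qc_violators_per_rule=2,
    n_snps=40,
)


class TestConfigValidation:
    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError, match="p0"):
            SimulationConfig(p0=0.5, p1=0.2)

    def test_overcommitted_specific_peaks_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_peaks=10, n_cell_types=5, n_specific_peaks_per_type=10)

    def test_marker_needs_coupled_peak(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_marker_genes_per_type=60, n_specific_peaks_per_type=50)


class TestAtacFragments:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=5, **SMALL)
        f1, _ = simulate_atac_fragments(cfg)
        f2, _ = simulate_atac_fragments(cfg)
        write_fragments(f1, tmp_path / "a.tsv")
        write_fragments(f2, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        back = read_fragments(tmp_path / "a.tsv")
        assert len(back) == len(f1)

    def test_truth_bookkeeping(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        _, truth = simulate_atac_fragments(cfg)
        planted = truth.planted_peak_types()
        assert len(planted) == cfg.n_cell_types * cfg.n_specific_peaks_per_type
        for ct, idxs in truth.specific_peaks.items():
            assert len(idxs) == cfg.n_specific_peaks_per_type
        # each planted specific peak belongs to exactly one type
        all_sets = list(truth.specific_peaks.values())
        for i, a in enumerate(all_sets):
            for b in all_sets[i + 1:]:
                assert not (a & b)

    def test_fragment_records_valid(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        frags, truth = simulate_atac_fragments(cfg)
        lengths = cfg.genome.lengths
        assert (frags["start"] >= 0).all()
        ends_ok = frags.groupby("chrom", observed=True)["end"].max()
        for chrom, mx in ends_ok.items():
            assert mx <= lengths[chrom]
        assert (frags["end"] - frags["start"] == cfg.fragment_length).all()

    def test_planted_access_rate_in_binomial_interval(self):
        """With p1 = 0.8, the fraction of target-type cells showing >= 1
        fragment in a planted peak lies in the exact binomial 99%
        interval around 0.8."""
        cfg = SimulationConfig(seed=11, p1=0.8, **{**SMALL, "n_cells_per_type": 200})
        frags, truth = simulate_atac_fragments(cfg)
        ct = cfg.cell_type_names()[0]
        peak_idx = sorted(truth.specific_peaks[ct])[0]
        peak = truth.peaks[peak_idx]
        target = [
            bc for bc, t in truth.cell_types.items()
            if t == ct and bc not in truth.qc_violators
        ]
        sub = frags[
            (frags["chrom"] == peak.chrom)
            & (frags["start"] < peak.end)
            & (frags["end"] > peak.start)
        ]
        with_hit = set(sub["barcode"]) & set(target)
        n = len(target)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.8)
        assert lo <= len(with_hit) <= hi

    def test_background_fragments_avoid_peaks(self):
        """Fragments outside planted accessibility land outside every peak:
        off-target peak hits come only from the Bernoulli channel at p0."""
        cfg = SimulationConfig(seed=3, p0=0.0, p1=1.0, **SMALL)
        frags, truth = simulate_atac_fragments(cfg)
        # with p0 = 0, any fragment overlapping a peak must belong to a cell
        # whose type has that peak planted
        planted = truth.planted_peak_types()
        for pk_i, ct in list(planted.items())[:20]:
            pk = truth.peaks[pk_i]
            sub = frags[
                (frags["chrom"] == pk.chrom)
                & (frags["start"] < pk.end)
                & (frags["end"] > pk.start)
            ]
            cell_types = {truth.cell_types[bc] for bc in sub["barcode"]}
            assert cell_types <= {ct}


class TestRnaCounts:
    def test_counts_are_non_negative_integers(self, rna_study):
        counts = rna_study.rna.counts
        assert counts.dtype.kind == "i" and (counts >= 0).all()

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        _, truth = simulate_atac_fragments(cfg)
        a = simulate_rna_counts(cfg, truth)
        b = simulate_rna_counts(cfg, truth)
        assert np.array_equal(a.counts, b.counts)

    def test_marker_fold_change_matches_configured(self):
        """Mean empirical log2 FC of planted markers within +/-0.2 of the
        configured value, averaged over 10 seeds at 200 cells/type."""
        lfcs = []
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed, **{**SMALL, "n_cells_per_type": 200}
            )
            _, truth = simulate_atac_fragments(cfg)
            rna = simulate_rna_counts(cfg, truth)
            df = rna.to_frame()
            clean = [bc for bc in df.index if not bc.startswith("RNAV")]
            df = df.loc[clean]
            types = pd.Series({bc: truth.cell_types[bc] for bc in clean})
            ct = cfg.cell_type_names()[0]
            for g in truth.marker_genes[ct][:3]:
                m_in = df.loc[types == ct, g].mean()
                m_out = df.loc[types != ct, g].mean()
                lfcs.append(np.log2(m_in / m_out))
        assert abs(np.mean(lfcs) - SimulationConfig().marker_log2_fold_change) <= 0.2


class TestTrajectory:
    def test_stages_respect_graph(self):
        cfg = SimulationConfig(seed=4, n_cells_per_stage=20, **SMALL)
        traj = simulate_trajectory(cfg)
        root = traj.graph.root
        reachable = traj.graph.subtree(root)
        assert set(traj.stage.values()) <= reachable
        assert len(traj.graph.nodes()) == 15

    def test_pseudotime_increases_along_edges(self):
        cfg = SimulationConfig(seed=4, n_cells_per_stage=30, **SMALL)
        traj = simulate_trajectory(cfg)
        pt = pd.Series(traj.pseudotime)
        st = pd.Series(traj.stage)
        means = pt.groupby(st).mean()
        for u, v in traj.graph.edges:
            assert means[v] > means[u]

    def test_event_split_counts(self):
        cfg = SimulationConfig(seed=4, n_transition_peaks_per_edge=10, **SMALL)
        traj = simulate_trajectory(cfg)
        for opened, closed in traj.events.values():
            assert len(opened) == 5 and len(closed) == 5
            assert not (set(opened) & set(closed))

    def test_cyclic_graph_rejected(self):
        from peakspec.trajectory import StageGraph

        bad = StageGraph((("A", "B"), ("B", "C"), ("C", "A")))
        with pytest.raises(ValueError):
            bad.validate()


class TestGwasSnps:
    def test_positions_within_bounds_and_exact_fraction(self):
        cfg = SimulationConfig(seed=6, **SMALL)
        _, truth = simulate_atac_fragments(cfg)
        bed = simulate_gwas_snps(cfg, truth)
        lengths = cfg.genome.lengths
        for _, r in bed.iterrows():
            assert 0 <= r["start"] < lengths[r["chrom"]]
        n_in = int(truth.snps["in_peak"].sum())
        assert n_in == round(cfg.snp_in_peak_fraction * cfg.n_snps)

    def test_in_peak_flags_verified_by_interval_scan(self):
        """Truth flags agree with a brute-force half-open interval scan."""
        cfg = SimulationConfig(seed=6, **SMALL)
        _, truth = simulate_atac_fragments(cfg)
        simulate_gwas_snps(cfg, truth)
        for _, s in truth.snps.iterrows():
            inside = any(
                p.chrom == s["chrom"] and p.start <= s["pos"] < p.end
                for p in truth.peaks
            )
            assert inside == s["in_peak"]
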