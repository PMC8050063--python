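# peakspec

Cell-type-specific chromatin accessibility analysis for single-nucleus
ATAC-seq with paired single-cell RNA-seq — the computational core of a
single-cell regulatory-landscape study of a complex tissue such as the
developing kidney.

Single-nucleus ATAC fragments mark open chromatin per cell, but the
signal is near-binary and sparse: the natural unit is whether a cell
shows *any* fragment in a region. `peakspec` implements the analysis
stack built on that observation:

- per-cell quality control (unique fragments, promoter ratio,
  mitochondrial ratio) and the corresponding scRNA filters;
- binarized cell-by-bin (5 kb) and cell-by-peak matrices, gene activity
  scores, and 10 kb pseudobulk profiles;
- **cell-type-specific peak calling**, the package's core statistic;
- genomic element stratification of peaks
  (exon > 5′-UTR > 3′-UTR > intron > promoter > distal);
- Wilcoxon rank-sum differential expression with detection and
  fold-change prefilters;
- proximity-based cis-regulatory element (CRE) prediction linking
  cell-type-specific peaks to cell-type-specific genes;
- ATAC/RNA concordance via z-scored cluster profiles, and
  pseudobulk-vs-bulk rank correlation;
- pseudotime stage binning along a branching differentiation tree with
  stage-to-stage chromatin opening/closing calls;
- GWAS variant-to-peak overlap with cell-type attribution and nearest
  genes.

A first-class synthetic study generator plants cell-type-specific
peaks, coupled marker genes, trajectory transition events and in-peak
SNPs, and records the ground truth, so every stage is testable at desk
scale without external downloads.

## The core statistic

For peak $j$ and focal cell type $t$, let $a$ be the number of type-$t$
cells with the peak accessible (at least one overlapping fragment) and
$b$ the number without; $c, d$ the same counts in a comparison type
$u$. The one-sided Fisher p-value is the upper hypergeometric tail

$$p_{j,t,u} = P(X \ge a), \quad X \sim \mathrm{Hypergeom}(N = a+b+c+d,\; K = a+c,\; n = a+b),$$

testing enrichment of accessibility in the focal type. P-values are
Benjamini–Hochberg adjusted per $(t, u)$ comparison family across all
peaks, and peak $j$ is **specific to $t$** only if the adjusted p-value
is below $\alpha = 0.05$ against *every* other type. Because a peak
cannot be simultaneously enriched in two types under one-sided tests,
the rule assigns each peak to at most one type — asserted on every run.

The same directional machinery, applied between a trajectory stage and
its ancestor, classifies peaks as *opening* (descendant-enriched) or
*closing* (ancestor-enriched) along differentiation.

## Worked example

```python
from peakspec.dap import call_cell_type_specific_peaks
from peakspec.matrices import build_cell_peak_matrix
from peakspec.qc import compute_atac_qc, filter_atac_cells, qc_promoter_windows
from peakspec.simulate import SimulationConfig, simulate_atac_fragments

config = SimulationConfig(seed=42)          # 5 types x 200 cells, 1000 peaks
fragments, truth = simulate_atac_fragments(config)
qc = compute_atac_qc(fragments, qc_promoter_windows(truth.genes), config.genome)
kept = set(filter_atac_cells(qc))
fragments = fragments[fragments["barcode"].isin(kept)]
matrix = build_cell_peak_matrix(fragments, truth.peaks)
labels = {bc: truth.cell_types[bc] for bc in matrix.barcodes}
result = call_cell_type_specific_peaks(matrix, labels, alpha=0.05)
```

Running `python examples/02_qc_and_specific_peaks.py` (which wraps the
snippet) prints:

```
QC: kept 1000/1020 cells (fragment count in [1000, 40000], mito < 10%, promoter ratio >= 20%)
  DCT: 50 specific peaks
  LOH: 50 specific peaks
  NP: 50 specific peaks
  PT: 50 specific peaks
  Podo: 50 specific peaks
recovered 250/250 planted peaks; 0 false assignments
```

The 20 removed cells are exactly the planted QC violators; each cell
type recovers its 50 planted specific peaks with no false assignment.
The other scripts in `examples/` walk through CRE linking, trajectory
dynamics, concordance and GWAS overlap the same way, and
`peakspec run-all --seed 7 --out run/` executes the whole pipeline from
a shell, writing every table plus a manifest of output digests.

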