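# Methods

This note documents the models, conventions and numerical choices
behind `peakspec`, and what the synthetic study does and does not
emulate.

## Coordinates and intervals

All internal coordinates are 0-based half-open `[start, end)` (BED
convention); GTF-style 1-based inclusive gene models are converted at
the reader boundary. Overlap is strict half-open intersection, so
book-ended intervals do not overlap, while `merge_intervals` *does*
merge book-ended intervals (gap 0) — matching the behaviour of the
interval-reduction routines used to build merged peak universes, and
the convention under which a fragment ending exactly at a peak start
does not count toward the peak. Nearest-feature queries anchor genes at
the strand-aware TSS; ties break deterministically by smaller start
coordinate, then lexicographic name.

## Quality control

ATAC cells are kept when the unique-fragment count (deduplicated on
chrom/start/end/barcode) lies in [1000, 40000] inclusive, the fraction
of fragments on the mitochondrial chromosome is strictly below 0.10,
and the fraction overlapping promoter windows is at least 0.20. The
promoter set for this covariate is TSS ± 2 kb per gene (merged); the
element-stratification module uses its own, separate 5 kb
upstream-only promoter definition. Ratio denominators use all unique
fragments of the barcode. RNA cells are kept with 200–3000 detected
genes inclusive and a mitochondrial count percentage of at most 50; the
exclusion bounds are strict, so a cell at exactly 3000 genes or exactly
50% mito is kept. Boundary conventions follow a literal reading of the
stated thresholds and are configurable through `QcThresholds`.

## Matrices

Fragment-to-feature assignment is by any-overlap of the full fragment
interval (not midpoint or cut site); a fragment spanning a bin boundary
therefore contributes to both bins, and a fragment may count toward
several overlapping gene windows. Cell-by-bin (default 5 kb) and
cell-by-peak matrices are binarized: an entry is 1 when the cell has at
least one overlapping fragment. Mitochondrial and unknown-chromosome
fragments are dropped before binning. Bin filtering removes exactly
`floor(0.05 · n_bins)` bins with the largest column sums — ties at the
cutoff broken by genomic order, for determinism — plus every bin
overlapping a blacklist interval; rows are never removed. Gene activity
is the per-cell fragment count over the transcript span
(`transcript_overlap`) or the span extended 2 kb upstream of the
strand-aware TSS (`body_plus_upstream`). Pseudobulk profiles aggregate
all cells' fragments into 10 kb bins, excluding sex and mitochondrial
chromosomes. Matrices are scipy CSR; on disk they are MatrixMarket with
barcode and feature-BED sidecars.

## Differentially accessible peaks

The 2×2 table per (peak, focal type, other type) counts *cells*, never
fragment multiplicities, because the matrices are binarized. The
one-sided enrichment p-value is the upper hypergeometric tail
`P(X ≥ a)` computed via `scipy.stats.hypergeom.sf` (the all-zero table
returns 1 by convention). Sidedness is a modelling choice: the stated
goal is peaks open in exactly one type, which the one-sided rule
encodes and which guarantees a peak is assigned to at most one type;
a two-sided variant would allow depletion to count as significance and
lose that uniqueness. BH adjustment is applied per (focal, other)
comparison family across all peaks — the convention of peak-level FDR
control within one comparison; global pooling across families would
couple unrelated comparisons. Reported DAP tables order rows by focal
type, ascending maximum adjusted p, then genomic position.

## RNA normalization, DE and HVGs

Normalization is reads-per-million followed by natural-log with
pseudo-count 1 (`log(1 + 10⁶ · c / total)`); the per-10k variant is a
parameter. Differential expression screens each gene with two
prefilters — detected (> 0) in at least 25% of one of the two groups,
and |logFC| ≥ 0.25 where logFC is `log(mean(expm1(x)) + 1)` per group,
differenced (the convention of the standard single-cell toolchains) —
then applies a two-sided Wilcoxon rank-sum test (exact distribution
when min(m, n) ≤ 10 and tie-free, otherwise the normal approximation
with continuity and tie correction, both via
`scipy.stats.mannwhitneyu`), and BH correction across tested genes
only. The DE table is two-sided; where "cell-type-specific genes" are
needed (CRE linking, marker recovery) the up-regulated significant rows
are used, since a depleted gene is specific to some *other* type.

Highly variable genes are ranked by mean-binned normalized dispersion:
variance/mean on the de-logged scale, z-scored within mean-quantile
bins (20 by default, fewer on small panels). The within-bin SD is
floored at a tenth of the global dispersion spread so nearly-constant
bins cannot promote noise genes. Plain log-scale variance is *not*
used: it ranks high-baseline genes first regardless of biological
variability.

## Element stratification, CRE links, GWAS overlap

Peaks receive exactly one element class under the priority
exon > 5′-UTR > 3′-UTR > intron > promoter > distal, pooling overlaps
across all genes. Promoters are strand-aware 5 kb upstream of the TSS
with no downstream extension; introns are transcript span minus the
exon union (single-exon genes contribute none). CRE links require
(1) peak and gene specific to the same cell type, (2) the peak's
*nearer edge* within ±100 kb of the TSS (any part of the peak inside
the window qualifies — edge-vs-midpoint being a free choice, the
inclusive reading was taken), and (3) the single TSS base not inside
the half-open peak interval. SNPs arrive as single-base BED records
(post-liftover, performed upstream); overlap is the half-open
point-in-interval test, cell types are attributed only through
DAP-specific peaks, and every SNP is annotated with its nearest gene by
|position − TSS| with the sign negative upstream in the gene's
orientation.

## Concordance

Cluster profiles are per-cluster means of normalized values, z-scored
per gene across clusters. The z-score uses the sample-SD convention
(ddof = 1; two clusters with means 2 and 4 give ∓0.707), with the
population convention behind a flag. Constant genes map to zero
columns. The concordance matrix is all pairwise Pearson correlations of
RNA-cluster versus ATAC-cluster profiles over the HVG set intersected
with both matrices (at least 3 shared genes). Pseudobulk similarity is
Spearman by default (average ranks for ties), Pearson optionally, over
identical bin universes only.

## Trajectory stage analysis

Pseudotime and lineage labels are inputs (from an external trajectory
tool or the generator); graph learning is out of scope. The default
stage tree is the 15-stage nephron graph: NP0→NP1→NP2→NP3 (nephron
progenitors), NP3→Podo1→Podo2→Podo3 (podocytes), NP3→IM1→IM2
(intermediate), IM2→PT1→PT2→PT3 (proximal tubule), IM2→LOH1→LOH2→DCT
(loop of Henle and distal tubule). Within each lineage segment, cells
are ranked by pseudotime and cut into equal-count stages (sizes differ
by at most one cell); boundaries are reported so alternative binning
rules can be compared. Each edge is tested in both directions with the
one-sided Fisher machinery and BH per direction across peaks — two
directional screens rather than one two-sided test, for consistency
with the specificity caller and explicit directional FDR. The root
yields no record; branch-vs-branch comparisons pool each branch's
cells and run the same bidirectional screen.

## The synthetic study

The generator emulates the statistical structure the analysis assumes,
at desk scale, with full determinism per seed (fragment files are
byte-identical across reruns).

**Genome and annotation.** Five 20 Mb autosomes plus scaled-down chrX,
chrY and chrM (16,299 bp). 300 genes (10 kb, three exons, terminal
UTRs, random strand) are spaced along the autosomes; 1000 peaks of
500 bp comprise one peak planted inside each marker gene's body 3 kb
downstream of the TSS (so it is linkable but does not cover the TSS and
stays clear of the ±2 kb QC promoter window) and intergenic peaks
placed clear of gene territories, each other, and the blacklist.

**Accessibility.** Five cell types × 200 cells; 50 planted specific
peaks per type (10 of them marker-coupled). A peak planted for a cell's
type (or open in its trajectory stage) emits fragments with probability
p1 = 0.6, any other peak with p0 = 0.05; an accessible (cell, peak)
pair emits 1 + Poisson(0.7) fragments inside the peak. Per-cell totals
are log-normal around 1500 (clipped into the QC-passing window), with
2% mitochondrial and 30% promoter-window fragments injected to realise
the QC covariates, and the remaining background placed uniformly
*outside all peaks* so off-target peak signal comes only from the
Bernoulli channel. Five violator cells per QC rule (low/high fragment
count, high mito, low promoter ratio) are appended so the filters have
exact planted targets.

**RNA.** Negative-binomial counts (per-gene Gamma-distributed baseline
means around 6, dispersion r = 2, log-normal cell size factors); each
type's 10 marker genes are scaled by 2² (log2FC = 2) in that type. Ten
mitochondrial genes carry ~5% of counts. The NB mean is chosen so that
normal cells comfortably clear the 200-detected-genes floor on a
300-gene panel; violators (near-zero expression; 40× mito load) are
planted per rule. ATAC and RNA barcodes pair 1:1 by default; an
`unpaired_rna` switch suffixes RNA barcodes to mimic unpaired
modalities.

**Trajectory.** Cells (150 per stage) get uniform pseudotime within
their stage's depth band, so pseudotime increases in expectation along
every edge. Each of the 14 edges carries 10 transition peaks (5
opening: p0 outside the descendant subtree, p1 inside; 5 closing: the
reverse), drawn from the non-coupled peak pool; by tree structure, a
planted event changes accessibility across its own edge only.

**SNPs.** `round(0.5 · 200)` SNPs uniform inside planted specific
peaks, the rest uniform outside all peaks — the in-peak fraction is
exact by construction.

**What passing does not show.** The generator omits doublets, ambient
RNA, batch effects, sequence-dependent bias, fragment-length structure,
LD between SNPs and overlapping gene models. Recovery at the planted
effect sizes (p0 = 0.05 → p1 = 0.6; log2FC = 2) demonstrates the
machinery is correct and calibrated, not that real tissues with subtler
differences would be recovered at the same rates.

## Scale choices

Test and acceptance runs use the reference design (5 × 200 cells, 1000
peaks), ten seeds for recovery/concordance checks, five for the stage
trajectory, and a panel-scaled HVG count of 60 (a fifth of the 300-gene
panel, mirroring the selectivity of a top-3000 choice on a ~20k-gene
transcriptome). The exhaustive Fisher check enumerates every 2×2 table
with N ≤ 30 against explicit tail summation.

## Pipeline and manifest

`run_pipeline` executes simulate → QC → matrices → DE → DAP →
stratification → links → concordance → trajectory stages → GWAS,
writing TSV/BED/MTX outputs plus a manifest containing the full
parameter snapshot and SHA-256 digests of every output. The manifest
deliberately records no wall-clock information, so identical
config + seed reproduces identical outputs *and* an identical manifest.
The flat cell-type scenario and the trajectory scenario are simulated
separately (the stage analysis runs on its own cells), both derived
deterministically from the one seed.

## Known limitations

- Peak calling itself (e.g. from pileups) is out of scope; peaks are
  inputs, as are cluster labels, pseudotime and lineage assignments.
- The Fisher screen treats cells as exchangeable within a type; it does
  not model per-cell depth covariates beyond binarization.
- `classify_peaks` assumes one transcript model per gene; alternative
  isoforms should be collapsed upstream.
- The GTF reader handles the minimal feature set
  (transcript/gene, exon, UTRs) — not full GFF3 semantics.
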