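# Methods

`lesionmap` re-implements, as a tested and reusable pipeline, the
bespoke computations of a single-cell + spatial transcriptomics analysis
of prostate lesion progression (benign hyperplasia → adenocarcinoma):
threshold quality control, Wilcoxon marker detection and rule-based
cluster annotation, control-bin gene-set module scoring (M1/M2
macrophage polarization, lesion-state signatures), expression-inferred
copy-number profiling with reference Z-score event calling and a
shared/unique partition between hyperplastic and malignant cells, a
Ward.D2 CNV lineage tree, signature-based spot deconvolution, and a
spot-level transformation-pathway/stage map. Everything is exercised on
synthetic data with planted ground truth; no sequencing data are
downloaded or required.

## Quality control

Metrics per column (cell or spot): total UMI, detected genes,
log10(genes)/log10(UMI), mitochondrial and hemoglobin UMI percentages.
Three built-in threshold profiles are implemented with the printed
inequality directions taken literally (strict where written strict):

| profile | removal rules |
|---|---|
| `internal_cell` | n_gene < 200, n_umi < 1000, log10 genes-per-UMI < 0.7, mito% > 10, HB% > 5 |
| `spatial_spot` | n_umi < 1000 or > 50,000, n_gene < 500, mito% > 15 |
| `geo_cell` | n_gene ≤ 200 or ≥ 6000, n_umi ≥ 50,000, mito% > 15 |

The `geo_cell` lower gene bound is ambiguous in its source description
("nFeature > 200" as a keep-rule); we remove at ≤ 200 and expose the
rule table so either convention is one line of config away. A
sample-level check flags (never errors) matrices whose overall
mitochondrial fraction exceeds 25%. Doublet detection is out of scope;
the generator can flag planted artefacts instead.

Because the synthetic gene universe is ~2,000 genes rather than a full
transcriptome, the detected-gene and genes-per-UMI thresholds are only
meaningful at `desk` scale; the `tiny` smoke fixture uses proportionally
scaled bounds (`fixture_cell_profile` / `fixture_spot_profile`). This is
a property of the fixtures, not of the QC operators, which always apply
whatever profile they are given.

## Marker detection and annotation

Normalisation is `ln(1 + 10,000·count/column_total)`. Marker detection
is a one-vs-rest two-sided Wilcoxon rank-sum per gene. Whenever both
groups have ≤ 8 observations the exact permutation distribution of the
rank-sum statistic is built by a generating-function dynamic program
over the pooled midranks (ties exact by construction), with two-sided
p = min(1, 2·min(lower tail, upper tail)); larger groups use the
tie-corrected normal approximation without continuity correction.
Log2 fold changes are computed on the linear (expm1) scale with a 1e-9
pseudocount; BH correction is applied within each group. Screening
modes: `marker` (upregulated, log2FC ≥ 0.25, expressed in ≥ 25% of
in-group cells — the deconvolution-signature screen) and `state`
(p < 0.05, log2FC > 1.5 — the lesion-state screen). Top-n signatures
order by descending log2FC, then ascending p, then gene id, so results
are reproducible under ties.

Cluster annotation assigns type *t* when at least three of *t*'s markers
are each detected in more than 50% of the cluster's cells **and** have
mean normalised expression ≥ 1. The source rule prints "< 1", which
would reward absent markers; we treat that as a typo and default to
≥ 1, with `high_expression=False` restoring the literal reading. Ties
between qualifying types give "ambiguous"; none gives "unassigned".

Module scores follow the control-bin scheme: genes are ranked by mean
expression and cut into 25 equal-frequency bins; each set gene draws 100
control genes uniformly from its bin (set genes excluded; with
replacement if the pool is small); score = mean(set) − mean(controls).
Sampling is seeded and iterates set genes in canonical row order, so
scores are invariant to how the gene set is listed.

## Expression-inferred CNV

Profile: order genes by (chromosome, start); centre each gene on the
reference-cell mean; smooth within each chromosome by a centred moving
average truncated at the ends; re-centre each cell by its median
smoothed value (this absorbs the genome-wide normalisation shift a large
amplification induces). An HMM denoising step used by external tools is
deliberately not reproduced — the calling statistic below is defined
directly on the smoothed profile.

Calling: per gene, μ and σ from the reference cells' smoothed values
(σ floored at 0.01); a gene is amplified in a target group when strictly
more than 50% of its cells have Z > +1, deleted when strictly more than
50% have Z < −1. Strict majorities make the two call sets provably
disjoint. Shared events between the hyperplastic and malignant groups
are the same-direction intersection; genes called in opposite directions
are flagged discordant and counted unique to each group. The lineage
tree applies Ward.D2 (scipy `ward`, equivalent to R `hclust(d,
"ward.D2")` on Euclidean distances) to per-subcluster mean profiles and
is exported as Newick with the midpoint edge-length convention (child at
height h_c under a parent at h_p gets edge (h_p − h_c)/2).

**Window sizing.** The library default window is 51 genes. The moving
average bleeds signal ±(w−1)/2 genes past a segment boundary, so the
window must be small relative to both segment and chromosome length:
with 80-gene segments on 330-gene chromosomes, a 51-gene window calls
halo genes far outside the true segments. The pipeline therefore sizes
the window proportionally to the gene universe — 17 genes at desk scale
(0.85% of 1,992 genes, the same order as the 101-gene window a common
expression-CNV tool uses on a ~10–15k-gene transcriptome). Across the
seeds we scanned, 17 keeps outside-segment specificity ≥ 0.99 while
holding per-category partition Jaccard ≥ 0.8; larger windows lose
specificity to boundary halos, smaller ones lose edge-gene sensitivity.
Margins are modest (worst observed specificity ≈ 0.992, worst Jaccard
≈ 0.82), which is inherent to the fixed ±1/50% calling rule at this
signal-to-noise level.

## Spot deconvolution

Signatures are per-group means of linear-scale normalised expression
(`expm1` of the log-normalised values, i.e. counts-per-10k) over the
union of per-group top-100 markers. Per spot, weights solve
min‖Sw − x‖₂ s.t. w ≥ 0 (scipy NNLS) on the genes shared with the
signature, then renormalise to the simplex; the raw weight sum and
residual are kept, and an all-zero solution is flagged "undetermined"
and set uniform. The upstream study used an external Poisson
platform-effect model for this step; NNLS on linear means is this
package's declared solver, pluggable via the `solver` argument. Using
counts-per-10k on both sides makes the mixture model exactly linear
(expm1 undoes log1p), so recovery is unbiased up to sampling noise.

## Transformation map

Inputs are per-spot weights over the three luminal-epithelial states
(normal, hyperplasia, malignant). If the top weight exceeds the
dominance threshold (0.8) the spot is stable in that state. Otherwise
the two largest weights, ordered by progression rank
normal < hyperplasia < malignant, name the pathway (n→h, h→m, n→m), and
the transformation index is w(later)/(w(earlier)+w(later)) ∈ [0,1],
staged by tertiles (early < 1/3 < intermediate < 2/3 < advanced). The
dominance threshold, two-state rule, index formula and tertile cuts are
this package's own definitions — the source analysis shows three
pathways at three intensities but states no formula — and all are
configuration knobs. An optional admissibility set (from external
trajectory analyses) can veto pathways; vetoed spots fall back to
stable. Rendering uses blue (n→h), orange (h→m), green (n→m) hues with
light/medium/dark intensity by stage, plus a TSV sidecar that
round-trips the map exactly.

For monotonicity checks, note the stage is a three-level ordinal
variable: tie-corrected Kendall tau-b against a continuous position is
bounded near 0.8–0.89 even for a perfect staircase, so
`stage_position_association` reports the tie-ignoring Kendall variant
(Goodman–Kruskal gamma over stage-informative pairs), which is 1 for a
perfectly monotone ramp.

## Synthetic data

Counts are negative binomial with inverse-dispersion θ = 10
(variance m + m²/θ), gene base weights log-normal(0, 1), library sizes
log-normal (cells: median 4,000 UMI at desk scale; spots: 8,000).
Mitochondrial genes (a dedicated chrM) take a Beta(2, 38) share of each
cell's library (mean 5%), hemoglobin genes Beta(1, 99); planted
violators (3% tiny libraries, 3% high-mito, 2% high-HB) give the QC
thresholds known targets. Cell types carry 60-gene marker programs at
fold 5 (desk scale); marker genes' base weights are pinned near one
count-per-10k so markers are high in their own type and below the
annotation rule's detection/mean thresholds elsewhere — with a
heavy-tailed random base this is not guaranteed on a scaled-down gene
universe, and real markers are exactly such low-background genes. The
three LE states share the LE markers and differ by 30-gene state
programs at fold 3; M1/M2 macrophages share myeloid markers and differ
by 20-gene polarization programs at fold 2. CNV segments multiply the
mean dosage (1.5 gain / 0.5 loss) over 80 contiguous genes; the desk
design plants one shared gain, one shared loss, one
hyperplasia-specific gain and one malignant-specific loss, so the
planted tree topology is ((hyperplasia, malignant), (normal LE, basal)).
Spots mix noise-free per-type expectation profiles on a grid: a stromal
background, three nodules (hyperplastic, malignant, normal) with
interior/rim mixtures, and a 2-row gradient strip ramping hyperplastic
into malignant signal, with spot-level violators analogous to cells.
All randomness flows from the single config seed; regeneration is
byte-identical.

What the generator does **not** emulate: batch effects, doublets,
ambient RNA, spliced/unspliced layers, spatial autocorrelation of
library size, cell-type-specific dispersion, and segmental dosage
heterogeneity within a carrier group. Passing tests therefore show the
operators implement their stated rules and recover structure under
idealised NB noise — not that the rules are optimal on real tissue.

## Problem sizes and determinism

Two fixture scales are used throughout: `tiny` (~300 cells, 100 spots,
328 genes; seconds) for smoke and determinism checks, and `desk`
(~2,450 cells, 900 spots, 1,992 genes over six autosomes + chrM;
tens of seconds) for recovery checks. These sizes were chosen so the
full test suite and the verification script each complete in a few
minutes on a single CPU. `scripts/acceptance.py --seed N --out f.json`
regenerates everything from scratch at the given seed and writes the
measured quantities (QC oracle mismatches, exact-Wilcoxon error, CNV
null calls and recovery, tree distance, deconvolution accuracy,
module-score calibration, strip monotonicity, determinism flag).

## Known limitations

* The CNV caller's fixed ±1/50% rule leaves no knob to trade
  sensitivity against the smoothing halo except the window; segments
  much shorter than ~2 windows will be missed at the edges.
* NNLS deconvolution ignores count heteroscedasticity; closely related
  groups separated only by small programs (M1 vs M2 macrophages) show
  the largest weight confusion.
* The transformation index is a two-state ratio; spots with three
  substantial state weights lose the smallest one.
* Exact Wilcoxon is limited to groups of ≤ 8 by design; beyond that the
  normal approximation is used even when an exact test would be
  feasible.
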