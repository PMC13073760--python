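# Methods

`sarcospot` re-implements, as a tested library, an integrative
biomarker-discovery analysis for undifferentiated sarcomas (US): bulk
tumor-vs-normal differential expression, pathway scoring restricted to
tumor-upregulated genes, a rank-based integration of tissue and cell-line
transcriptomes, expression-based copy-number inference on spatial single-cell
data, a stepwise candidate-prioritization cascade, and the clinical scoring
statistics used to evaluate an immunohistochemistry (IHC) cohort. Every stage
is driven by a synthetic-data generator with planted ground truth, so the
whole pipeline is testable without external downloads.

## Bulk differential expression (`sarcospot.bulk`)

FPKM matrices are modelled on the log2(FPKM + 1) scale. Expression QC keeps a
gene when FPKM >= 1 in at least 20% of all samples or of the samples within
either group (a group counts only when it has >= 2 samples), then restricts
to protein-coding biotypes. Differential expression is a per-gene two-group
linear model with empirical-Bayes variance moderation: per-gene residual
variances s_g^2 (df d) are shrunk toward a prior s_0^2 with prior df d_0,

    s~_g^2 = (d_0 s_0^2 + d s_g^2) / (d_0 + d),

and the moderated t = (mean difference) / sqrt(s~_g^2 (1/n_1 + 1/n_2)) is
referred to a t distribution with d + d_0 df. The hyperparameters are
estimated by the canonical method of moments on log variances (trigamma
inversion); on shared-variance ensembles d_0 diverges and the statistic
collapses to the ordinary t with the pooled ensemble variance. P-values are
Benjamini-Hochberg adjusted (via statsmodels); genes with FDR < 0.01 and
|log2FC| >= 2 are classified up/down, the rest unchanged. The implementation
reproduces Bioconductor limma's `lmFit`/`eBayes` to machine precision on
random fixtures (test-suite oracle); limma itself is never called by the
library. Log2 fold changes are differences of group means of log2(FPKM + 1),
matching the transform-then-model order; boundary equality (log2FC exactly 2)
counts as differential. Designs are unpaired; multi-factor and paired models
are out of scope.

## Pathway scoring (`sarcospot.gsva`)

Single-sample gene-set variation scores are computed from log2(FPKM + 1)
values with the published GSVA recipe: a per-gene Gaussian-kernel CDF
(bandwidth = gene sd / 4) evaluated at the observed points gives each
sample's expression-level statistic; genes are ordered per sample by that
statistic; the symmetric rank weight |p/2 - position|^tau (tau = 1) drives a
weighted KS-like random walk, scored as max positive deviation minus the
magnitude of the max negative deviation ("mx.diff"; the single largest
deviation variant is available via `method="max_dev"`). Scores are bounded in
[-1, 1] and invariant to gene-row order. Gene sets are first intersected with
the tumor-upregulated, expressed genes; sets retaining fewer than 10 genes
are dropped. Differential pathway activity reuses the moderated two-group
test on the score matrix at FDR < 0.05, with row-wise z-scores emitted for
display. Degenerate samples whose kernel statistic is flat (e.g. constant
expression) score 0 by definition, since their ranking is arbitrary.

## Quadrant-spotlight integration (`sarcospot.quadrant`)

Two datasets without shared normalization are compared on scale-free axes.
Tissue axis: dNT = median(log2 FPKM+1 over tumors) - median(over normals) per
gene. Cell-line axis: within each sample, a gene's ECDF percentile among a
fixed DEG subset, midrank(g)/n in (0, 1], summarized as the median across
samples; midranks make the mean percentile identity (n+1)/(2n) exact under
ties. Selection keeps genes with dNT > 0 (strict) whose median percentile
reaches the empirical 80th percentile of the subset, computed with the
linear-interpolation quantile convention (numpy's default, "type 7"); on 101
distinct percentiles the threshold is the 81st order statistic, so exactly 21
genes clear it. Interpreting the "80th percentile" as a quantile of the
observed medians (rather than a fixed 0.8 percentile value) is a deliberate
reading: it is the one that yields a fixed selected fraction regardless of
how compressed the percentile distribution is.

## Spatial preprocessing (`sarcospot.spatial`)

Cell tables are AnnData objects (obs: tissue, FOV, slide coordinates in mm,
CD45/CD68 intensities, doublet flag, cell-type label; var: gene positions).
QC keeps singlet, CD45-negative cells with >= 20 detected genes from selected
FOVs; the CD45 cutoff defaults to an Otsu split of the bimodal intensity
histogram and is overridable. Doublet flags are consumed as input (from the
generator or any external caller); the published doublet detector is not
re-implemented. Counts are CPM/log1p normalized; optional TMM factors follow
the edgeR recipe (upper-quartile-matched reference, 30%/5% trimming of M and
A, precision-weighted mean of M, log-factors centered to 0). Clustering runs
on z-scaled genes -> PCA (n_pcs = 30, capped at rank) -> per-batch mean
centering in PC space (a documented linear surrogate for the published batch
integration, which is not re-implemented) -> shared-nearest-neighbor graph
with Jaccard weights -> Leiden community detection with a fixed seed; a
forced cluster count falls back to k-means. The full 1000-gene panel is used
(no HVG selection).

## Two-pass CNV inference (`sarcospot.cnv`)

Copy number is inferred from expression alone, per tissue. Genome smoothing:
per-gene log2 ratio to a baseline ((log1p CPM - baseline)/ln 2), clamped to
+/-3, moving-averaged over 25 genes ordered by (chrom, start) within each
chromosome (edge windows shrink), then per-cell median re-centered. Pass 1
uses the tissue-mean profile as baseline and scores each cell's deviation as
the mean squared ratio. Reference-like cells are the lowest-deviation
fraction of non-mitotic-high cells (mitotic score = mean log1p CPM over a
configurable cycle-gene list; high = tissue mean + 1 sd), with the fraction
adaptively the smallest value in [0.2, 0.4] whose pool reaches 200 cells.
Pass 2 re-baselines on the reference mean and reports per cell:

* CNV_level — median inferred copy number, 2 * 2^ratio on the diploid scale;
* CNV_score — mean |ratio| over the top 10% of bins by |ratio| (the
  upper-tail deviation from neutrality; the tail quantile is configurable);
* optional spatial smoothing — distance-weighted kNN propagation within a
  tissue, weights 1/(distance + epsilon), self included; epsilon defaults to
  5e-3 mm, roughly a cell radius, so the self weight reads as "distance to
  self = own radius" rather than dominating the average;
* CNV-high call — tissue-wise score > mean + 1 sd (sample sd); a
  zero-variance tissue yields no calls.

Two refinements inside the `TwoPassCNV` estimator (the op-level functions
keep their plain contracts): (i) when total counts are supplied, pass-1
deviations are standardized within depth-decile strata before ranking —
sampling noise shrinks with depth, so otherwise the deepest aberrant cells
undercut noisy neutral cells and contaminate the reference pool; (ii) when
spatial smoothing is on, reference ranking uses the elementwise max of the
standardized raw and kNN-smoothed deviations, i.e. a reference must look
copy-neutral both on its own profile and in its neighborhood. Cell-type
labels never enter inference or reference selection (asserted by a
label-permutation test). No HMM segmentation, subclone trees, or
allele-specific calls.

## Candidate prioritization (`sarcospot.prioritize`)

Within the target subset (CNV-high cells carrying a configured cell-type
label) genes are ranked by mean log1p CPM, ties broken lexicographically, and
the top 30 kept per tissue. The cascade intersects the per-tissue top-30
lists (per-tissue-then-intersect, matching the "shared between tumors"
construction), then the quadrant-selected gene set, then gates on membrane
evidence. Three binary annotations (membrane association, plasma-membrane
localization, transmembrane topology) combine into a weighted evidence score
with default weights (1, 2, 3); the weights order candidates for display
only — the retained set depends solely on the evidence-positive gate, whose
strictness (any evidence vs. a minimum score) is configurable. Genes missing
from the annotation table are treated as all-false with a warning.

## Clinical statistics (`sarcospot.clinical`)

H-score = sum over intensity bins 1-3 of intensity x percent of cells,
range [0, 300], linear in the intensity fractions. Group comparisons use the
Wilcoxon rank-sum test (midranks; exact by enumeration when combined n <= 12
without ties, else normal approximation with tie and continuity corrections —
slightly conservative at cohort scale), an exact Fisher test for r x c tables
by full enumeration of tables with the observed margins under the
probability-ordering two-sided definition (1e-7 relative slack; feasible at
n = 30, r <= 3), and Pearson correlation with the t-based p-value. Survival
is treated as a two-level status (Alive vs. died of disease), not
time-to-event.

## Synthetic data (`sarcospot.simulate`)

The generators emulate the statistical structure of the study's inputs.

* **Bulk cohort** — 6 tumor vs 7 normal samples; log2(FPKM + 1) ~
  N(mu_g, sigma) with mu_g ~ U(2, 9), sigma = 0.4; planted up/down genes
  shift the tumor mean by +/-2.5 log2 units; 20% of genes sit below the
  FPKM = 1 QC floor and 20% carry a non-coding biotype. sigma = 0.4 makes
  per-gene power high at the pipeline thresholds, the regime the planted-
  recovery suites are meant to probe.
* **Cell-line panel** — 2 samples; baseline log2 expression N(4, 1.5);
  designated genes shifted +5 log2 units so their within-sample percentile
  clears 0.9 in expectation.
* **Spatial tissue** — a 1000-gene panel laid uniformly on a synthetic
  2-chromosome genome in panel order (only the ordering matters to the
  smoother). Counts are negative binomial (gamma-Poisson, theta = 10) around
  per-gene lognormal base means (mu = 1.3, sigma = 0.5; ~4000 counts/cell),
  i.e. a curated imaging panel of robustly expressed genes — sparser settings
  make per-gene log ratios nearly binary and starve the smoother; depth and
  dispersion are free parameters of the generator, not claims about any real
  dataset. Clone cells multiply in-segment gene means by the segment copy
  ratio and carry a scattered 30-gene marker program (x3) so planted
  populations are also separable by clustering. Clones and immune cells are
  Gaussian blobs on a separated ring inside each FOV (spatially coherent by
  construction); immune cells have high bimodal CD45 intensity; 5% doublets
  add a partner cell's counts and are flagged; 2% of cells are generated at
  ~0.2% depth to fall below the 20-gene QC floor.
* **Clinical cohort** — 30 patients with intensity fractions (Dirichlet over
  the positive bins), consistent H-scores and positivity, localization in
  {C, C/M, C/M/N}, subtype/grade/presentation frequencies matching a
  30-patient US series, and a tunable positivity/localization association
  with survival (0 = null, used for type-I calibration).

What the generators do **not** model: mouse-read contamination, segmentation
errors, spatially varying capture efficiency, gene-length effects in FPKM,
isoform structure, or pixel-level images (intensities are scalar per cell).
Passing recovery suites therefore demonstrate internal correctness of the
pipeline under its own assumptions, not performance on real CosMx or RNA-seq
data.

## Numerical choices and degenerate inputs

Trigamma inversion by Newton iteration (50 iterations, 1e-10 relative
tolerance); BH ties via step-up with cumulative minimum; GSVA kernel
bandwidth floor handled by scoring flat statistics 0; TMM skips genes absent
in either cell; smoothing requires an odd window no wider than a chromosome;
zero-variance tissues produce no CNV-high calls; empty QC or restriction
results raise `EmptyResultError` rather than returning silently empty
objects; Fisher enumeration caps p at 1. Every generator is deterministic
under a fixed seed, and clustering/CNV are deterministic given data and seed.

## Problem sizes in the test suite

The recovery suites run at deliberately moderate scale: 5000-gene bulk
cohorts, 3000-cell tissues for the CNV band (three seeds), twenty 1200-cell
tissues for reference-purity calibration, and 500 seeds for clinical type-I
calibration. These sizes keep the full suite to a few minutes while leaving
the asserted margins (recall >= 0.9, CNV sensitivity >= 0.8, specificity
>= 0.9, AUC >= 0.9) comfortably away from Monte-Carlo noise.

## Known limitations

The moderated model assumes homoscedastic groups per gene; the CNV smoother
cannot see focal events narrower than ~half a window; CNV_level is
insensitive to gains covering < 50% of the genome (by design of the median);
the mean+1sd CNV-high rule is fraction-sensitive when aberrant cells dominate
a tissue; TMM assumes most genes are not differential between cells; the
exact Fisher enumeration is exponential in table size and intended for
cohort-scale tables only.
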