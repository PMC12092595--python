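# Methods

This note documents the models and procedures the package implements,
the defaults it ships, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

Expression travels as a `CountMatrix` — cell and gene identifier lists
plus a cells × genes array (sparse or dense) and a layer tag
(`raw` → `lognorm`). The tag is load-bearing: scoring, typing and
binning refuse raw input rather than silently casting, because a
module score on raw counts is a different (and wrong) statistic.
Cell annotations and spatial maps are plain pandas DataFrames with a
required-column contract (`cell_id`, `sample_id`, `condition`,
`cell_type`, `lineage`, `is_T`; `x_um`, `y_um`). Lineage
(lymphocyte / non-lymphocyte / other) is always assigned from an
explicit user-supplied map — unmapped types become `other` with a
warning, never a guess. All coordinates are planar micrometers; there
is no 3-D support.

Bundled gene sets contain only symbols that can be stated with
confidence for the biology at hand: the ISG anchor set
{ISG15, ISG20, IFIT1, IRF7} and the cytotoxicity anchor {GZMB}. Real
analyses should pass fuller panels (GMT or newline lists); panel
composition is treated as configuration, not as something the package
invents. Gene matching is case-sensitive with an opt-in
case-insensitive fallback for human/mouse symbol casing (ISG15/Isg15).

## QC and normalization

QC applies cell-level rules first — minimum detected genes, then a
total-count window `[min_counts, max_counts]` — and then removes genes
detected in fewer than `min_cells_per_gene` of the *surviving* cells.
Each removed cell is attributed to the first rule it fails, so the
per-rule counts in the `QCReport` sum exactly to the total removed.
Defaults: `min_genes_per_cell=100`, `min_counts_per_cell=2000`,
`max_counts_per_cell=35000`, `min_cells_per_gene=3` — the standard
filter for sequencing-based spatial spots. The cell-before-gene order
is a convention choice (the thresholds themselves do not dictate one);
it is fixed, reported, and idempotent.

Normalization is `log_base(count / cell_total * target_sum + pc)` with
the pseudocount added *after* scaling. Two dialects are built in:
`visium` (target 10,000, log2, pc=1) and `xenium` (target 1,000,
natural log, pc=1). Cells with zero totals are an error naming the
cell: their scaling is undefined, and silently dropping them would
desynchronize matrix and annotation.

## Module scores and ISG-T calling

Genes are ranked by mean log-normalized expression over all cells and
cut into `n_bins` equal-frequency bins (sizes differ by ≤ 1; ties
broken by input gene order for determinism). For each program gene
present in the matrix, `n_ctrl_per_gene` control genes are drawn
without replacement from that gene's bin after excluding all program
genes; the concatenated draw (a multiset — repeats keep their weight)
is the control pool. The per-cell score is the mean over program genes
minus the mean over the pool. Defaults `n_bins=24`,
`n_ctrl_per_gene=100` follow the long-standing convention for this
scoring scheme in the single-cell field; both are exposed. When a bin
has fewer eligible controls than requested — common on small simulated
or imaging panels — the draw falls back to sampling with replacement
and warns, rather than failing or silently shrinking the pool.

The score is shift-invariant (a constant added to the whole matrix
cancels) and calibrated: under an i.i.d. null it centers at 0, which
the acceptance suite measures directly.

ISG-T cells are identified in the source biology by unsupervised
clustering; clustering is deliberately out of scope here, so the
package substitutes an explicit, auditable threshold rule:
`sd:k` (score > mean + k·SD of a reference population, default k=3),
`quantile:q`, or `abs:x`. The `sd` reference defaults to non-T cells
when any are present among the scored cells — the largest population
guaranteed free of the T-cell program — falling back to all scored
cells. Externally derived cluster labels can always be used instead by
bypassing `call_isgt`. Per-sample ISG-T frequency is
`#(called ∧ is_T) / #is_T`; a sample with no T cells yields a missing
value, never 0, since the proportion is undefined there.

## Cell typing

`train_classifier` fits a multinomial logistic regression with L2
penalty; the regularization strength is selected by stratified
`cv_folds`-fold cross-validated log-loss over `strength_grid`
(candidate C values in the scikit-learn sense, i.e. inverse penalty;
default 10 log-spaced values in [1e-4, 1e4], folds = 5). Every class
must have at least `cv_folds` members. The fitted model is stored as a
plain (gene list, class list, weights, intercepts) bundle in JSON;
prediction computes the softmax directly from those arrays, so it is
reproducible from the file alone, invariant to gene column order, and
ties at the argmax break by class-label order. At predict time genes
are aligned by identifier: unknown query genes are dropped, model
genes missing from the query are imputed as 0 on the log scale (with a
logged fraction) — imaging panels are small, so partial overlap is
normal — but less than 50% overlap is treated as a feature-space
mismatch and fails hard.

## Spatial proximity

`nearest_focal_distances` computes, per sample, the minimum Euclidean
distance from every non-focal cell to the nearest focal (ISG-T) cell,
using an exact KD-tree query (`scipy.spatial.cKDTree`); exactness is
part of the contract and is verified against an O(n·m) brute-force
double loop. The direction is fixed — non-focal → nearest focal, not
the reverse, which differs when counts are unbalanced. Distances never
cross sample boundaries, and samples containing no focal cell are
excluded and listed rather than given infinite distances, so medians
are never contaminated by an undefined statistic.

Medians are aggregated two ways, both exposed: `pooled_cells` (median
over all cells of a type, optionally within condition; the natural
reading when group sizes are reported as cell counts) and
`median_of_sample_medians` (robust to unbalanced biopsies). Types are
ranked ascending by median within each lineage class; ties break by
type name and are flagged. The result serializes as a star network
(ISG-T hub, one spoke per type carrying distance and rank) with an
optional radial matplotlib figure.

Condition comparisons support one-way ANOVA with Tukey HSD adjusted
pairwise p-values (3+ groups) and the two-group alternatives
(two-sided Mann-Whitney, Welch t, Wilcoxon rank-sum), plus Pearson r
with its t-distribution p for paired numeric vectors. Groups with zero
variance everywhere yield a missing p with an explanatory note rather
than an exception. Tukey HSD adjusts within the ANOVA family only; an
optional Benjamini-Hochberg pass across cell types is available but
off by default, matching per-figure testing practice.

## Synthetic data

The expression simulator draws counts from a negative binomial
parameterized by (mean, dispersion) with variance μ + μ²/θ (θ = 2 by
default, a typical droplet-data value), via a gamma-Poisson mixture.
Per-gene baseline means are log-normal (log-mean ln 0.5, log-sd 1 —
a plausible droplet-depth expression profile) unless given explicitly;
per-cell library factors are log-normal with unit mean and
coefficient of variation `library_size_cv` (default 0.3). The ISG
program multiplies the mean of each program gene by `2^log2fc` in a
`program_fraction` subset of T cells (defaults: 1.0 and 0.05); truth
labels are recorded. An optional `type_markers` map gives each cell
type its own marker program, which is what makes labeled references
for the classifier simulable.

The tissue simulator is a Thomas-like clustered point process: parents
(pDC) uniform on the domain, each offspring (ISG-T) displaced from a
uniformly chosen parent by an isotropic Gaussian of scale
`attraction_sigma_um`, reflected at the boundary so per-type counts
are exact; all other types uniform. σ = ∞ disables the attraction.
Defaults per 2000 × 2000 μm sample: 50 pDC, 100 ISG-T, and ~1,700
other cells across six uniform types — tissue-scale densities chosen
once as a plausible biopsy composition and exposed in the spec object.
Cohorts reuse one spec per condition with per-sample seeds
`base_seed + global sample index`, so a whole cohort reproduces from a
single integer.

Expression and tissue generators use distinct seed streams (a stream
tag is mixed into the seed), so fixing one never perturbs the other.

What the simulators deliberately do **not** model: spatial coupling of
expression (position and expression are independent), 3-D tissue,
doublets, ambient RNA, batch effects, or cell-type-dependent library
depth. Passing tests therefore demonstrate that the *statistics* are
implemented correctly and recover planted structure under clean
conditions; they do not certify behavior under segmentation errors,
batch structure, or panel dropout in real biopsies.

## Problem sizes and numerics

The test and acceptance workloads use 2,000-cell × 2,000-gene
expression cohorts (25 seeds for the null calibration), 10-sample
tissue cohorts per condition at four attraction scales, 50 random
nearest-neighbor instances up to 2,000 cells / 100 focal, and a
600-cell 5-class typing reference — sizes at which every planted
effect is comfortably detectable while the full suite runs in well
under a minute per module. Exactness claims are tested at 1e-12
(normalization arithmetic, score-vs-naive equivalence), 1e-9
(geometry), and 1e-8 (closed-form statistics). Stochastic claims use
fixed seeds and tolerance bands stated in the tests themselves.
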