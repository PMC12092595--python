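# isgt

Identification of interferon-stimulated-gene-expressing T cells
(**ISG-T cells**) in single-cell and spatial transcriptomics data, and
quantification of their spatial relationship to other cell types —
in particular plasmacytoid dendritic cells (pDC), the main producers of
type I interferon.

In autoimmune kidney disease (ANCA-associated and lupus nephritis), a
subset of T cells upregulates interferon-stimulated genes such as
*ISG15*, *ISG20*, *IFIT1* and *IRF7*. Two questions drive the analyses
this package implements: *how large is that subset* in each sample, and
*where do those cells sit* in tissue relative to the interferon source.
The package is a library first (everything is importable from `isgt`),
with an `isgt` command-line wrapper for running the same pipeline from
a shell.

## What it computes

**Module score.** For a gene program \(G\) (e.g. an ISG panel) the
per-cell score is

```
score(c) = mean_{g in G} x_cg  -  mean_{g' in ctrl(G)} x_cg'
```

on log-normalized expression `x`. The control pool `ctrl(G)` draws, for
every program gene, `n_ctrl_per_gene` random non-program genes from the
same mean-expression bin (genes ranked by mean expression and cut into
`n_bins` equal-frequency bins). Expression-matched controls make the
score a calibrated null: without a program effect it centers at 0.
ISG-T cells are then called by an explicit threshold rule (default:
score > mean + 3 SD of a program-free reference population), and
per-sample ISG-T frequency among T cells is reported.

**Preprocessing.** QC filtering (minimum detected genes per cell, a
total-count window, minimum cells per gene) and two library-size
normalization dialects: totals scaled to 10,000 with log2 and
pseudocount 1 (`visium`, sequencing-based spots) or totals scaled to
1,000 with natural log and pseudocount 1 (`xenium`, imaging-based
cells).

**Cell typing.** A multinomial logistic classifier with L2 penalty,
regularization chosen by stratified cross-validated log-loss, trained
on a labeled reference and applied to query cells with gene-id-based
feature alignment.

**Spatial proximity.** Within each tissue sample, the minimum Euclidean
distance (μm) from every non-ISG-T cell to its nearest ISG-T cell;
per-type medians (pooled cells, or median of per-sample medians);
a star-shaped median-distance network with ISG-T at the hub and
cell types ranked within lymphocyte / non-lymphocyte classes; and
condition comparisons (one-way ANOVA + Tukey HSD, Mann-Whitney,
Welch t, Wilcoxon rank-sum, Pearson r).

**Synthetic data.** A negative-binomial expression simulator with a
planted ISG program in a fraction of T cells, and a Thomas-like tissue
simulator in which ISG-T "offspring" scatter around uniformly placed
pDC "parents" with Gaussian scale σ (σ = ∞ gives uniform placement).
Both record ground truth, so every stage of the pipeline is testable
without any external download.

## Worked example

`examples/spatial_proximity.py` simulates 5 "disease" biopsies
(ISG-T attracted to pDC at σ = 30 μm) and 5 uniform "control"
biopsies, then runs the proximity analysis:

```
Disease cohort, median distance to the nearest ISG-T cell (um):
cell_type        lineage  median_d_um  rank
        B     lymphocyte   135.203452     1
       Tn     lymphocyte   135.828495     2
      pDC non_lymphocyte    26.889113     1
       PT non_lymphocyte   129.862474     2
      ...

closest non-lymphocyte neighbor: pDC

pDC -> nearest ISG-T, disease vs control:
  median[control] = 88.35 um (n=250)
  median[disease] = 26.89 um (n=250)
  one-way ANOVA: F = 131.4, p = 3.66e-27
```

pDC is the rank-1 non-lymphocyte neighbor (median ≈ 27 μm vs
≈ 130 μm for unattracted types), and the disease median is several-fold
smaller than the control median — the simulated attraction is recovered
both as a ranking and as a condition contrast. The other examples
(`score_isg_program.py`, `cell_typing.py`, `cli_pipeline.sh`) cover
program scoring/ISG-T calling, reference classification, and the
command-line chain.

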