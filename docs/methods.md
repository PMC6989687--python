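# Methods

## Scope and model

`ehtmark` identifies a haematopoietic-transitioning minority among
endothelial cells in a cells × genes TPM matrix and nominates marker genes
for it. The pipeline is deterministic given a configuration and one
top-level seed; every random draw comes from a named substream of that
seed (`ehtmark._rng.substream`), so adding a stream never perturbs another.

### Quality control

A cell is discarded iff `mapped_reads < 500,000` or
`mito_fraction > 0.30`, both strict, matching the printed filtering rule
exactly (a cell at either boundary passes). The mitochondrial fraction is
computed from expression units by default — mitochondrial TPM over
endogenous + mitochondrial TPM, spike-ins excluded from both sums —
because the pipeline consumes TPM matrices; whether the original fraction
was read-based is not documented, so a per-cell read-based fraction can be
supplied to `compute_qc(..., mito_read_fraction=...)` instead. A cell with
zero biological expression has an undefined fraction; it is failed with
reason `high_mito` and a logged warning.

### Spike-in-excluded renormalisation

ERCC spike-in columns are dropped and each cell's remaining values are
multiplied by `1e6 / (cell's non-spike-in sum)`. Mitochondrial genes are
retained — only spike-ins leave the transcriptome. Within-cell gene ratios
are untouched; per-cell sums equal 10⁶ to 1e-6 relative tolerance.

### Classification

* **Log transform.** Natural log of (TPM + 1). Only "log-transformed" is
  specified upstream; any fixed base yields identical mixture assignments
  up to covariance rescaling, so one base is pinned for reproducibility.
* **PCA.** On the centred, *unscaled* log values of the panel genes (no
  unit-variance scaling — the minimal reading of the stated method).
  Implemented by SVD of the centred panel sub-matrix; loadings are the
  top-2 eigenvectors of the sample covariance (n−1 denominator). Signs are
  fixed so each loading's largest-magnitude entry is positive. Panel genes
  missing from the matrix are dropped with a warning; fewer than two
  usable genes, or zero total panel variance, is an error (a zero-variance
  panel cannot orient any component, so the degenerate case is refused
  rather than silently returning all-zero scores).
* **Mixture.** A two-component full-covariance Gaussian mixture fitted by
  EM, written in-package. `n_init = 10` restarts are seeded
  k-means++-style (first centre uniform, second with probability
  proportional to squared distance) from one generator; the restart with
  the highest final log-likelihood wins. Covariances get a diagonal ridge
  of 1e-6 × the mean score variance. Convergence when the log-likelihood
  changes by less than `tol·(1+|ll|)` with `tol = 1e-7`, capped at 500
  iterations. A component holding fewer than 2/n cells flags the fit
  `degenerate` instead of failing silently. The number of components is
  fixed at two; no model selection.
* **Annotation.** Cells are hard-assigned by maximum responsibility. The
  component with the larger responsibility-weighted mean log expression of
  the anchor gene (*Runx1* by default) is haematopoietic; an exact tie is
  raised to the caller.

### Marker scan

Per gene, a Gaussian likelihood-ratio test with MLE (1/n) variance:
null = one common mean, alternative = two group means with a *shared*
variance (the one-binary-covariate linear model reading; a per-group
variance is deliberately not fitted here — the Welch module covers
unequal variances for summary comparisons). The statistic
`n·ln(RSS_null/RSS_alt)` is referred to χ²(1); the closed form
`n·ln(1 + t²/(n−2))` with the pooled-variance t is used as an independent
test oracle. Effect = haematopoietic mean − endothelial mean of log
expression. Genes with total variance ≤ `min_variance` (default 0, i.e.
constant genes) are excluded from testing *and* from the Bonferroni family
size m. Rows are ranked by raw p, ties broken by |effect| descending then
gene id, for deterministic output. Perfect separation (RSS_alt = 0,
RSS_null > 0) reports an infinite statistic and p = 0 with a warning.

The χ²(1) reference is asymptotic: at n ≈ 78 cells the raw p-values are
slightly anticonservative in the far tail (the exact null of the statistic
is a monotone transform of t with n−2 df). Uniformity of null p-values is
therefore property-tested at n = 300, where the approximation holds to
Kolmogorov–Smirnov resolution, while family-wise error of the
Bonferroni-corrected scan at the study's own n = 78 is verified directly
by a 200-replicate label-permutation simulation and stays within
0.05 + 3·SE.

### Enrichment

* **Fisher.** One-sided (enrichment) hypergeometric tail P(X ≥ x) with
  fold (x/n)/(K/N); a two-sided option exists but is non-default. The
  background universe is always an explicit argument — in the pipeline it
  defaults to the set of genes actually tested in the marker scan, not a
  whole annotation.
* **Reporter metabolites.** The standard inverse-normal formulation:
  z_g = Φ⁻¹(1 − p_g) with p clipped to [1e-15, 1 − 1e-15];
  z_agg = Σ_{g∈neighbours} z_g / √k; for each distinct degree k the
  background mean μ_k and SD σ_k are estimated from `n_background`
  (default 10,000) random size-k sets of scored genes drawn without
  replacement; z_corrected = (z_agg − μ_k)/σ_k and p_met = 1 − Φ(z_corrected).
  The upstream description names the approach without a formula, so this
  faithful standard variant (undirected, sampled background) is pinned
  here explicitly. Metabolites with no scored neighbour are omitted, not
  zero-filled; σ_k = 0 or k exceeding the scored-gene count is an error.

### Welch's t-test

From summaries: t = (m₂ − m₁)/√(s₁²/n₁ + s₂²/n₂) with Welch–Satterthwaite
df and a two-sided p. Printed SDs are assumed to use the sample (n−1)
convention. The raw-data entry point reduces samples to summaries and
delegates, so the two routes agree identically. Recomputing the published
flow-cytometry comparison from its printed summaries gives t = 2.633 vs
the printed 2.635; the 0.002 gap is attributable to rounding of the
printed means/SDs and both tests use a 0.01 tolerance.

## Synthetic data: what it emulates and what it does not

Defaults are the study conditions: 78 pass-QC cells containing a 10-cell
haematopoietic minority, 2,000 endogenous genes, 25 planted markers with a
natural-log effect of 2.0, 92 ERCC species at a 2% TPM fraction, 13
mitochondrial genes, 5 low-depth and 5 high-mito injected failures, mean
depth 1.5 M reads.

Design choices, made once:

* **Log-normal expression, no counts.** Per gene a baseline log-mean
  μ_g ~ Normal(2.0, 1.5); per cell, expression = exp(Normal(μ_g + shift,
  0.5)). The pipeline consumes TPM and tests log-TPM, so a count layer
  would add nothing testable. Dropout appears only implicitly through low
  μ_g tails; there is no explicit zero inflation.
* **Panel structure.** Endothelial-role panel genes (*Cdh5, Kdr, Pecam1,
  Pcdh12, Sox7*) are expressed in every cell (μ = 3.5); blood-role genes
  (*Gfi1, Gfi1b, Myb, Runx1, Spi1*) are near-silent in plain endothelium
  (μ = 0) and shifted by +3.0 in the minority, which therefore co-expresses
  both programmes — the bimodality the classifier exploits.
* **Planted markers.** Baselines are clipped to μ_g ≥ 1.0: a marker that
  is not expressed cannot be discovered, and marker candidates in real
  screens are by construction expressed genes. The *Cd44*-role gene gets
  an extra +1.0 effect (total 3.0) and a baseline ≥ 3.0, reflecting its
  role as the standout marker the screen is meant to surface.
* **Spike-in fraction is a direct parameter** (default 0.02), not a
  dilution model: a 1-in-4000 input dilution does not by itself fix a read
  fraction.
* **QC failures.** Pass-cell mitochondrial fractions are Uniform(0.02,
  0.15); planted high-mito cells Uniform(0.40, 0.60) (fraction targeted
  exactly by scaling the mitochondrial block). Depths are log-normal
  (σ = 0.2) around the mean, floored at the threshold for honest cells;
  planted low-depth cells are Uniform{100,000 … 499,999}.
* **Not emulated:** gene-length/GC effects, amplification noise,
  batch structure, doublets, or realistic library-size distributions
  (none are reported upstream; defaults are stated, not fitted). Passing
  tests therefore demonstrate correctness of the *computation* under a
  clean generative model, not robustness to every artefact of real data.

## Problem sizes used in the test suite

The default fixture (88 cells × 2,105 genes) runs every end-to-end check.
The family-wise-error simulation uses 200 label permutations of one null
dataset; reporter calibration uses 1,000 metabolites over 2,000 uniform
p-values with a 10,000-draw background; LRT oracle equivalence uses 1,000
random instances. The whole suite completes in well under a minute.

## Known limitations

* The χ² reference for the LRT is asymptotic (quantified above).
* The equal-variance LRT is a pinned interpretation; a per-group-variance
  LRT variant is out of scope.
* The Fisher fold printed upstream (1.32 on 395/1605 genes) depends on an
  unstated background universe and cannot be recomputed from published
  information; the module computes folds only for explicit backgrounds.
* Full-scale replication on the deposited sequencing data requires
  external downloads and re-quantification and is outside the package;
  the synthetic study is the supported validation surface.
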