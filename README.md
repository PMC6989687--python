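# ehtmark

Marker discovery for haematopoietic-transitioning cells in single-cell
expression data from the embryonic aorta-gonad-mesonephros (AGM) region.

During the endothelial-to-haematopoietic transition (EHT), a small minority
of AGM endothelial cells switches on the blood programme while still
expressing endothelial genes. `ehtmark` re-implements, as a tested and
reusable pipeline, the computational route by which such cells are
identified in Smart-seq-style TPM data and by which surface-marker
candidates (such as *Cd44*) are nominated:

1. **QC filtering** — cells with fewer than 500,000 mapped reads or a
   mitochondrial expression fraction above 30% are discarded (both
   thresholds strict, as printed).
2. **Spike-in-excluded TPM rescaling** — ERCC spike-in genes are dropped
   and each cell's remaining TPM values are rescaled to sum to 10⁶, so
   downstream statistics consider endogenous expression only.
3. **Classification** — PCA on the centred log(TPM+1) values of a ten-gene
   panel (*Cdh5, Kdr, Pecam1, Pcdh12, Sox7, Gfi1, Gfi1b, Myb, Runx1,
   Spi1*); a two-component full-covariance Gaussian mixture is fitted by
   EM on the first two principal components, and the component with the
   higher *Runx1* expression is labelled haematopoietic.
4. **Marker scan** — for every gene *g*, a Gaussian likelihood-ratio test
   of the alternative model with a binary haematopoietic term against the
   common-mean null on log(TPM+1):

   LRT_g = n · ln(RSS₀/RSS₁) ~ χ²₁,  equivalently n · ln(1 + t²/(n−2)),

   Bonferroni-corrected over the number of genes tested, with the effect
   size μ₁ − μ₀ (difference of group means of log expression).
5. **Enrichment** — one-sided Fisher's exact test of a gene category with
   fold enrichment (x/n)/(K/N), and reporter-metabolite scoring over a
   bipartite gene–metabolite network: z_g = Φ⁻¹(1 − p_g), per metabolite
   z_agg = Σ z_g/√k, corrected against size-matched random gene sets.
6. **Group statistics** — Welch's unequal-variance t-test computable from
   printed means/SDs/sizes (Satterthwaite degrees of freedom).

A first-class synthetic-data generator plants all of this structure — a
78-cell pass-QC population with a 10-cell haematopoietic minority, 25
planted markers led by a *Cd44*-role gene, spike-ins, mitochondrial genes
and injected QC failures — so every stage is validated against known truth.

## Worked example

```python
from ehtmark import (
    GroupSummary, MarkerPanel, SimulationConfig,
    annotate_components, compute_qc, filter_cells, fit_gmm2,
    generate_dataset, log_transform, marker_pca,
    rescale_tpm_excluding_spikeins, scan_all, welch_t_from_summary,
)

matrix, reads, truth = generate_dataset(SimulationConfig(seed=1))
filtered = filter_cells(matrix, compute_qc(matrix, reads))
logm = log_transform(rescale_tpm_excluding_spikeins(filtered))
panel = MarkerPanel()
labels = annotate_components(
    fit_gmm2(marker_pca(logm, panel).scores, seed=1), logm, panel
)
table = scan_all(logm, labels)
print(filtered.n_cells, len(labels.cells_with_label("haematopoietic")))
print(table.head(3)[["gene_id", "p_bonferroni", "effect"]])
```

prints

```
78 10
  gene_id  p_bonferroni    effect
0     Myb  4.713593e-28  2.976407
1    Cd44  6.936316e-28  3.141980
2   Runx1  1.013257e-26  2.831222
```

i.e. 78 of 88 cells survive QC, exactly the 10 planted cells form the
haematopoietic cluster, and the *Cd44*-role gene sits at the top of the
marker ranking — alongside blood-programme panel genes such as *Myb* and
*Runx1* — with a natural-log effect near its planted value (2.0 + 1.0
extra), every adjusted p-value far below 0.05.

The Welch worked example from printed summaries:

```python
welch_t_from_summary(GroupSummary(22.13, 4.85, 4), GroupSummary(30.88, 5.08, 5))
# WelchResult(t=2.6332..., df=6.7039..., p_two_sided=0.0350...)
```

A command-line interface mirrors the stages:

```bash
ehtmark simulate --seed 1 --out-dir synthetic
ehtmark qc --matrix synthetic/matrix.tsv --reads synthetic/reads.tsv
ehtmark welch 22.13 4.85 4 30.88 5.08 5
ehtmark run --config run.yaml   # full pipeline from a YAML config
```

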