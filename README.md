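# snsubtype

Molecular subtype discovery from multi-cell-type single-nucleus RNA-seq
cohorts, with gene-set-level analysis, similarity network fusion,
subtype-specific differential expression, clinical association, and
subtype prediction.

## The problem

Neurodevelopmental and psychiatric conditions such as autism spectrum
disorder are clinically and genetically heterogeneous: patients who share
a diagnosis may carry distinct molecular alterations. A molecular-first
approach clusters patients directly on brain expression data — here,
single-nucleus RNA-seq profiled separately in each annotated cell type —
and only afterwards asks how the resulting subtypes differ in genes,
pathways, and clinical severity.

`snsubtype` implements that workflow end to end for cohorts of the form
*cases + controls, cells grouped by patient and cell type*:

1. **Gene-set scoring (GSVA-style).** Each cell's expression profile is
   converted into per-gene-set enrichment scores: a Gaussian kernel CDF
   transform per gene, `z_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i)` with
   bandwidth `h_i = s_i/4`, a symmetric rank statistic
   `r_ij = |p/2 − rank_ij|`, and a weighted Kolmogorov–Smirnov-like
   random walk whose deviation statistic is the enrichment score
   (bounded in [−1, 1]).
2. **Two-level similarity network fusion (SNF).** Per cell type, patient
   mean profiles give a patient × patient affinity
   `W_ij = exp(−d_ij/(μ·ε_ij))` with locally scaled bandwidth
   `ε_ij = (m_i + m_j + d_ij)/3`. Cross-diffusion
   `P_v ← S_v · (mean of other views) · S_vᵀ` (K-nearest-neighbor kernel
   `S_v`, `K = 3`, `T = 100` iterations) fuses the cell-type networks
   within each modality (genes; gene sets), and then fuses the two
   modality networks into one.
3. **Spectral clustering with model selection.** Patients are clustered
   on the fused network's normalized Laplacian; the number of subtypes
   is chosen by the eigen-gap and a varimax-aligned rotation cost, and
   partitions are scored by an affinity-based silhouette.
4. **Subtype-specific differential expression.** Genes are tested with a
   two-part hurdle model (logistic detection + Gaussian level,
   likelihood-ratio test against the design without the subtype
   indicator, covariates: detection rate, age, sex, RIN, PMI, region,
   batch, ribosomal fraction); gene sets with an empirical-Bayes
   moderated t. Features pass at |log2FC| ≥ 0.14 (a 10% difference) and
   BH FDR < 0.05, and must be differential both against the other
   subtypes and against controls (intersection rule).
5. **Clinical association.** Per-patient fold changes vs controls are
   correlated with a combined clinical score (mean of within-category
   ADI-R score ranks); per-gene correlation p-values are combined with
   Fisher's method (−2 Σ ln p ~ χ²(2m)); per-category rank differences
   use Welch t-tests; risk-gene enrichment uses hypergeometric tests.
6. **Cross-dataset correspondence.** Subtypes derived independently on a
   bulk (or pseudo-bulk) matrix are matched to the single-nucleus
   subtypes by Pearson correlation of fold-change signatures.
7. **Subtype prediction.** PLS-DA (partial least squares on one-hot
   labels, argmax decoding) under three splitting schemes: stratified
   7:3 cell split, leave-one-patient-out-per-subtype, and patient-level
   profiles; components chosen by repeated stratified cross-validation;
   performance reported as micro/macro/weighted F1.

Because the real cohorts behind such studies are access-restricted, the
package ships a first-class synthetic cohort generator
(`snsubtype.synthetic`) that plants all the structure the pipeline
assumes — negative-binomial counts with dropout, three patient subtypes,
subtype×cell-type DE genes with known signed effects, coordinately
shifted gene sets, covariates, and clinical scores linked to each
patient's planted effect magnitude — together with the ground truth used
to score every stage.

## Worked example

```bash
snsubtype simulate --seed 1 --out cohort/            # writes mtx/tsv/gmt/json
snsubtype run-all --data-dir cohort/ --out results/ --seed 1
```

or in Python:

```python
from snsubtype import SimConfig, simulate_cohort, simulate_bulk
from snsubtype import PipelineConfig, run_pipeline
from snsubtype.snf import SNFParams

config = SimConfig(seed=1)                 # 15 cases (6/4/5), 16 controls
cohort = simulate_cohort(config)
bulk = simulate_bulk(config, cohort.truth)
result = run_pipeline(PipelineConfig(out_dir="out", seed=1,
                                     snf=SNFParams(seed=1), bulk=bulk),
                      cohort=cohort)
print(result.assignment.k)
print({m: round(a.silhouette, 3) for m, a in result.modality_assignments.items()})
```

With seed 1 this prints:

```
3
{'gene': 0.549, 'set': 0.718, 'final': 0.734}
```

meaning: the eigen-gap selects three subtypes; clustering the fused
network recovers the planted 6/4/5 patient grouping exactly (adjusted
Rand index 1.0, reported in `out/clustering.json`); and the fused
network separates the subtypes at least as cleanly as either the
gene-level or the gene-set-level network alone — the qualitative
signature of fusing complementary views. The output directory also
contains the subtype-specific feature tables
(`subtype_specific_features.tsv`: at this seed 269 of the 270 planted DE
genes and all 18 planted gene sets are recovered, with a false-discovery
proportion of 0.03), clinical association reports, the bulk
correspondence matrices, and PLS-DA performance
(`prediction.json`: macro F1 ≈ 0.99 for the 7:3 cell split).

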