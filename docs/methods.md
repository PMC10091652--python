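# Methods

This note documents the models, parameter choices, numerical
conventions, and known limitations of `snsubtype`. Everything stated
here about behavior on synthetic data is computed by the test suite or
by `scripts/acceptance.py`.

## Synthetic cohort model

The generator (`snsubtype.synthetic`) is the package's substrate for
validation: it plants exactly the structure the analysis assumes and
returns the ground truth alongside the data.

**Counts.** For gene *g*, cell *c* of patient *p* in cell type *t*:

    count ~ NB(mean = b_g · m_tg · u_bg · v_rg · 2^(s·fc·sev_p) · L_c,
               dispersion φ = 0.4)

- `b_g`: log-normal baseline, median 1 count/cell, sdlog 1.2. The
  500-gene default universe stands for the highly-variable-gene stratum
  of a real matrix, which is biased toward detectably expressed genes;
  a median around one count per cell reflects that stratum, not the
  whole transcriptome.
- `m_tg` (cell type, sdlog 0.5), `u_bg` (batch, sdlog 0.05), `v_rg`
  (region, sdlog 0.05): multiplicative nuisance structure. Batch and
  region are patient-level assignments and are available as covariates.
- `L_c`: per-cell library factor, sdlog 0.3 (drives realistic
  detection-rate variation, used as a covariate downstream).
- The `2^(s·fc·sev_p)` term applies only to planted
  (subtype, cell type, gene) triples: `fc = 1.0` by default, sign `s`
  alternating within each planted list (half up, half down).

**Dropout.** A Bernoulli keep with logit linear in the log mean
(intercept 3.0, slope 1.0) thins the counts. The curve is deliberately
high and flat over the expressed stratum: most zero inflation comes
from the NB itself (~55% zeros overall), and the thinning distorts
group mean ratios by well under the 0.15 recovery tolerance. A steeper
dropout would make planted log2 fold changes unrecoverable from group
means by any estimator — the planted effect would no longer be the
quantity the pipeline is being scored against.

**Planted DE genes** are drawn without replacement from genes whose
cell-type-level mean is at least `de_min_base_mean = 1.0` count/cell
(disjoint across all (subtype, cell type) pairs). Genes far below that
floor are mostly zeros and carry no recoverable fold change on the
log-normalized scale, so planting "effects" there would only dilute
every sensitivity measure with planted-but-unmeasurable features.

**Patient severity.** Each case patient gets a log-normal severity
multiplier (sdlog `severity_sd = 0.15`), normalized to mean 1 within
each subtype, scaling that patient's planted effects. This is the
across-patient variation that makes individual-level fold changes
informative; the within-subtype normalization keeps the group-level
log2 fold change exactly ±`de_log2fc`.

**Gene sets.** 50 sets, sizes 10–40. Two sets per planted
(subtype, cell type) pair are "shifted": `set_shift_fraction = 0.8` of
their members are drawn from that pair's same-sign planted DE genes,
producing a coordinated shift detectable by set-level scoring; the
remaining sets are random draws.

**Clinical scores.** Five integer ADI-R-like categories per case
patient: `round(base_k + 8 · linkage · σ_p + N(0, 1))`, where `σ_p` is
the patient's mean planted |effect| (severity × fc, zero for patients
of subtypes with nothing planted). With `clinical_linkage = 0` the
scores are pure noise (a clean null); with the default linkage of 1 the
combined rank score correlates ~0.9 with planted severity.

**What the generator does not model:** ambient RNA, doublets, UMI
saturation, per-individual random expression offsets beyond
batch/region, missing clinical categories, and the 100k-nucleus scale
of real cohorts. Passing tests therefore demonstrate correctness of
the machinery and recoverability of planted structure under a clean
generative model — not robustness to every artifact of real tissue
data.

## Preprocessing

Size factors are median-ratio library-size factors
(`s_c = libsize_c / median libsize`; value `log2(count/s_c + 1)`).
Pooling-deconvolution factors are deliberately not reimplemented: all
downstream stages consume any log-normalized matrix, and the
substitution is isolated in this one function. HVG selection ranks by
variance of log expression after removing genes matching configurable
regexes (defaults `^MT-`, `^RP[LS]`; the intended exclusion families
differ between tissues, so this is user-configurable rather than
hard-coded).

## Gene-set scoring

Per-cell scoring with Gaussian kernel CDF (`h_i = s_i/4`, sample sd,
ddof 1), decreasing-z ranking with ties broken by input gene order
(stable sort — scores depend on this rule, hence it is fixed and
documented), symmetric rank statistic `|p/2 − rank|`, and the weighted
random walk with `tau = 1`, `mx_diff = true` (max positive plus min
negative deviation) as defaults. Sets are first restricted to genes
present in the matrix and then size-filtered (`min_size = 10`), in
that order. Zero-variance genes are removed with a warning before
scoring. If every member of a singleton-like set sits exactly at the
middle rank the weight total is zero; the walk then falls back to
unweighted membership increments.

The kernel CDF is O(genes·cells²); it is evaluated exactly over unique
values with multiplicity weights (log-normalized data is mostly zeros)
in a numba kernel, with an erf saturation cutoff at 6·√2·h whose error
(< 1e−14) is far below the 1e−10 band the implementation is verified
to against a brute-force oracle.

## Similarity network fusion

Distances are squared Euclidean on standardized features (constant
features dropped; standardization is configurable since reasonable
pipelines differ here). The kernel defaults to `exp(−d/(μ·ε))` with
`ε_ij = (m_i + m_j + d_ij)/3` and `μ = 0.5`; a Gaussian-density variant
is exposed via `kernel="density"` because monotone transforms of the
kernel are largely absorbed by the subsequent normalization.

Row-stochastic normalization (`P_ij = W_ij/(2Σ_{k≠i}W_ik)`, diag 1/2)
scales each row by its own degree and is therefore *not* exactly
symmetric for a general symmetric kernel. The fusion loop symmetrizes
before every re-normalization, so asymmetry stays at the level already
present in the normalized inputs (asserted in debug mode: unit row
sums within 1e−8, no amplification of asymmetry). On affinity families
that are uniform within blocks with K = block size − 1 the iteration
has the normalized input as an exact fixed point, which is what the
fixed-point tests exercise; for general inputs diffusion sharpens the
network by design and no fixed-point claim is made.

K-nearest neighbors use descending affinity with ties broken by
ascending index, self excluded. Defaults `K = 3`, `T = 100`.

**Cluster number.** The eigen-gap criterion maximizes
`λ_{k+1} − λ_k` of the symmetric normalized Laplacian over k = 2..5.
The rotation cost is `J(k) = (1/n) Σ_i 1/max_j Z_ij²` on
varimax-rotated, row-normalized leading eigenvectors — the varimax
step resolves the arbitrary basis of the leading eigenspace, without
which the cost is basis-dependent and systematically favors the
smallest k. J reaches its floor of 1 exactly when each patient loads
on a single rotated eigenvector (clean indicator structure). This is a
documented approximation to alignment-based rotation-cost selection,
not a reimplementation of any specific one.

**Clustering** is NJW-style: row-normalized leading eigenvectors,
seeded k-means with 20 restarts, labels renumbered by descending
cluster size then first-patient index, making runs deterministic under
a fixed seed. The silhouette uses the affinity-derived distance
`d = 1 − P/max_offdiag(P)` (a convention, since affinities are not
metric distances) with singleton clusters contributing 0.

## Differential expression

**Genes: fixed-effects hurdle.** Logistic regression for detection,
Gaussian linear model for expressed-cell level; LRT = summed deviance
differences of both parts, df = added columns per active part, p from
χ². A constant detection vector drops the discrete part (so the
all-expressed case reduces exactly to the classical Gaussian
two-sample LRT); too few expressed cells (< p + 2) drops the
continuous part. Logistic separation triggers a small-ridge refit
(λ = 1e−3), flagged. A per-individual random intercept is *not*
fitted: individuals are nested within subtypes, so an individual fixed
effect would alias the test factor, and a random-effects hurdle is out
of scope; covariates (detection rate, age, sex, RIN, PMI, region,
batch, ribosomal fraction) are fixed effects. Type-I error of the
combined LRT is verified at 200 cells over 2,000 null simulations
(empirical ≈ 0.05–0.06).

The reported log2FC is the hurdle convention
`π̂₁m̂₁ − π̂₀m̂₀` (detection frequency × conditional mean), evaluated
with the test indicator toggled and covariates at observed values.

**Gene sets: moderated linear model.** Per-set OLS with empirical-Bayes
variance shrinkage: the scaled-F prior (d₀, s₀²) is estimated by the
method of moments on log s² (trigamma inversion by Newton), posterior
`s̃² = (d₀s₀² + d_g s²)/(d₀ + d_g)`, moderated t with d₀ + d_g df.
Equal residual variances give a non-finite moment estimate, treated as
d₀ = ∞ (all posteriors collapse to s₀²). The chain is verified against
an independently coded moment oracle and against the reference R
implementation. GSVA scores are not on a log scale; the same 0.14
threshold is applied to their mean-difference "logFC" as a convention,
with this caveat.

**Families and rules.** BH correction is applied within
(cell type, subtype, comparison, feature kind) — the narrowest
consistent family. Subtype-specific features are the intersection of
the vs-other-subtypes and vs-controls calls, with effect size and
direction reported from the vs-other-subtypes fit. Unique/common
partitions are evaluated within cell type (a `--global` evaluation
across cell types would conflate cell-type-specific effects; within is
the default, and the choice is explicit in the API). Discordance
events are common features whose per-subtype vs-control signs
disagree, attributed to the minority sign; zero fold changes are
excluded from the vote and flagged, and an exact sign tie lists all
voters.

## Clinical association

Combined score = mean of within-category average ranks (average tie
handling), over non-missing categories; patients with no clinical data
are excluded with a logged count. Per-patient fold changes vs controls
use the unadjusted hurdle contrast: with a single patient on one side,
patient-level covariates are confounded with the contrast and not
estimable. Pearson correlations (two-sided p, switchable) are combined
with Fisher's method; p = 0 inputs are clamped to the smallest
positive float with a warning. Per-gene correlation p-values within a
subtype are positively dependent (patients' fold changes share the
subtype pattern), so the Fisher meta p-value is an approximation whose
null tail is somewhat inflated; the Monte Carlo null test bounds the
proportion of (subtype, cell type) pairs below 0.1 at 20% rather than
the independent-p nominal 10%. Cell types with fewer subtype-specific
features than `min_degs = 10` (or `min_degs_small = 5` where the
relaxed floor is configured per subtype) are reported NA.

A recoverable clinical signal requires one subtype to carry the
planted effects (generator option `active_subtypes`): when all
subtypes are planted symmetrically with the same effect size, every
patient's severity has the same distribution and the across-patient
correlation signal cancels by construction. The planted-signal checks
therefore use a one-active-subtype cohort.

## Cross-dataset correspondence

Pseudo-bulk profiles are the cell-type-weighted mixture of each
patient's planted mean profiles, log2(x+1), plus Gaussian noise
(sd 0.1). Bulk subtypes are derived by the same GSVA + SNF machinery
treating the bulk matrix as a single-view pair (genes; gene sets).
Fold changes on both sides are covariate-free mean differences of
individual-level profiles (individual-level averaging when a patient
has multiple samples); the correspondence matrix is the Pearson r/p of
fold-change vectors over the shared gene universe, and the pairing is
the row-wise argmax.

## Prediction

PLS-DA: NIPALS partial least squares on one-hot labels with argmax
decoding (no class-prior thresholding). Components are tuned by
repeated stratified k-fold cross-validation on the training side
(10×10 for the cell-level schemes, 3×10 for the patient-level scheme),
selecting the grid value with the best mean accuracy, ties to the
fewest components; grid values exceeding the fold-wise rank cap are
skipped. The 7:3 split is stratified per subtype with train size
rounded half up; leave-patient-out holds out every cell of one random
patient per subtype (the no-leakage contract is asserted in tests);
the patient-level scheme classifies per-patient mean profiles.

## Problem sizes and determinism

The default validation cohort is 15 case patients (6/4/5) + 16
controls × 3 cell types × 100 cells × 500 genes × 50 sets — large
enough that every planted structure is comfortably recoverable while a
full pipeline run stays under two minutes on one CPU. Every stochastic
operation takes an explicit seed; a rerun with the same configuration
and seed reproduces byte-identical output files (fixed float
formatting, sorted JSON keys, seeded k-means and splits).

## Known limitations

- The hurdle model is fixed-effects; cells from the same patient are
  treated as independent given covariates, which anticonservatively
  narrows standard errors on real data with strong per-individual
  offsets (the generator has none beyond batch/region). A
  pseudobulk-per-patient sensitivity analysis is the recommended
  companion on real cohorts.
- The rotation-cost criterion is an approximation (varimax alignment
  rather than explicit Givens-rotation search).
- The Fisher meta p-value ignores inter-gene dependence (see above).
- Only the Gaussian kernel CDF is implemented for set scoring; raw
  counts should be log-normalized first.
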