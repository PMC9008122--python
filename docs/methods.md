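# Methods

This note documents what the package computes, the assumptions behind
each stage, the defaults and why they were chosen, and what the
synthetic cohorts do and do not establish.

## Image model and preprocessing

A subject is a 3D Hounsfield-unit volume with anisotropic voxel spacing
and two binary segmentations: the gross tumour volume (GTV) and the
mesorectum (CTV), disjoint by construction. All geometry is physical:
spacings, perturbation radii and filter scales are millimetres, never
voxels, so 2.0 mm and 2.5 mm slice data are treated identically.

Before feature extraction, volumes are resampled to a 1 mm isotropic
grid (trilinear for the image, nearest-neighbour with re-binarization
for masks; the output lattice shares the input origin). The drawn
contour (*morphological mask*) is kept for shape features; for intensity
and texture features the contour is re-segmented by removing voxels with
HU strictly below −50 (*intensity mask*), which excises rectal air from
the region of interest. The comparison is strict: a voxel at exactly
−50 HU is retained.

Contour perturbation uses the exact Euclidean distance transform on a
2× trilinearly refined grid: the 0.5-isosurface places the contour
midway between boundary voxel centres rather than on them, which halves
the rasterization bias (a 10 mm rasterized ball dilated by 2 mm lands
within 3% of the analytic (12/10)³ volume ratio; a naive voxel
structuring element misses by ~7%). Dilation never removes a voxel and
erosion never adds one, so the nesting erode2 ⊆ erode1 ⊆ original ⊆
dilate1 ⊆ dilate2 and the closing property hold exactly.

## Feature engine

Per segmentation, 1130 features: 14 shape + 93 intensity/texture
statistics × 12 image types.

* **Discretization** — fixed bin width w = 10 HU anchored at the
  in-mask minimum: bin(x) = ⌊x/w⌋ − ⌊min/w⌋ + 1. Constant width keeps
  one gray level equal to the same absolute HU contrast across subjects,
  appropriate for a calibrated modality; a warning is raised when the
  bin count leaves [16, 128].
* **Shape** — marching-cubes mesh volume/surface (the binary mask is
  smoothed with a 0.8-voxel-equivalent physical Gaussian before meshing;
  hard binary input inflates the staircase surface and reads a sphere's
  sphericity ~9% low), voxel volume, sphericity, maximum 3D and three
  planar diameters, PCA axis lengths (4√λ), elongation, flatness.
  Degenerate single-voxel masks fall back to voxel-box quantities with
  elongation = flatness = 1.
* **Texture matrices** — built in 3D over the 13 unique distance-1
  directions (26-connectivity). GLCM and GLRLM statistics are computed
  per direction and averaged; GLSZM zones and GLDM dependences use
  26-connected neighbourhoods; GLDM dependence counts include the centre
  voxel (α = 0: equal levels only). Gray levels absent from the region
  are dropped from the matrices but surviving levels keep their integer
  values in level-weighted statistics. Zero-variance regions use
  continuity conventions: GLCM correlation = 1, NGTDM contrast = 0.
* **First order** — population moments on raw intensities; entropy and
  uniformity on the discretized histogram; kurtosis is the raw fourth
  standardized moment (3 for a Gaussian).
* **Filter bank** — original; Laplacian-of-Gaussian at σ = 1, 2, 3 mm
  via separable Gaussian/second-derivative kernels whose derivative
  kernel is re-centred to sum exactly to zero (a constant volume maps to
  exactly zero despite kernel truncation); and a single-level
  undecimated coiflet-1 wavelet decomposition applied per axis (8
  subbands at the input lattice size). The lowpass filter is normalized
  to unit DC gain, so the LLL band of a constant is that constant; the
  wavelet family is configurable. Shape is never computed on filtered
  images, and the intensity mask is always derived from the original HU
  image, not from filtered intensities.

## Robustness screening

Contouring variability: erode/dilate by 1 and 2 mm (4 variants), each
re-segmented against the HU floor before extraction. Scanner
variability: additive voxelwise noise — Gaussian (mean 20 HU, SD 20 HU),
Poisson (mean 20, hence variance 20), Uniform on [20 − 20√3, 20 + 20√3]
(mean 20, SD 20 HU) — five replicates each (15 volumes), clipped to the
valid scanner range [−1024, 3071] HU.

Agreement is ICC(2,1): two-way random effects, absolute agreement,
single measurement, treating variants as random raters; a zero-variance
table is defined as ICC = 1. A feature is robust when **both** the
contour-set ICC (original + 4) and the noise-set ICC (original + 15)
reach the threshold (default 0.7). The two perturbation families change
different things (the support vs the intensities), so the AND rule is
the conservative composition; a pooled single-ICC mode over all 20
tables is available as configuration. Shape features are exempt from the
noise criterion — intensity noise cannot move a fixed contour. GTV and
CTV features are screened independently.

## NAR models

The neoadjuvant rectal score NAR = [5·pN − 3·(cT − pT) + 12]²/9.61
summarizes downstaging; the binary endpoints are NAR > 16 (high risk)
and NAR < 8 (low risk). Candidate predictors are the robust radiomics
features plus age, cT, cN and CEA treated as continuous (CEA is
median-imputed when missing). Clinical candidates bypass the radiomics
reduction and are always offered to the final model.

Reduction and fit, in order: (1) greedy Spearman pruning — features are
walked in descending univariate label association (ties by name) and
dropped when |ρ| > 0.60 against an already-kept feature; (2) ReliefF —
k = 10 nearest hits/misses under Manhattan distance on [0, 1]-scaled
features over all instances, top 30 kept by default (both k and the
budget are configuration; the retention budget is not externally
prescribed); (3) L1-penalized logistic regression over a 50-point
geometric λ path from λ_max down to 10⁻³·λ_max, λ* chosen by minimum
mean tenfold cross-validated binomial deviance. Predictors are
standardized internally and coefficients reported on the original
scale. The probability cutoff maximizes Youden's J over midpoints of
observed scores, ties broken toward higher sensitivity; sensitivity,
specificity, PPV and NPV are reported at that cutoff.

Global importance is permutation-based: each column of the evaluation
table is shuffled n_repeats times and the mean AUC loss against the
unshuffled baseline is reported, on the union of features selected
across the outer folds.

## Survival models

Endpoints: locoregional-failure-free, distant-metastasis-free,
disease-free and overall survival. Clinical candidates add the
post-surgical covariates: adjuvant chemotherapy, surgical margin
(dummy-coded close/positive against clear), time from radiotherapy to
surgery, pT, pN, and the NAR score.

Univariate screening retains features with score-test P strictly below
0.1 from the per-feature Cox model at β = 0 — for a single covariate
this is the log-rank trend test, computed in closed form for all
columns at once. The radiomics branch is then Spearman-pruned (ordered
by screen P) and fit with L1-penalized Cox regression (Breslow ties);
its linear predictor is the **radiomics score**. Clinical and combined
(clinical + radiomics score) models are L2-penalized Cox fits. Both
penalized fits pick their penalty by minimum tenfold cross-validated
partial-likelihood deviance; at zero penalty the ridge fit reduces to
the ordinary Newton solution.

Discrimination is the IPCW cumulative/dynamic time-dependent AUC
(Uno-type; censoring distribution by Kaplan–Meier on the training
fold), evaluated on the grid of training-fold event times between the
5th and 95th follow-up percentiles, with the integrated AUC weighted by
the estimated event-time density. Kaplan–Meier curves and the standard
log-rank test support group comparisons such as NAR > 16 vs ≤ 16.

## Evaluation

Outer tenfold cross-validation is stratified on the binary label (NAR)
or event indicator (survival), so per-fold event counts differ by at
most one. Every selection step — screening, pruning, ReliefF,
standardization, penalty choice (inner tenfold CV with an independently
derived seed) — runs on the training fold only; the held-out fold is
used exactly once, to score the frozen model. The pipeline is
deterministic given the (cohort, fold, permutation) seeds, and the test
suite includes an adversarial leakage check: poisoning held-out rows of
a decoy feature leaves the training-fold fit bitwise unchanged.

Fold ROC curves are vertically averaged on a 0.01-step FPR grid; AUCs
are reported as mean ± SD over folds. The clinical-vs-combined contrast
per endpoint is a paired two-sided t-test on fold-wise AUCs with
Bonferroni correction over the four survival endpoints (adjusted
P = min(1, 4·P)).

## Synthetic cohorts

The generator exists so that every stage can be verified against a
planted truth. A latent aggressiveness a ~ N(0, 1) drives both the
tumour texture (correlation length 1.5·e^{0.25a} mm, SD 25·e^{0.15a} HU
of a Gaussian random field) and the outcome hazards, making "combined
beats clinical" a recoverable planted effect rather than an assumption.

* **Image tier** (`generate_cohort`) — ellipsoidal tumour (semi-axes
  8–14 mm) in a mesorectal shell (5–9 mm thick, separated by a ~1 mm
  moat so GTV ∩ CTV = ∅), an air lumen cylinder (−1000 HU) crossing the
  tumour contour, soft-tissue background around 45 HU, two scanner
  profiles (2.5 mm slices/noisier vs 2.0 mm/quieter, mixed ≈ 79/21).
* **Clinical tier** — staging frequencies match a realistic LARC
  population (cT2/3/4 ≈ 6/74/20%, cN0/1/2 ≈ 22/58/20%); CEA is
  log-normal (median 5.9 ng/mL, IQR ≈ 2.7–16) with 10% missing;
  pathology follows proportional-odds models: pT shifted by cT and a
  (loading 0.45), pN by cN and a (loading 0.80). The pN loading is
  deliberately the stronger one: the NAR formula weights nodal stage by
  5, so this is the channel through which image texture must reach the
  binary NAR endpoints, while the coarse pN ordinal passes only part of
  the signal to the clinical survival models. Event times are
  exponential with hazard h₀·mult(endpoint)·exp(β_tex·a + 0.3(cT−3) +
  0.5 pN + 0.6·positive-margin), h₀ = 0.004/month, censored by a uniform
  36–84-month follow-up window. Defaults (β_tex = 0.7 with the loadings
  above) were calibrated once so that the combined-minus-clinical
  integrated-AUC gap averages ≈ 0.03–0.05 at n = 200 while the planted
  feature stays recoverable; they are configuration, not constants.
* **Tabular tier** (`generate_feature_cohort`) — the modelling stages
  are exercised at n = 200 × many seeds, which is far beyond what full
  image extraction allows at desk scale; this tier emits the
  radiomics-like feature matrix directly: one planted CTV feature
  a + N(0, 0.4²), one weaker GTV feature 0.5a + N(0, 1), and ~28
  correlated-noise columns from a two-factor model (so Spearman pruning
  has real work). Statistical claims about the modelling stack
  (calibration, leakage, recovery) are made on this tier; claims about
  the extractor are made on the image tier.

What passing tests show — and do not show. The phantoms verify
arithmetic (feature counts, variant counts), estimator correctness
(against brute-force and from-scratch oracles), statistical calibration
(null screens retain ≈ α, permuted labels score AUC ≈ 0.5) and
recoverability of planted effects. They do not establish clinical
performance: real CT texture, real contouring variation and real
outcome biology are all richer than the generative model, and effect
sizes here are chosen, not discovered.

## Numerical choices and conventions

* ICC denominators ≤ 0 (possible with negative variance components) are
  mapped to the 0/1 boundary; zero-variance tables are ICC = 1.
* The L1 logistic solver is SAGA with an unpenalized intercept
  (objective: mean deviance/2 + λ‖w‖₁), warm-started along the path;
  path fits use a 10⁻⁵ tolerance (ranking λ only), final fits 10⁻⁸.
* Cox partial likelihoods use Breslow tie handling throughout, matching
  the penalized solvers they are compared against.
* Degenerate comparisons are explicit: zero-variance fold differences in
  the paired t-test report P = 1 (no shift) or 0 (constant shift) with a
  flag; single-valued score vectors make the Youden cutoff an error, not
  a guess.
* Desk-scale problem sizes: heavy statistical checks run on tabular
  cohorts of n = 200 over 10–20 seeds with 5-fold outer / 5-fold inner
  CV; the documented defaults (tenfold/tenfold) are used in the worked
  example and remain the recommended analysis settings.

## Known limitations

* The mesh-based shape features inherit marching-cubes lattice
  orientation effects (≲ 1% under axis permutation); voxel-count and
  PCA-based quantities are exact.
* The phantom lumen is a straight cylinder and the mesorectum a shell —
  adequate to exercise re-segmentation and disjointness, not anatomy.
* Proportional hazards are true by construction in the generator;
  violation diagnostics are out of scope.
* The univariate screen's score test and the log-rank test coincide
  exactly only for the no-ties continuous case; with heavy ties the
  Breslow approximation is used.
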