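# rectomics

CT-radiomics outcome modelling for locally advanced rectal cancer (LARC),
built as a tested, fully reproducible pipeline that runs end to end on
synthetic phantom cohorts.

Patients with LARC receive neoadjuvant chemoradiotherapy before total
mesorectal excision, but the markers that predict who benefits — the
neoadjuvant rectal (NAR) score, pathological stage — are only available
*after* surgery. Radiomics asks whether quantitative texture and shape
features of the pre-treatment planning CT, extracted from the tumour
(GTV) and the surrounding mesorectum (CTV), can predict those outcomes
up front. This package implements that analysis for researchers who want
to study, stress-test or extend it without access to patient data:

* **Feature engine** — IBSI-style radiomics: 14 shape descriptors plus
  93 first-order/texture statistics (GLCM, GLRLM, GLSZM, NGTDM, GLDM)
  over 12 image types (original, Laplacian-of-Gaussian at σ = 1, 2, 3 mm,
  8 wavelet subbands), i.e. **1130 features per segmentation**, after
  1 mm isotropic resampling, removal of intra-contour air below −50 HU,
  and fixed-bin-width (10 HU) discretization.
* **Robustness screen** — 4 contour variants (erode/dilate 1–2 mm) and
  15 noise-injected volumes (Gaussian / Poisson / Uniform, mean 20 HU,
  SD 20 HU where applicable, 5 replicates each); features kept only when
  ICC(2,1) ≥ 0.7 across both variant sets.
* **NAR models** — binary endpoints NAR > 16 (high risk) and NAR < 8
  (low risk), where NAR = [5·pN − 3·(cT − pT) + 12]²/9.61; Spearman
  pruning (|ρ| > 0.6), ReliefF ranking, L1-penalized logistic regression
  with tenfold CV-minimum-deviance λ, Youden operating point, and
  DALEX-style permutation importance.
* **Survival models** — LRFFS, DMFS, DFS, OS; univariate Cox screen
  (P < 0.1), LASSO-Cox **radiomics score**, ridge-Cox clinical and
  combined models; discrimination by IPCW time-dependent AUC and its
  event-density-weighted integral (iAUC).
* **Evaluation** — nested tenfold cross-validation with event-balanced
  folds and strictly leakage-free in-fold feature selection; paired
  t-tests with Bonferroni correction for the clinical-vs-combined
  contrast.
* **Synthetic cohorts** — a phantom generator producing CT-like volumes
  (textured ellipsoidal tumour, mesorectal shell, air lumen, two scanner
  profiles) and clinical tables whose outcomes depend on both stage and
  a latent texture parameter, so every claim the pipeline makes can be
  verified against planted ground truth.

## Worked example

```python
from rectomics import PhantomConfig, generate_feature_cohort, impute_cea
from rectomics.evaluation import (clinical_design, nested_cv_nar,
                                  nested_cv_survival, compare_models)

cfg = PhantomConfig(n_subjects=200, seed=42)
X, table = generate_feature_cohort(cfg)   # radiomics-like features + clinical table
table = impute_cea(table)                 # median-impute missing CEA

Xc = table[["age", "cT", "cN", "cea"]].astype(float)
res = nested_cv_nar(X, Xc, table["nar_gt16"].to_numpy(), k=10, seed=0)
print(f"NAR>16 model: AUC {res.mean_auc:.2f} +/- {res.sd_auc:.2f} over 10 folds")
print("top importance:", list(res.importance.index[:3]))

sres = nested_cv_survival(X, clinical_design(table),
                          table["os_months"], table["os_event"], k=10, seed=0)
m = sres.fold_iauc.mean()
cmp_ = compare_models(sres.fold_iauc["clinical"], sres.fold_iauc["combined"])
print(f"OS iAUC: clinical {m['clinical']:.2f}, radiomics {m['radiomics']:.2f}, "
      f"combined {m['combined']:.2f} (paired t P={cmp_['p_raw']:.3f})")
```

Output:

```
NAR>16 model: AUC 0.69 +/- 0.11 over 10 folds
top importance: ['original_glcm_Contrast_ctv', 'wavelet-LLL_firstorder_Kurtosis_ctv', 'wavelet-LHH_glszm_GrayLevelNonUniformityNormalized']
OS iAUC: clinical 0.69, radiomics 0.67, combined 0.73 (paired t P=0.073)
```

Reading this: the held-out AUC of 0.69 says the NAR>16 classifier
recovers real signal from the planted cohort; the permutation-importance
ranking surfaces the planted mesorectal texture feature
(`original_glcm_Contrast_ctv` — the `_ctv` suffix marks CTV features)
first; and adding the radiomics score to the clinical covariates lifts
the integrated time-dependent AUC for overall survival from 0.69 to
0.73. Numbers vary with the cohort seed.

The image-level pipeline has the same shape, one stage earlier:
`generate_cohort` writes volumes and masks, `volumes.resample_isotropic`
and `features.extract_all` turn them into 2260-column feature rows, and
`robustness.select_robust` screens them. A `rectomics` command-line
interface exposes the stages (`simulate`, `extract`, `robustness`,
`fit-nar`, `fit-survival`, `evaluate`, `run-all`) with plain
CSV/JSON/NIfTI artifacts and a digest-carrying run manifest.

## Layout

```
src/rectomics/
  volumes.py      NIfTI I/O, isotropic resampling, intensity re-segmentation,
                  mm-accurate morphological perturbation
  features/       discretization, shape, first-order, texture matrices,
                  LoG/wavelet filter bank, whole-subject extraction
  robustness.py   contour/noise variants, ICC(2,1), robust-feature selection
  synthetic.py    phantom cohort generator (image tier + tabular tier)
  nar.py          Spearman pruning, ReliefF, LASSO logistic, Youden,
                  permutation importance
  survival.py     NAR score, Cox screen, LASSO-/ridge-Cox, time-dependent AUC
  evaluation.py   event-balanced folds, nested CV, model comparison
  cli.py          typer CLI over the stages
docs/methods.md   model and procedure documentation
```
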