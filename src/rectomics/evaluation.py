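"""Nested cross-validation and model comparison.

Outer folds are stratified on the binary label (NAR models) or the event
indicator (survival models) so every fold carries its share of events;
all feature selection, standardization and penalty tuning happen strictly
inside the training fold — the test fold is touched only to score the
frozen model.  The inner tenfold CV that picks the penalty runs inside
each training fold with an independently derived seed.

The clinical-vs-combined contrast is a paired two-sided t-test on the
fold-wise AUCs with Bonferroni correction over the four survival
endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sksurv.util import Surv

from .nar import (
    NarPipelineConfig,
    averaged_roc,
    fit_nar_pipeline,
    permutation_importance,
)
from .survival import (
    LassoCoxScore,
    RidgeCox,
    default_eval_times,
    time_dependent_auc,
    univariate_cox_screen,
)
from .nar import spearman_prune

CLINICAL_SURVIVAL_FEATURES = (
    "age",
    "cT",
    "cN",
    "cea",
    "adjuvant_chemo_yes",
    "margin_close",
    "margin_positive",
    "time_rt_surgery_days",
    "pT",
    "pN",
    "nar",
)

__all__ = [
    "CLINICAL_SURVIVAL_FEATURES",
    "make_folds",
    "clinical_design",
    "nested_cv_nar",
    "nested_cv_survival",
    "compare_models",
    "NarCVResult",
    "SurvivalCVResult",
]


def make_folds(strata, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment; per-fold counts of the rarer class
    (events) differ by at most one.  Deterministic under a fixed seed."""
    strata = np.asarray(strata).astype(int)
    n_events = int(strata.sum()) if set(np.unique(strata)) <= {0, 1} else None
    if n_events is not None and n_events < k:
        raise ValueError(f"only {n_events} events for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(strata), dtype=int)
    for f, (_, te) in enumerate(skf.split(np.zeros(len(strata)), strata)):
        folds[te] = f
    return folds


def clinical_design(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric clinicopathologic design matrix.

    Margin is dummy-coded (close, positive) against a clear reference;
    adjuvant chemo is a yes-indicator; everything else is continuous.
    CEA must already be imputed.
    """
    if table["cea"].isna().any():
        raise ValueError("CEA has missing values; run impute_cea first")
    out = pd.DataFrame(index=table.index)
    for c in ("age", "cT", "cN", "cea", "time_rt_surgery_days", "pT", "pN", "nar"):
        out[c] = table[c].astype(float)
    out["adjuvant_chemo_yes"] = (table["adjuvant_chemo"] == "yes").astype(float)
    out["margin_close"] = (table["margin"] == "close").astype(float)
    out["margin_positive"] = (table["margin"] == "positive").astype(float)
    return out[list(CLINICAL_SURVIVAL_FEATURES)]


# ---------------------------------------------------------------------------
# NAR nested CV


@dataclass
class NarCVResult:
    fold_auc: np.ndarray
    fold_curves: list[tuple[np.ndarray, np.ndarray]]
    fold_features: list[list[str]]
    final_fit: object
    union_features: list[str]
    importance: pd.Series | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_auc, ddof=1))

    def averaged_roc(self):
        return averaged_roc(self.fold_curves)


def nested_cv_nar(
    X_radiomics: pd.DataFrame,
    X_clinical: pd.DataFrame,
    y,
    k: int = 10,
    seed: int = 0,
    config: NarPipelineConfig | None = None,
    compute_importance: bool = True,
) -> NarCVResult:
    """Outer k-fold CV of the full NAR pipeline plus a final whole-data fit.

    Per outer fold the entire reduction (prune, ReliefF, LASSO with inner
    tenfold lambda selection) is refit on the training part only.  The
    importance analysis permutes columns of the union of per-fold selected
    feature sets against the final model.
    """
    y = np.asarray(y).astype(int)
    ss = np.random.SeedSequence(seed)
    outer_seed, inner_seed, perm_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    config = config or NarPipelineConfig()
    config = NarPipelineConfig(
        spearman_threshold=config.spearman_threshold,
        relief_k=config.relief_k,
        relief_n_keep=config.relief_n_keep,
        cv=config.cv,
        random_state=inner_seed,
    )
    folds = make_folds(y, k, outer_seed)
    aucs, curves, feats = [], [], []
    for f in range(k):
        tr, te = folds != f, folds == f
        fit = fit_nar_pipeline(X_radiomics[tr], X_clinical[tr], y[tr], config)
        p = fit.predict_proba(X_radiomics[te], X_clinical[te])[:, 1]
        if y[te].min() == y[te].max():
            warnings.warn(f"fold {f} has one class; excluded", stacklevel=2)
            continue
        aucs.append(roc_auc_score(y[te], p))
        fpr, tpr, _ = roc_curve(y[te], p)
        curves.append((fpr, tpr))
        feats.append(fit.model.selected_features_)
    final = fit_nar_pipeline(X_radiomics, X_clinical, y, config)
    union = sorted(set().union(*feats)) if feats else []
    importance = None
    if compute_importance and union:
        X_all = pd.concat([X_radiomics, X_clinical], axis=1)[final.features]
        imp = permutation_importance(final.model, X_all, y, seed=perm_seed)
        importance = imp.loc[[c for c in imp.index if c in set(union)]]
    return NarCVResult(
        fold_auc=np.asarray(aucs),
        fold_curves=curves,
        fold_features=feats,
        final_fit=final,
        union_features=union,
        importance=importance,
    )


# ---------------------------------------------------------------------------
# survival nested CV


@dataclass
class SurvivalCVResult:
    fold_iauc: pd.DataFrame  # columns clinical / radiomics / combined
    final_models: dict
    fold_features: list[dict]

    def mean_sd(self, model: str) -> tuple[float, float]:
        v = self.fold_iauc[model].to_numpy()
        return float(v.mean()), float(v.std(ddof=1))


def _fit_survival_models(
    Xr: pd.DataFrame,
    Xc: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    alpha_screen: float,
    inner_cv: int,
    inner_seed: int,
):
    """Fit radiomics / clinical / combined models on one training set."""
    y = Surv.from_arrays(event.astype(bool), time)

    kept_r, p_r = univariate_cox_screen(Xr, time, event, alpha_screen)
    if not kept_r:
        kept_r = [p_r.idxmin()]
    order = list(p_r[kept_r].sort_values(kind="stable").index)
    pruned = spearman_prune(Xr[kept_r], threshold=0.6, order=order)
    lasso = LassoCoxScore(cv=inner_cv, random_state=inner_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lasso.fit(Xr[pruned], y)

    kept_c, p_c = univariate_cox_screen(Xc, time, event, alpha_screen)
    if not kept_c:
        kept_c = [p_c.idxmin()]
    clinical = RidgeCox(cv=inner_cv, random_state=inner_seed)
    clinical.fit(Xc[kept_c], y)

    score_tr = lasso.predict(Xr[pruned])
    Xcomb = Xc[kept_c].copy()
    Xcomb["radiomics_score"] = score_tr
    combined = RidgeCox(cv=inner_cv, random_state=inner_seed)
    combined.fit(Xcomb, y)

    def predict(which: str, Xr_new: pd.DataFrame, Xc_new: pd.DataFrame):
        if which == "radiomics":
            return lasso.predict(Xr_new[pruned])
        if which == "clinical":
            return clinical.predict(Xc_new[kept_c])
        Xn = Xc_new[kept_c].copy()
        Xn["radiomics_score"] = lasso.predict(Xr_new[pruned])
        return combined.predict(Xn)

    models = {"radiomics": lasso, "clinical": clinical, "combined": combined}
    features = {"radiomics": pruned, "clinical": kept_c}
    return models, features, predict


def nested_cv_survival(
    X_radiomics: pd.DataFrame,
    X_clinical: pd.DataFrame,
    time,
    event,
    k: int = 10,
    seed: int = 0,
    alpha_screen: float = 0.1,
    inner_cv: int = 10,
) -> SurvivalCVResult:
    """Outer k-fold CV of the three survival models for one endpoint.

    Per fold: screen + prune + LASSO-Cox radiomics score, ridge-Cox
    clinical and combined models, all on the training part; the held-out
    fold contributes one integrated time-dependent AUC per model.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ss = np.random.SeedSequence(seed)
    outer_seed, inner_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)
    )
    folds = make_folds(event, k, outer_seed)
    rows, feats = [], []
    for f in range(k):
        tr, te = folds != f, folds == f
        models, features, predict = _fit_survival_models(
            X_radiomics[tr], X_clinical[tr], time[tr], event[tr],
            alpha_screen, inner_cv, inner_seed,
        )
        feats.append(features)
        grid = default_eval_times(time[tr], event[tr])
        row = {}
        for which in ("clinical", "radiomics", "combined"):
            lp = predict(which, X_radiomics[te], X_clinical[te])
            try:
                _, _, iauc = time_dependent_auc(
                    lp, time[te], event[te], eval_times=grid,
                    train_time=time[tr], train_event=event[tr],
                )
            except ValueError:
                iauc = np.nan
            row[which] = iauc
        rows.append(row)
    fold_iauc = pd.DataFrame(rows).dropna()
    final_models, _, _ = _fit_survival_models(
        X_radiomics, X_clinical, time, event, alpha_screen, inner_cv, inner_seed
    )
    return SurvivalCVResult(
        fold_iauc=fold_iauc, final_models=final_models, fold_features=feats
    )


# ---------------------------------------------------------------------------
# model comparison


def compare_models(
    auc_a, auc_b, m_comparisons: int = 4
) -> dict[str, float]:
    """Paired two-sided t-test on fold-wise AUCs, Bonferroni-adjusted.

    ``m_comparisons`` defaults to the four survival endpoints.  Degenerate
    zero-variance differences give P = 1 (all-zero) or 0 (constant
    nonzero shift) with a flag.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = b - a
    degenerate = bool(np.allclose(d.std(ddof=1) if len(d) > 1 else 0.0, 0.0))
    if degenerate:
        p = 1.0 if np.allclose(d, 0.0) else 0.0
        t = 0.0 if np.allclose(d, 0.0) else np.inf * np.sign(d.mean())
    else:
        t, p = stats.ttest_rel(b, a)
        t, p = float(t), float(p)
    return {
        "mean_difference": float(d.mean()),
        "t_statistic": t,
        "p_raw": p,
        "p_adjusted": min(1.0, m_comparisons * p),
        "m_comparisons": m_comparisons,
        "degenerate": degenerate,
    }
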