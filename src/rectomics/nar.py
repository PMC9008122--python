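"""Binary NAR-endpoint classifiers (NAR > 16 high risk, NAR < 8 low risk).

Feature reduction runs in two stages — Spearman correlation pruning
(|rho| > 0.60 against an already-kept feature drops a feature) and ReliefF
ranking — before an L1-penalized logistic regression whose penalty is
chosen by tenfold cross-validated binomial deviance.  The operating point
on the probability scale is picked by Youden's index, and global feature
importance is measured by AUC loss under per-column permutation.

Clinical candidates (age, cT, cN, CEA, all treated as continuous) bypass
the radiomics reduction stages and are always offered to the LASSO.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

CLINICAL_NAR_FEATURES = ("age", "cT", "cN", "cea")

__all__ = [
    "CLINICAL_NAR_FEATURES",
    "spearman_prune",
    "SpearmanPruner",
    "relief_weights",
    "relief_rank",
    "ReliefFSelector",
    "LassoLogisticNar",
    "youden_operating_point",
    "averaged_roc",
    "permutation_importance",
    "NarPipelineConfig",
    "fit_nar_pipeline",
]


# ---------------------------------------------------------------------------
# Spearman pruning


def _association_order(X: pd.DataFrame, y) -> list[str]:
    """Columns by descending |Spearman rho| with the label, ties by name."""
    assoc = {}
    yv = np.asarray(y, dtype=float)
    for c in X.columns:
        rho = stats.spearmanr(X[c].to_numpy(), yv).statistic
        assoc[c] = 0.0 if np.isnan(rho) else abs(float(rho))
    return sorted(X.columns, key=lambda c: (-assoc[c], c))


def spearman_prune(
    X: pd.DataFrame,
    y=None,
    threshold: float = 0.60,
    order: list[str] | None = None,
) -> list[str]:
    """Greedy correlation pruning: walk features in a deterministic order
    and drop any with |Spearman rho| > threshold against a kept feature.

    The order is descending univariate label association (ties by name)
    when ``y`` is given, an explicit ``order`` when passed, else name order.
    """
    if order is None:
        order = _association_order(X, y) if y is not None else sorted(X.columns)
    if len(order) <= 1:
        return list(order)
    rho = pd.DataFrame(
        stats.spearmanr(X[order].to_numpy()).statistic
        if len(order) > 2
        else np.array(
            [[1.0, stats.spearmanr(X[order[0]], X[order[1]]).statistic], [0, 1.0]]
        ),
        index=order,
        columns=order,
    ).abs()
    kept: list[str] = []
    for c in order:
        if all(rho.loc[c, k] <= threshold or np.isnan(rho.loc[c, k]) for k in kept):
            kept.append(c)
    return kept


class SpearmanPruner(BaseEstimator):
    """sklearn-style transformer around :func:`spearman_prune`."""

    def __init__(self, threshold: float = 0.60):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        self.selected_ = spearman_prune(X, y, self.threshold)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_")
        return X[self.selected_]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


# ---------------------------------------------------------------------------
# ReliefF


def relief_weights(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 10
) -> np.ndarray:
    """Binary ReliefF weights.

    Features are min-max scaled to [0, 1]; every instance contributes its
    ``k`` nearest same-class hits and other-class misses under Manhattan
    distance.  Weight = mean miss-difference minus mean hit-difference, so
    informative features score positive and noise near zero.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    n, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Z = (X - X.min(axis=0)) / span
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("ReliefF here is defined for binary labels")
    k = k_neighbors
    if counts.min() - 1 < k:
        k = max(1, int(counts.min() - 1))
        warnings.warn(
            f"class too small for k={k_neighbors} neighbours; using k={k}",
            stacklevel=2,
        )
    dist = np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.inf)
    w = np.zeros(p)
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        other = np.flatnonzero(y != y[i])
        same = same[same != i]
        hits = same[np.argsort(dist[i, same], kind="stable")[:k]]
        misses = other[np.argsort(dist[i, other], kind="stable")[:k]]
        if misses.size:
            w += np.abs(Z[i] - Z[misses]).mean(axis=0)
        if hits.size:
            w -= np.abs(Z[i] - Z[hits]).mean(axis=0)
    return w / n


def relief_rank(
    X: pd.DataFrame, y, k_neighbors: int = 10, n_keep: int = 30
) -> tuple[list[str], pd.Series]:
    """Top ``n_keep`` features by ReliefF weight (descending, ties by name)."""
    w = pd.Series(
        relief_weights(X.to_numpy(dtype=np.float64), y, k_neighbors),
        index=X.columns,
        name="relief_weight",
    )
    ranked = w.sort_values(ascending=False, kind="stable")
    return list(ranked.index[:n_keep]), ranked


class ReliefFSelector(BaseEstimator):
    def __init__(self, k_neighbors: int = 10, n_keep: int = 30):
        self.k_neighbors = k_neighbors
        self.n_keep = n_keep

    def fit(self, X: pd.DataFrame, y):
        self.selected_, self.weights_ = relief_rank(
            X, y, self.k_neighbors, self.n_keep
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_")
        return X[self.selected_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


# ---------------------------------------------------------------------------
# LASSO logistic regression with CV-min-deviance penalty


class LassoLogisticNar(ClassifierMixin, BaseEstimator):
    """L1-penalized logistic regression over a lambda path.

    Predictors are standardized internally; ``coef_`` is reported on the
    original feature scale.  ``lambda_`` minimizes the mean tenfold
    cross-validated binomial deviance.  With ``lambda`` forced high the
    model collapses to intercept = logit(prevalence).
    """

    def __init__(
        self,
        n_lambdas: int = 50,
        lambda_min_ratio: float = 1e-3,
        cv: int = 10,
        random_state: int = 0,
        fixed_lambda: float | None = None,
    ):
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.random_state = random_state
        self.fixed_lambda = fixed_lambda

    def _path(self, n: int, Z: np.ndarray, y: np.ndarray) -> np.ndarray:
        lam_max = np.abs(Z.T @ (y - y.mean())).max() / n
        lam_max = max(lam_max, 1e-6)
        return np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambdas)

    @staticmethod
    def _fit_at(Z, y, lam, model=None, tol=1e-8):
        """One L1 fit at penalty ``lam``; objective is mean binomial
        deviance/2 + lam * ||w||_1 with an unpenalized intercept (saga).
        Pass a warm-started ``model`` to continue along a path."""
        n = len(y)
        if lam >= np.abs(Z.T @ (y - y.mean())).max() / n:
            # fully penalized: intercept-only
            b0 = float(np.log(y.mean() / (1 - y.mean())))
            return np.zeros(Z.shape[1]), b0, model
        if model is None:
            model = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / (n * lam),
                solver="saga",
                max_iter=20000,
                tol=tol,
                warm_start=True,
                random_state=0,
            )
        else:
            model.set_params(C=1.0 / (n * lam))
        model.fit(Z, y)
        return model.coef_.ravel().copy(), float(model.intercept_[0]), model

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary labels required")
        Xv = X.to_numpy(dtype=np.float64)
        self.feature_names_in_ = np.asarray(X.columns)
        self.mean_ = Xv.mean(axis=0)
        self.scale_ = Xv.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Z = (Xv - self.mean_) / self.scale_
        n = len(y)

        min_class = int(np.bincount(y).min())
        if self.fixed_lambda is not None:
            lambdas = np.array([self.fixed_lambda])
            best = 0
        elif min_class < 2 or n < 2 * self.cv // 2 + 2:
            # too few samples per class to cross-validate: take a mid-path
            # penalty rather than failing outright
            warnings.warn(
                "too few samples to cross-validate lambda; using a mid-path "
                "penalty",
                stacklevel=2,
            )
            lambdas = self._path(n, Z, y)
            best = len(lambdas) // 2
        else:
            lambdas = self._path(n, Z, y)
            n_splits = min(self.cv, min_class)
            skf = StratifiedKFold(
                n_splits=n_splits, shuffle=True, random_state=self.random_state
            )
            dev = np.zeros((n_splits, len(lambdas)))
            for f, (tr, te) in enumerate(skf.split(Z, y)):
                if y[tr].min() == y[tr].max():  # pragma: no cover - restratified
                    raise RuntimeError("fold without both classes")
                warm = None
                for j, lam in enumerate(lambdas):
                    # the CV path only ranks lambdas; a looser tolerance is
                    # plenty and several-fold faster
                    coef, b0, warm = self._fit_at(Z[tr], y[tr], lam, warm, tol=1e-5)
                    p = 1.0 / (1.0 + np.exp(-(Z[te] @ coef + b0)))
                    dev[f, j] = 2.0 * log_loss(y[te], p, labels=[0, 1], normalize=False)
            best = int(np.argmin(dev.mean(axis=0)))
            self.cv_deviance_ = dev.mean(axis=0)
        self.lambda_path_ = lambdas
        self.lambda_ = float(lambdas[best])
        coef_std, b0, _ = self._fit_at(Z, y, self.lambda_)
        self.coef_std_ = coef_std
        self.intercept_std_ = b0
        self.coef_ = coef_std / self.scale_
        self.intercept_ = b0 - float(self.mean_ @ self.coef_)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Xv = X[list(self.feature_names_in_)].to_numpy(dtype=np.float64)
        Z = (Xv - self.mean_) / self.scale_
        return Z @ self.coef_std_ + self.intercept_std_

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    @property
    def selected_features_(self) -> list[str]:
        check_is_fitted(self, "coef_")
        return [f for f, c in zip(self.feature_names_in_, self.coef_std_) if c != 0]


# ---------------------------------------------------------------------------
# Operating point, ROC averaging, permutation importance


def youden_operating_point(scores, labels) -> dict[str, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between consecutive distinct scores; ties are
    broken toward higher sensitivity (the lower cutoff).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("degenerate scores: cutoff undefined")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for c in cuts:
        pred = scores >= c
        tp = int((pred & (labels == 1)).sum())
        fn = int((~pred & (labels == 1)).sum())
        tn = int((~pred & (labels == 0)).sum())
        fp = int((pred & (labels == 0)).sum())
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        # strict improvement, or equal J with higher sensitivity
        if best is None or j > best["youden"] + 1e-12 or (
            abs(j - best["youden"]) <= 1e-12 and sens > best["sensitivity"]
        ):
            ppv = tp / (tp + fp) if tp + fp else 0.0
            npv = tn / (tn + fn) if tn + fn else 0.0
            best = {
                "cutoff": float(c),
                "sensitivity": sens,
                "specificity": spec,
                "ppv": ppv,
                "npv": npv,
                "youden": j,
            }
    return best


def averaged_roc(
    per_fold: list[tuple[np.ndarray, np.ndarray]], grid_step: float = 0.01
):
    """Vertically average fold ROC curves on a fixed FPR grid.

    ``per_fold``: list of (fpr, tpr) arrays.  Returns ``(grid, mean_tpr,
    sd_tpr)``; folds whose curve is degenerate (single class) should be
    excluded upstream.
    """
    if len(per_fold) < 2:
        raise ValueError("need at least two fold curves")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    tprs = []
    for fpr, tpr in per_fold:
        tprs.append(np.interp(grid, fpr, tpr))
    tprs = np.asarray(tprs)
    return grid, tprs.mean(axis=0), tprs.std(axis=0)


def permutation_importance(
    model,
    X: pd.DataFrame,
    y,
    seed: int = 0,
    n_repeats: int = 10,
) -> pd.Series:
    """Mean AUC loss when one column at a time is shuffled (DALEX-style)."""
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    base = roc_auc_score(y, model.predict_proba(X)[:, 1])
    losses = {}
    for col in X.columns:
        drop = np.zeros(n_repeats)
        for r in range(n_repeats):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            drop[r] = base - roc_auc_score(y, model.predict_proba(Xp)[:, 1])
        losses[col] = float(drop.mean())
    return pd.Series(losses, name="auc_loss").sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Assembled NAR pipeline (prune -> relief -> lasso) for one training set


@dataclass
class NarPipelineConfig:
    spearman_threshold: float = 0.60
    relief_k: int = 10
    relief_n_keep: int = 30
    cv: int = 10
    random_state: int = 0


@dataclass
class NarFit:
    model: LassoLogisticNar
    radiomics_selected: list[str]
    features: list[str]

    def predict_proba(self, X_radiomics: pd.DataFrame, X_clinical: pd.DataFrame):
        X = pd.concat([X_radiomics, X_clinical], axis=1)[self.features]
        return self.model.predict_proba(X)


def fit_nar_pipeline(
    X_radiomics: pd.DataFrame,
    X_clinical: pd.DataFrame,
    y,
    config: NarPipelineConfig | None = None,
) -> NarFit:
    """Radiomics reduction (Spearman prune then ReliefF) + clinical
    passthrough, then LASSO logistic regression."""
    config = config or NarPipelineConfig()
    y = np.asarray(y).astype(int)
    kept = spearman_prune(X_radiomics, y, config.spearman_threshold)
    ranked, _ = relief_rank(
        X_radiomics[kept], y, config.relief_k, config.relief_n_keep
    )
    X = pd.concat([X_radiomics[ranked], X_clinical], axis=1)
    model = LassoLogisticNar(cv=config.cv, random_state=config.random_state)
    model.fit(X, y)
    return NarFit(model=model, radiomics_selected=ranked, features=list(X.columns))
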