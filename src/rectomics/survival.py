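"""Survival modelling: NAR score, Cox screening and penalized Cox models.

Three models per endpoint (LRFFS, DMFS, DFS, OS):

* *radiomics* — univariate Cox screen (P < 0.1) and Spearman pruning of the
  robust radiomics features, then an L1-penalized Cox fit whose linear
  predictor is the **radiomics score**;
* *clinical* — screened clinicopathologic covariates in an L2-penalized
  (ridge) Cox model;
* *combined* — the clinical covariates plus the radiomics score, ridge Cox.

Penalty strength is chosen by tenfold cross-validated partial-likelihood
deviance in both penalized fits.  Discrimination is measured with the
IPCW cumulative/dynamic time-dependent AUC and its event-density-weighted
integral (iAUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

ENDPOINTS = ("lrffs", "dmfs", "dfs", "os")

__all__ = [
    "ENDPOINTS",
    "nar_score",
    "nar_classes",
    "univariate_cox_screen",
    "UnivariateCoxScreen",
    "LassoCoxScore",
    "RidgeCox",
    "time_dependent_auc",
    "km_logrank",
    "cox_partial_loglik",
]

# NAR formula constants: [5 pN - 3 (cT - pT) + 12]^2 / 9.61
_NAR_DENOM = 9.61


def nar_score(cT, pT, pN):
    """Neoadjuvant rectal score from clinical T and pathological T/N stage.

    ``[5 pN - 3 (cT - pT) + 12]^2 / 9.61`` — a validated surrogate
    endpoint: downstaging (pT < cT) and node negativity lower the score.
    """
    cT = np.asarray(cT)
    pT = np.asarray(pT)
    pN = np.asarray(pN)
    if np.any((cT < 1) | (cT > 4)):
        raise ValueError("cT must be in 1..4")
    if np.any((pT < 0) | (pT > 4)):
        raise ValueError("pT must be in 0..4")
    if np.any((pN < 0) | (pN > 2)):
        raise ValueError("pN must be in 0..2")
    score = (5.0 * pN - 3.0 * (cT - pT) + 12.0) ** 2 / _NAR_DENOM
    return score if score.ndim else float(score)


def nar_classes(score):
    """Binary endpoint labels: high risk (NAR > 16) and low risk (NAR < 8)."""
    score = np.asarray(score, dtype=float)
    return score > 16.0, score < 8.0


# ---------------------------------------------------------------------------
# Partial likelihood utilities (Breslow tie handling)


def cox_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a linear predictor."""
    order = np.argsort(time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    # risk-set denominator: suffix logsumexp over subjects with time >= t_i
    rev = np.log(np.cumsum(np.exp(lp - lp.max())[::-1]))[::-1] + lp.max()
    # ties share the risk set of the first tied index
    first = np.searchsorted(time, time, side="left")
    ll = lp[event == 1].sum() - rev[first][event == 1].sum()
    return float(ll)


def _score_test(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Vectorized per-column Cox score test at beta = 0.

    For a single covariate this is the log-rank trend test; returns the
    two-sided P-value per column.
    """
    order = np.argsort(time, kind="stable")
    X, time, event = X[order], time[order], event[order]
    n = len(time)
    first = np.searchsorted(time, time, side="left")
    # suffix sums over the risk set
    s0 = (n - np.arange(n)).astype(np.float64)
    s1 = np.cumsum(X[::-1], axis=0)[::-1]
    s2 = np.cumsum((X**2)[::-1], axis=0)[::-1]
    ev = np.flatnonzero(event == 1)
    r = first[ev]
    m = s1[r] / s0[r, None]
    v = s2[r] / s0[r, None] - m**2
    u = (X[ev] - m).sum(axis=0)
    var = v.sum(axis=0)
    chi2 = np.divide(u**2, var, out=np.zeros_like(var), where=var > 0)
    return stats.chi2.sf(chi2, df=1)


def univariate_cox_screen(
    X: pd.DataFrame, time, event, alpha: float = 0.1
) -> tuple[list[str], pd.Series]:
    """Retain features with a univariate Cox score-test P strictly < alpha.

    The score test at beta=0 coincides with the log-rank (trend) test for
    the covariate, computed in closed form for every column at once.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events")
    if event.sum() < 10:
        warnings.warn(
            f"only {int(event.sum())} events; univariate screen is unstable",
            stacklevel=2,
        )
    p = pd.Series(
        _score_test(X.to_numpy(dtype=np.float64), time, event),
        index=X.columns,
        name="p",
    )
    kept = list(p.index[p < alpha])
    return kept, p


class UnivariateCoxScreen(BaseEstimator):
    """sklearn-style transformer wrapping :func:`univariate_cox_screen`.

    ``y`` is a structured survival array (sksurv convention).
    """

    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y):
        time, event = y[y.dtype.names[1]], y[y.dtype.names[0]].astype(int)
        self.selected_, self.pvalues_ = univariate_cox_screen(
            X, time, event, self.alpha
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_")
        return X[self.selected_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


# ---------------------------------------------------------------------------
# Penalized Cox fits with CV-min-deviance penalty selection


def _cv_deviance_alpha(
    fit_path,  # callable(train_idx) -> (alphas, coef_matrix [p, n_alphas])
    predict_lp,  # callable(coefs, idx) -> lp
    alphas: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    cv: int,
    seed: int,
) -> int:
    """Index of the alpha minimizing mean held-out partial-likelihood deviance."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    dev = np.zeros((cv, len(alphas)))
    for f, (tr, te) in enumerate(skf.split(np.zeros(len(time)), event)):
        coefs = fit_path(tr)
        for a in range(len(alphas)):
            lp = predict_lp(coefs[:, a], te)
            dev[f, a] = -2.0 * cox_partial_loglik(lp, time[te], event[te])
    return int(np.argmin(dev.mean(axis=0)))


class LassoCoxScore(BaseEstimator):
    """L1-penalized Cox model producing the per-subject radiomics score.

    Predictors are standardized internally; coefficients are reported on
    the original feature scale.  The penalty is chosen by tenfold
    cross-validated partial-likelihood deviance (minimum-deviance rule).
    """

    def __init__(
        self, cv: int = 10, n_alphas: int = 50, random_state: int = 0, alphas=None
    ):
        self.cv = cv
        self.n_alphas = n_alphas
        self.random_state = random_state
        self.alphas = alphas  # explicit path overrides the data-driven one

    def fit(self, X: pd.DataFrame, y):
        Xv = X.to_numpy(dtype=np.float64)
        time = y[y.dtype.names[1]].astype(float)
        event = y[y.dtype.names[0]].astype(int)
        self.feature_names_in_ = np.asarray(X.columns)
        self.mean_ = Xv.mean(axis=0)
        self.scale_ = Xv.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Z = (Xv - self.mean_) / self.scale_

        if self.alphas is not None:
            alphas = np.asarray(self.alphas, dtype=float)
            path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
            path.fit(Z, y)
        else:
            path = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, n_alphas=self.n_alphas, alpha_min_ratio=0.01
            )
            path.fit(Z, y)
            alphas = np.asarray(path.alphas_)

        def fit_path(tr):
            m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(Z[tr], y[tr])
            out = np.zeros((Z.shape[1], len(alphas)))
            got = m.coef_
            # coxnet may drop path tail; align on fitted alphas
            fitted = {round(a, 12): i for i, a in enumerate(m.alphas_)}
            for i, a in enumerate(alphas):
                j = fitted.get(round(a, 12))
                if j is not None:
                    out[:, i] = got[:, j]
                elif i > 0:
                    out[:, i] = out[:, i - 1]
            return out

        if len(alphas) > 1:
            best = _cv_deviance_alpha(
                fit_path,
                lambda c, idx: Z[idx] @ c,
                alphas,
                time,
                event,
                self.cv,
                self.random_state,
            )
        else:
            best = 0
        self.alpha_ = float(alphas[best])
        coef_std = path.coef_[:, best]
        self.coef_std_ = coef_std
        self.coef_ = coef_std / self.scale_
        self.intercept_ = -float(self.mean_ @ self.coef_)
        if not np.any(coef_std):
            warnings.warn(
                "all LASSO-Cox coefficients are zero at the selected penalty; "
                "the radiomics score is constant",
                stacklevel=2,
            )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """The radiomics score (Cox linear predictor)."""
        check_is_fitted(self, "coef_")
        Xv = X[list(self.feature_names_in_)].to_numpy(dtype=np.float64)
        return ((Xv - self.mean_) / self.scale_) @ self.coef_std_

    @property
    def selected_features_(self) -> list[str]:
        check_is_fitted(self, "coef_")
        return [f for f, c in zip(self.feature_names_in_, self.coef_std_) if c != 0]


class RidgeCox(BaseEstimator):
    """L2-penalized Cox model with CV-min-deviance penalty selection.

    ``alphas=None`` scans a log grid including (near-)zero penalty; at
    zero penalty this is the ordinary Newton partial-likelihood fit.
    """

    def __init__(self, alphas=None, cv: int = 10, random_state: int = 0):
        self.alphas = alphas
        self.cv = cv
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        Xv = X.to_numpy(dtype=np.float64)
        time = y[y.dtype.names[1]].astype(float)
        event = y[y.dtype.names[0]].astype(int)
        self.feature_names_in_ = np.asarray(X.columns)
        self.mean_ = Xv.mean(axis=0)
        self.scale_ = Xv.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Z = (Xv - self.mean_) / self.scale_
        alphas = (
            np.asarray(self.alphas, dtype=float)
            if self.alphas is not None
            else np.concatenate([[1e-8], np.logspace(-3, 2, 11)])
        )

        def fit_at(tr, alpha):
            m = CoxPHSurvivalAnalysis(alpha=max(alpha, 1e-12), n_iter=200)
            m.fit(Z[tr], y[tr])
            return m.coef_

        def fit_path(tr):
            cols = []
            for a in alphas:
                try:
                    cols.append(fit_at(tr, a))
                except Exception:
                    cols.append(np.zeros(Z.shape[1]))
            return np.column_stack(cols)

        if len(alphas) > 1:
            best = _cv_deviance_alpha(
                fit_path,
                lambda c, idx: Z[idx] @ c,
                alphas,
                time,
                event,
                self.cv,
                self.random_state,
            )
        else:
            best = 0
        self.alpha_ = float(alphas[best])
        self.coef_std_ = fit_at(np.arange(len(time)), self.alpha_)
        self.coef_ = self.coef_std_ / self.scale_
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Xv = X[list(self.feature_names_in_)].to_numpy(dtype=np.float64)
        return ((Xv - self.mean_) / self.scale_) @ self.coef_std_


# ---------------------------------------------------------------------------
# Time-dependent AUC and Kaplan-Meier


def default_eval_times(time, event, lo_pct: float = 5.0, hi_pct: float = 95.0):
    """Event times between the 5th and 95th percentile of follow-up."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lo, hi = np.percentile(time, [lo_pct, hi_pct])
    ts = np.unique(time[(event == 1) & (time > lo) & (time < hi)])
    return ts


def time_dependent_auc(
    lp,
    time,
    event,
    eval_times=None,
    train_time=None,
    train_event=None,
):
    """IPCW cumulative/dynamic AUC(t) and its integrated value.

    The censoring distribution is estimated by Kaplan-Meier on the
    training data (or the evaluation data itself when none is given); the
    integrated AUC is the event-density-weighted average over the grid.
    Returns ``(eval_times, auc_curve, integrated_auc)``.
    """
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if train_time is None:
        train_time, train_event = time, event
    train_time = np.asarray(train_time, dtype=float)
    train_event = np.asarray(train_event, dtype=int)
    if eval_times is None:
        eval_times = default_eval_times(train_time, train_event)
    eval_times = np.asarray(eval_times, dtype=float)
    # drop grid points outside the comparable range of the test fold
    tmax = time.max()
    keep = (eval_times < tmax) & (eval_times >= time.min())
    keep &= np.array([np.any((time <= t) & (event == 1)) for t in eval_times])
    eval_times = eval_times[keep]
    if eval_times.size == 0:
        raise ValueError("no evaluable time point in the test fold")
    y_train = Surv.from_arrays(train_event.astype(bool), train_time)
    y_test = Surv.from_arrays(event.astype(bool), time)
    auc, mean_auc = cumulative_dynamic_auc(y_train, y_test, lp, eval_times)
    good = np.isfinite(auc)
    if eval_times[good].size == 0:
        raise ValueError("time-dependent AUC undefined on the whole grid")
    if not np.all(good):
        # recompute the integral on the finite part
        auc_f, mean_auc = cumulative_dynamic_auc(
            y_train, y_test, lp, eval_times[good]
        )
        return eval_times[good], auc_f, float(mean_auc)
    return eval_times, auc, float(mean_auc)


def km_logrank(time, event, group):
    """Product-limit curves per group plus the log-rank test.

    Returns ``(curves, statistic, p_value)`` with ``curves`` a dict
    group -> fitted :class:`~lifelines.KaplanMeierFitter`.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) < 2:
        raise ValueError("log-rank needs at least two groups")
    curves = {}
    for g in labels:
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(time[group == g], event[group == g])
        curves[g] = kmf
    res = multivariate_logrank_test(time, group, event)
    return curves, float(res.test_statistic), float(res.p_value)
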