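"""NAR score, Cox screening, penalized Cox fits, time-dependent AUC and
Kaplan-Meier/log-rank — against hand computations and independent
optimizers."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from sksurv.util import Surv

from rectomics.survival import (
    LassoCoxScore,
    RidgeCox,
    cox_partial_loglik,
    km_logrank,
    nar_score,
    time_dependent_auc,
    univariate_cox_screen,
)


class TestNarScore:
    @pytest.mark.parametrize(
        "cT,pT,pN,expected",
        [
            (4, 0, 0, 0.0),           # the bracket vanishes
            (3, 0, 0, 9 / 9.61),      # 3^2 / 9.61 ~ 0.94
            (3, 3, 1, 289 / 9.61),    # 17^2 / 9.61 ~ 30.07
        ],
    )
    def test_direct_formula_evaluation(self, cT, pT, pN, expected):
        assert nar_score(cT, pT, pN) == pytest.approx(expected)

    def test_printed_values(self):
        assert nar_score(3, 0, 0) == pytest.approx(0.94, abs=0.005)
        assert nar_score(3, 3, 1) == pytest.approx(30.07, abs=0.005)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            nar_score(5, 0, 0)
        with pytest.raises(ValueError):
            nar_score(3, 0, 3)


def _hand_logrank_binary(time, event, x):
    """Explicit log-rank statistic for a binary covariate (group 1 vs 0)."""
    times = np.unique(time[event == 1])
    o_minus_e, var = 0.0, 0.0
    for t in times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (x == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (x == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestUnivariateScreen:
    def test_planted_signal_retained(self, rng):
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(1.5 * x)))
        X = pd.DataFrame({"planted": x, "noise": rng.normal(size=n)})
        kept, p = univariate_cox_screen(X, t, np.ones(n, dtype=int))
        assert "planted" in kept
        assert p["planted"] < 1e-6

    def test_null_retention_rate_near_alpha(self, rng):
        n, m = 300, 100
        t = rng.exponential(20.0, size=n)
        e = (rng.uniform(size=n) < 0.5).astype(int)
        X = pd.DataFrame(rng.normal(size=(n, m)), columns=[f"f{i}" for i in range(m)])
        kept, _ = univariate_cox_screen(X, t, e, alpha=0.1)
        assert 0.05 <= len(kept) / m <= 0.15

    def test_binary_covariate_matches_hand_logrank(self):
        time = np.array([2.0, 4.0, 5.0, 7.0, 9.0, 12.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        from scipy import stats as sps

        chi2_hand = _hand_logrank_binary(time, event, x)
        p_hand = sps.chi2.sf(chi2_hand, df=1)
        _, p = univariate_cox_screen(pd.DataFrame({"x": x}), time, event, alpha=1.1)
        assert p["x"] == pytest.approx(p_hand, abs=1e-6)

    def test_few_events_warns(self, rng):
        n = 30
        t = rng.exponential(20, n)
        e = np.zeros(n, dtype=int)
        e[:4] = 1
        with pytest.warns(UserWarning, match="events"):
            univariate_cox_screen(pd.DataFrame({"x": rng.normal(size=n)}), t, e)


def _surv(time, event):
    return Surv.from_arrays(np.asarray(event, bool), np.asarray(time, float))


def _prox_grad_lasso_cox(Z, time, event, lam, n_iter=200000, lr=0.01):
    """Proximal gradient on the coxnet objective:
    -(1/n) Breslow log PL + lam * ||b||_1."""
    n, p = Z.shape
    b = np.zeros(p)
    order = np.argsort(time, kind="stable")
    Zs, ts, es = Z[order], time[order], event[order]
    first = np.searchsorted(ts, ts, side="left")
    ev = np.flatnonzero(es == 1)

    def grad(b):
        eta = Zs @ b
        w = np.exp(eta)
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * Zs)[::-1], axis=0)[::-1]
        g = -(Zs[ev] - s1[first[ev]] / s0[first[ev], None]).sum(axis=0) / n
        return g

    for _ in range(n_iter):
        b_new = b - lr * grad(b)
        b_new = np.sign(b_new) * np.maximum(np.abs(b_new) - lr * lam, 0.0)
        if np.max(np.abs(b_new - b)) < 1e-12:
            b = b_new
            break
        b = b_new
    return b


class TestLassoCox:
    def test_fully_penalized_limit_constant_score(self, rng):
        n = 40
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        t = rng.exponential(10, n)
        m = LassoCoxScore(alphas=[1e4])
        with pytest.warns(UserWarning, match="constant"):
            m.fit(X, _surv(t, np.ones(n)))
        assert np.all(m.coef_std_ == 0)
        assert np.ptp(m.predict(X)) == 0.0

    def test_planted_prognostic_sign(self, rng):
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(1.0 * x)))
        X = pd.DataFrame({"planted": x, "noise": rng.normal(size=n)})
        m = LassoCoxScore(cv=5).fit(X, _surv(t, np.ones(n)))
        assert m.coef_std_[0] > 0

    def test_matches_proximal_gradient_oracle_at_fixed_lambda(self, rng):
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        n, lam = 8, 0.05
        Z = rng.normal(size=(n, 2))
        Z = (Z - Z.mean(0)) / Z.std(0)
        time = np.array([3.0, 5.0, 6.0, 8.0, 10.0, 12.0, 15.0, 20.0])
        event = np.array([1, 1, 1, 1, 1, 1, 1, 1])
        time = time * np.exp(-0.5 * Z[:, 0])
        net = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[lam], tol=1e-12)
        net.fit(Z, _surv(time, event))
        b_ref = _prox_grad_lasso_cox(Z, time, event, lam)
        np.testing.assert_allclose(net.coef_.ravel(), b_ref, atol=1e-5)


class TestRidgeCox:
    def test_large_penalty_shrinks_to_zero(self, rng):
        n = 60
        X = pd.DataFrame({"x": rng.normal(size=n)})
        t = rng.exponential(1.0 / (0.05 * np.exp(X["x"])))
        m = RidgeCox(alphas=[1e6]).fit(X, _surv(t, np.ones(n)))
        assert abs(m.coef_std_[0]) < 1e-3

    def test_duplicated_covariate_splits_effect(self, rng):
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.8 * x)))
        y = _surv(t, np.ones(n))
        single = RidgeCox(alphas=[1.0]).fit(pd.DataFrame({"x": x}), y)
        double = RidgeCox(alphas=[1.0]).fit(pd.DataFrame({"x1": x, "x2": x}), y)
        # ridge symmetry: the two copies share the effect equally
        assert double.coef_std_[0] == pytest.approx(double.coef_std_[1], rel=1e-4)

    def test_zero_penalty_matches_newton_partial_likelihood(self, rng):
        n = 30
        x = rng.normal(size=n)
        time = np.sort(rng.exponential(1.0 / (0.1 * np.exp(0.7 * x))))
        event = np.ones(n, dtype=int)
        m = RidgeCox(alphas=[0.0]).fit(pd.DataFrame({"x": x}), _surv(time, event))
        z = (x - x.mean()) / x.std()

        def negll(b):
            return -cox_partial_loglik(b[0] * z, time, event)

        b_ref = optimize.minimize_scalar(lambda b: negll([b])).x
        assert m.coef_std_[0] == pytest.approx(b_ref, abs=1e-6)


class TestTimeDependentAuc:
    def test_null_predictor_near_half(self, rng):
        n = 500
        t = rng.exponential(20, n)
        e = (rng.uniform(size=n) < 0.7).astype(int)
        lp = rng.normal(size=n)
        _, auc, iauc = time_dependent_auc(lp, t, e)
        assert iauc == pytest.approx(0.5, abs=0.05)
        assert np.nanmean(auc) == pytest.approx(0.5, abs=0.05)

    def test_perfect_ranking_uncensored(self):
        t = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        e = np.ones(6, dtype=int)
        times, auc, iauc = time_dependent_auc(-t, t, e, eval_times=[3, 5, 7, 9, 11])
        np.testing.assert_allclose(auc, 1.0)
        assert iauc == pytest.approx(1.0)

    def test_matches_pair_counting_uncensored(self):
        # 6 uncensored subjects, arbitrary predictor; AUC(t*) is the
        # fraction of concordant (case, control) pairs at t*
        t = np.array([1.0, 3.0, 4.0, 6.0, 9.0, 11.0])
        e = np.ones(6, dtype=int)
        lp = np.array([0.3, 2.0, -1.0, 0.5, -0.2, 0.1])
        for tstar in (2.0, 5.0, 10.0):
            cases = t <= tstar
            controls = ~cases
            pairs = concordant = 0
            for i in np.flatnonzero(cases):
                for j in np.flatnonzero(controls):
                    pairs += 1
                    if lp[i] > lp[j]:
                        concordant += 1
                    elif lp[i] == lp[j]:
                        concordant += 0.5
            _, auc, _ = time_dependent_auc(lp, t, e, eval_times=[tstar])
            assert auc[0] == pytest.approx(concordant / pairs)


class TestKaplanMeierLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([2.0, 4.0, 6.0, 2.0, 4.0, 6.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        _, stat, p = km_logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_fixture_matches(self):
        t = np.array([2.0, 4.0, 5.0, 7.0, 9.0, 12.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        g = np.array([1, 0, 1, 0, 1, 0])
        chi2_hand = _hand_logrank_binary(t, e, g)
        _, stat, _ = km_logrank(t, e, g)
        assert stat == pytest.approx(chi2_hand, rel=1e-6)

    def test_survival_is_one_at_time_zero(self):
        t = np.array([5.0, 7.0, 9.0, 4.0, 6.0, 8.0])
        e = np.ones(6, dtype=int)
        g = np.array([0, 0, 0, 1, 1, 1])
        curves, _, _ = km_logrank(t, e, g)
        for kmf in curves.values():
            assert kmf.predict(0.0) == 1.0

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="two groups"):
            km_logrank(np.array([1.0, 2.0]), np.array([1, 1]), np.array([0, 0]))
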