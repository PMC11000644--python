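"""Base learners: logistic and beta-regression fits against closed forms
and independent numeric oracles; AUC/RMSE; CV feature-set selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import beta as beta_dist

from metscate.learners import (
    auc,
    compress_boundaries,
    cv_select,
    fit_beta_regression,
    fit_logistic,
    rmse,
)


def beta_nll(params, X, y):
    """Independent beta-regression negative log-likelihood (logit mean link,
    log-linked scalar precision); the oracle for the MLE checks."""
    k = X.shape[1]
    mu = expit(X @ params[:k])
    phi = np.exp(params[k])
    return -np.sum(beta_dist.logpdf(y, mu * phi, (1 - mu) * phi))


def numeric_beta_mle(X, y, start=None):
    k = X.shape[1]
    x0 = np.zeros(k + 1) if start is None else start
    best = None
    for method in ("BFGS", "Nelder-Mead"):
        r = minimize(beta_nll, x0, args=(X, y), method=method,
                     options={"maxiter": 20000, "xatol": 1e-12, "fatol": 1e-14}
                     if method == "Nelder-Mead" else {"gtol": 1e-10, "maxiter": 5000})
        if best is None or r.fun < best.fun:
            best = r
        x0 = best.x  # polish
    return best


class TestLogistic:
    def test_intercept_only_predicts_sample_mean(self):
        X = pd.DataFrame(index=range(200))
        y = np.r_[np.ones(50), np.zeros(150)]
        fit = fit_logistic(X, y)
        np.testing.assert_allclose(fit.predict(X), 0.25, atol=1e-8)

    def test_two_by_two_coefficient_is_log_odds_ratio(self):
        x = np.r_[np.zeros(100), np.ones(100)]
        y = np.r_[np.ones(20), np.zeros(80), np.ones(40), np.zeros(60)]
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.coefficients["x"] == pytest.approx(
            np.log((40 / 60) / (20 / 80)), abs=1e-6)

    def test_simulation_recovery_within_3_se(self, rng):
        n = 5000
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        beta = {"const": -2.0, "a": 0.8, "b": -0.5}
        p = expit(beta["const"] + 0.8 * X.a - 0.5 * X.b)
        y = (rng.random(n) < p).astype(float)
        fit = fit_logistic(X, y)
        import statsmodels.api as sm
        se = sm.Logit(y, sm.add_constant(X)).fit(disp=0).bse
        for name, true in beta.items():
            assert abs(fit.coefficients[name] - true) < 3 * se[name]

    def test_perfect_separation_engages_penalized_fallback(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.ridge_fallback
        p = fit.predict(pd.DataFrame({"x": x}))
        assert (p[:20] < 0.5).all() and (p[20:] > 0.5).all()

    def test_affine_rescaling_leaves_predictions_invariant(self, rng):
        n = 400
        X = pd.DataFrame({"z": rng.normal(size=n)})
        y = (rng.random(n) < expit(-1 + X.z)).astype(float)
        f1 = fit_logistic(X, y)
        X2 = pd.DataFrame({"z": 10.0 * X.z + 5.0})
        f2 = fit_logistic(X2, y)
        np.testing.assert_allclose(f1.predict(X), f2.predict(X2), atol=1e-6)

    def test_rejects_non_binary_outcome(self):
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0]}), [0.2, 0.8])


class TestBetaRegression:
    def test_intercept_only_matches_numeric_mle(self, rng):
        y = np.clip(rng.beta(4, 3, size=120), 1e-6, 1 - 1e-6)
        X = pd.DataFrame(index=range(120))
        fit = fit_beta_regression(X, y)
        Xc = np.ones((120, 1))
        oracle = numeric_beta_mle(Xc, y)
        ours = np.array([fit.coefficients["const"], np.log(fit.precision)])
        assert beta_nll(ours, Xc, y) == pytest.approx(oracle.fun, abs=1e-6)
        assert expit(ours[0]) == pytest.approx(expit(oracle.x[0]), abs=1e-6)

    def test_covariate_fit_matches_numeric_mle(self, rng):
        n = 150
        z = rng.normal(size=n)
        mu = expit(0.4 + 0.6 * z)
        y = np.clip(rng.beta(mu * 15, (1 - mu) * 15), 1e-6, 1 - 1e-6)
        fit = fit_beta_regression(pd.DataFrame({"z": z}), y)
        Xc = np.column_stack([np.ones(n), z])
        ours = np.array([fit.coefficients["const"], fit.coefficients["z"],
                         np.log(fit.precision)])
        oracle = numeric_beta_mle(Xc, y, start=ours + 0.05)
        assert beta_nll(ours, Xc, y) <= oracle.fun + 1e-6

    def test_simulation_recovery_within_3_se(self, rng):
        n = 5000
        z = rng.normal(size=n)
        mu = expit(0.3 + 0.5 * z)
        y = rng.beta(mu * 20, (1 - mu) * 20)
        fit = fit_beta_regression(pd.DataFrame({"z": z}), y)
        # asymptotic SE ~ O(1/sqrt(n)); 3*0.03 is conservative here
        assert abs(fit.coefficients["const"] - 0.3) < 0.09
        assert abs(fit.coefficients["z"] - 0.5) < 0.09
        assert abs(fit.precision - 20) < 2.0

    def test_near_degenerate_response_recovers_location(self):
        y = np.full(80, 0.37) + np.linspace(-1e-3, 1e-3, 80)
        fit = fit_beta_regression(pd.DataFrame(index=range(80)), y)
        assert expit(fit.coefficients["const"]) == pytest.approx(0.37, abs=1e-3)
        assert fit.precision > 1e4  # precision blows up as spread vanishes

    def test_local_optimum_property(self, rng):
        y = np.clip(rng.beta(2, 5, size=90), 1e-6, 1 - 1e-6)
        z = rng.normal(size=90)
        fit = fit_beta_regression(pd.DataFrame({"z": z}), y)
        Xc = np.column_stack([np.ones(90), z])
        ours = np.array([fit.coefficients["const"], fit.coefficients["z"],
                         np.log(fit.precision)])
        base = beta_nll(ours, Xc, y)
        rng2 = np.random.default_rng(1)
        for _ in range(25):
            assert beta_nll(ours + rng2.normal(0, 0.05, 3), Xc, y) >= base - 1e-8

    def test_boundary_compression(self):
        y = np.array([0.0, 0.5, 1.0])
        out = compress_boundaries(y)
        assert 0 < out[0] < out[1] == 0.5 < out[2] < 1
        np.testing.assert_allclose(out[0], 0.5 / 3)
        np.testing.assert_allclose(out[2], (2 + 0.5) / 3)


class TestMetrics:
    def test_auc_matches_exhaustive_pair_enumeration(self, rng):
        for _ in range(5):
            scores = np.round(rng.random(30), 2)  # induce ties
            labels = (rng.random(30) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            brute = conc / (len(pos) * len(neg))
            assert auc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_auc_edges_and_symmetry(self, rng):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        s = rng.normal(size=500)
        y = (rng.random(500) < 0.5).astype(int)
        assert abs(auc(s, y) - 0.5) < 0.1
        assert auc(s, y) + auc(-s, y) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_rmse_closed_forms(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([2.0, 3.0], [1.0, 2.0]) == pytest.approx(1.0)
        assert rmse([0.2, 0.6], [0.0, 1.0]) == pytest.approx(np.sqrt(0.1))
        with pytest.raises(ValueError):
            rmse([], [])
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestCvSelect:
    def test_signal_beats_noise(self, rng):
        n = 400
        Xs = pd.DataFrame({"s": rng.normal(size=n)})
        y = (rng.random(n) < expit(2 * Xs.s)).astype(float)
        Xn = pd.DataFrame({"n0": rng.normal(size=n)})
        best, scores = cv_select({"signal": Xs, "noise": Xn}, y, k=5,
                                 metric="auc", seed=1)
        assert best == "signal"
        assert scores["signal"] > scores["noise"]

    def test_identical_candidates_tie_break_to_first(self, rng):
        n = 120
        X = pd.DataFrame({"z": rng.normal(size=n)})
        y = (rng.random(n) < 0.3).astype(float)
        best, scores = cv_select({"A": X, "B": X.copy()}, y, k=4,
                                 metric="auc", seed=2)
        assert best == "A"
        assert scores["A"] == scores["B"]

    def test_smaller_candidate_wins_ties(self, rng):
        n = 150
        z = rng.normal(size=n)
        y = np.clip(0.4 + 0.1 * np.tanh(z) + rng.normal(0, 0.05, n), 0.05, 0.95)
        small = pd.DataFrame({"z": z})
        big = pd.DataFrame({"z": z, "z_dup": z})  # same predictions, more cols
        best, scores = cv_select({"big": big, "small": small}, y, k=5,
                                 metric="rmse", seed=3)
        assert scores["big"] == pytest.approx(scores["small"], abs=1e-6)
        assert best == "small"

    def test_leave_one_out_matches_bruteforce(self, rng):
        n = 14
        z = rng.normal(size=n)
        y = np.clip(0.5 + 0.1 * z + rng.normal(0, 0.05, n), 0.05, 0.95)
        X = pd.DataFrame({"z": z})
        X2 = pd.DataFrame({"z": z, "z2": z ** 2})
        _, scores = cv_select({"lin": X, "quad": X2}, y, k=n, metric="rmse", seed=0)
        # brute-force LOO oracle
        from metscate.learners import fit_beta_regression as fbr
        preds = np.empty(n)
        for i in range(n):
            rest = np.delete(np.arange(n), i)
            f = fbr(X.iloc[rest], y[rest])
            preds[i] = f.predict(X.iloc[[i]])[0]
        assert scores["lin"] == pytest.approx(rmse(preds, y), abs=1e-10)

    def test_requires_two_candidates(self):
        with pytest.raises(ValueError):
            cv_select({"only": pd.DataFrame({"x": [1.0, 2.0]})}, [0, 1])
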