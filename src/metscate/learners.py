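"""Base learners: arm-specific logistic outcome models and beta-regression
pseudo-outcome models, with k-fold cross-validated feature-set selection.

Roles follow the two-stage meta-learner layout: M0/M1 are logistic models
for the binary outcome fit on the unexposed/exposed arm; M2/M3 are beta
regressions (logit mean link, scalar precision) for the rescaled imputed
treatment effects on the same arms.  Feature sets are compared by
out-of-fold AUC (outcome models, higher is better) or RMSE (pseudo-outcome
models, lower is better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from statsmodels.othermod.betareg import BetaModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "LearnerFit",
    "fit_logistic",
    "fit_beta_regression",
    "compress_boundaries",
    "auc",
    "rmse",
    "cv_select",
]

#: Inverse L2 strength of the separation-fallback penalized logistic fit
#: (weak, fixed; engaged only when plain maximum likelihood fails).
_RIDGE_C = 1e4


@dataclass
class LearnerFit:
    """A fitted base learner plus the metadata needed to reuse it."""

    role: str  # M0 | M1 | M2 | M3
    family: str  # "logistic" | "beta"
    coefficients: pd.Series
    link: str = "logit"
    precision: Optional[float] = None  # beta models only
    featureset_id: str = "original"
    cv_score: Optional[float] = None
    converged: bool = True
    ridge_fallback: bool = False

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.coefficients.index if c != "const"]

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        Xc = X[self.feature_names].to_numpy(float)
        beta = self.coefficients
        return beta["const"] + Xc @ beta[self.feature_names].to_numpy(float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted probability (logistic) or mean in (0,1) (beta)."""
        return expit(self.linear_predictor(X))

    def to_dict(self) -> dict:
        return {
            "role": self.role, "family": self.family, "link": self.link,
            "featureset_id": self.featureset_id,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "precision": None if self.precision is None else float(self.precision),
            "cv_score": None if self.cv_score is None else float(self.cv_score),
            "converged": bool(self.converged),
            "ridge_fallback": bool(self.ridge_fallback),
        }


def _with_const(X: pd.DataFrame) -> pd.DataFrame:
    return sm.add_constant(X.astype(float), has_constant="add")


def fit_logistic(X: pd.DataFrame, y, role: str = "M0",
                 featureset_id: str = "original") -> LearnerFit:
    """Maximum-likelihood logistic regression with a separation fallback.

    Rare outcomes in small subgroups can separate perfectly; when plain
    Newton fitting fails or does not converge, the model is refit with a
    weak fixed L2 penalty and flagged ``ridge_fallback``.
    """
    y = np.asarray(y, float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if X.isna().any().any():
        raise ValueError("design matrix must be imputation-complete")
    Xc = _with_const(X)
    converged = False
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            params = res.params
            # Huge coefficients signal quasi-separation even when the
            # optimizer reports convergence.
            if converged and np.abs(params.to_numpy()).max() > 30:
                converged = False
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            converged = False
    if converged:
        coef = pd.Series(params, index=Xc.columns)
        return LearnerFit(role=role, family="logistic", coefficients=coef,
                          featureset_id=featureset_id, converged=True)
    # Weak-ridge fallback, fit on standardized columns for conditioning and
    # mapped back to the raw scale.
    Xv = X.to_numpy(float)
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xv - mu) / sd
    lr = LogisticRegression(C=_RIDGE_C, solver="lbfgs", max_iter=5000)
    lr.fit(Z, y)
    b = lr.coef_[0] / sd
    b0 = lr.intercept_[0] - float(mu @ b)
    coef = pd.Series(np.concatenate([[b0], b]), index=["const", *X.columns])
    return LearnerFit(role=role, family="logistic", coefficients=coef,
                      featureset_id=featureset_id, converged=True,
                      ridge_fallback=True)


def compress_boundaries(y01: np.ndarray, n: Optional[int] = None) -> np.ndarray:
    """Pull boundary responses inside (0,1).

    The beta likelihood excludes the endpoints, which a [-1,1] -> [0,1]
    rescaled treatment effect can hit exactly (and float saturation can
    reach to machine precision).  Values are clamped to
    ``[0.5/n, 1 - 0.5/n]`` — at exact 0/1 this equals the usual
    ``(y*(n-1)+0.5)/n`` compression; interior values further than 0.5/n
    from a boundary are untouched."""
    y01 = np.asarray(y01, float)
    if n is None:
        n = len(y01)
    half = 0.5 / n
    return np.clip(y01, half, 1.0 - half)


def fit_beta_regression(X: pd.DataFrame, y01, role: str = "M2",
                        featureset_id: str = "original") -> LearnerFit:
    """Beta regression: logit mean link, log-linked scalar precision.

    ``y01`` must lie in [0,1]; exact endpoints are compressed inward first.
    The returned ``precision`` is phi on the natural scale.
    """
    y = compress_boundaries(np.asarray(y01, float))
    if (y <= 0).any() or (y >= 1).any():
        raise ValueError("response must lie inside (0, 1) after boundary compression")
    if X.isna().any().any():
        raise ValueError("design matrix must be imputation-complete")
    Xc = _with_const(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = BetaModel(y, Xc, link_phi=sm.families.links.Log()).fit(
            disp=0, maxiter=500)
    converged = bool(res.mle_retvals.get("converged", True))
    params = np.asarray(res.params, float)
    coef = pd.Series(params[:-1], index=Xc.columns)
    phi = float(np.exp(params[-1]))
    return LearnerFit(role=role, family="beta", coefficients=coef,
                      precision=phi, featureset_id=featureset_id,
                      converged=converged)


def auc(scores, labels) -> float:
    """Area under the ROC curve = Mann-Whitney concordance (ties count 1/2)."""
    labels = np.asarray(labels, float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def rmse(pred, obs) -> float:
    """Root mean squared error."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.size == 0:
        raise ValueError("RMSE undefined on empty input")
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation lengths differ")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def _out_of_fold(X: pd.DataFrame, y: np.ndarray, k: int, metric: str,
                 seed: int, family: str) -> np.ndarray:
    """Out-of-fold predictions under a k-fold split fixed by the seed.

    Binary responses use stratified folds (each fold keeps both classes
    whenever the minority class has >= k members; otherwise k is lowered
    to the minority count so no fold is single-class).
    """
    n = len(y)
    if metric == "auc":
        k_eff = min(k, int(np.bincount(y.astype(int)).min()))
        if k_eff < 2:
            raise ValueError("too few minority-class observations for CV")
        splitter = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), y)
    else:
        splitter = KFold(n_splits=min(k, n), shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    oof = np.full(n, np.nan)
    for train, test in splits:
        if family == "logistic":
            fit = fit_logistic(X.iloc[train], y[train])
        else:
            fit = fit_beta_regression(X.iloc[train], y[train])
        oof[test] = fit.predict(X.iloc[test])
    return oof


def cv_select(candidates: Mapping[str, pd.DataFrame], response,
              k: int = 10, metric: str = "auc", seed: int = 0,
              family: Optional[str] = None) -> tuple[str, dict]:
    """Pick a feature set by k-fold cross-validation.

    ``candidates`` maps featureset_id -> feature matrix (same rows).  The
    score of a candidate is the metric on its pooled out-of-fold
    predictions: AUC is maximized, RMSE minimized.  Ties (to 1e-6) break
    toward the candidate with fewer columns, then by insertion order.
    Returns ``(best_id, scores_by_id)``.
    """
    if metric not in ("auc", "rmse"):
        raise ValueError("metric must be 'auc' or 'rmse'")
    if len(candidates) < 2:
        raise ValueError("need at least two candidate feature sets")
    y = np.asarray(response, float)
    if family is None:
        family = "logistic" if metric == "auc" else "beta"
    scores: dict[str, float] = {}
    for fid, X in candidates.items():
        if len(X) != len(y):
            raise ValueError(f"candidate {fid!r} rows do not match response")
        oof = _out_of_fold(X, y, k, metric, seed, family)
        scores[fid] = auc(oof, y) if metric == "auc" else rmse(oof, y)
    sign = -1.0 if metric == "auc" else 1.0
    best_score = min(sign * s for s in scores.values())
    # Scores within epsilon are ties; prefer the smaller feature set, then
    # insertion order.
    tied = [fid for fid in scores if sign * scores[fid] <= best_score + 1e-6]
    order = list(candidates)
    best = min(tied, key=lambda fid: (candidates[fid].shape[1], order.index(fid)))
    return best, scores
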