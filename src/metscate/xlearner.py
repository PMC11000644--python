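"""X-learner estimation of conditional average treatment effects (CATE).

The estimand is the conditional risk difference
``tau(x) = E(Y^1 - Y^0 | X = x)`` for a binary outcome.  The estimator:

1. fit arm-specific logistic outcome models M0 (unexposed) and M1
   (exposed), each with its feature set chosen by 10-fold CV AUC;
2. impute per-record treatment effects (ITE): ``d1 = Y - M0(x)`` on the
   exposed arm, ``d0 = M1(x) - Y`` on the unexposed arm (each arm has only
   its own ITE);
3. rescale the ITEs from [-1, 1] to (0, 1) via ``(d + 1) / 2`` with
   boundary compression, and regress them on the covariates with beta
   regressions M2 (unexposed) and M3 (exposed), feature sets chosen by
   10-fold CV RMSE;
4. back-transform the predicted means (``tau = 2*mu - 1``) and blend:
   ``cate(x) = g * tau0(x) + (1 - g) * tau1(x)``.

Because the exposure here is calendar time (pandemic vs pre-pandemic
follow-up year) and is independent of baseline covariates, the blending
weight ``g`` is the marginal exposure probability ``n_exposed / n_total``
rather than a propensity score.

Inference is by stratified nonparametric bootstrap: records are resampled
with replacement within each exposure arm (so ``g`` is preserved), the
pipeline is rerun per replicate with the feature sets frozen at the
original-sample selection, and percentile intervals / sign-fraction
p-values are formed from the replicate statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .learners import LearnerFit, cv_select, fit_beta_regression, fit_logistic
from .preprocess import build_design_matrix

__all__ = [
    "PipelineConfig",
    "IteVector",
    "CateResult",
    "BootstrapResult",
    "compute_ite",
    "rescale_ite",
    "combine_cate",
    "estimate_pipeline",
    "bootstrap_inference",
    "subgroup_cate",
    "cate_difference",
]

DEFAULT_FEATURESETS = ("original", "squares", "both")


@dataclass
class PipelineConfig:
    """Tunable knobs of the estimation pipeline.

    ``featuresets`` lists the candidate expansions compared by CV; a
    single-element list skips selection.  ``swap_weights`` flips the
    blending convention to ``(1-g)*tau0 + g*tau1`` for sensitivity
    analysis.  ``n_boot`` defaults to the headline 15,000 iterations;
    pass something smaller for exploratory runs.
    """

    featuresets: Sequence[str] = DEFAULT_FEATURESETS
    k_folds: int = 10
    seed: int = 0
    swap_weights: bool = False
    n_boot: int = 15_000
    interaction_shortlist: Optional[Sequence[str]] = None


@dataclass
class IteVector:
    """Arm-specific imputed treatment effects, raw and rescaled to (0,1)."""

    d0: pd.Series  # unexposed rows: M1(x) - Y
    d1: pd.Series  # exposed rows:   Y - M0(x)
    rescaled0: pd.Series
    rescaled1: pd.Series


@dataclass
class CateResult:
    """Point-estimate output of one pipeline run."""

    cate: pd.Series  # per-record CATE, aligned to the input records
    g: float
    overall: float
    weighting: str
    featuresets: dict = field(default_factory=dict)  # role -> featureset_id
    cv_scores: dict = field(default_factory=dict)    # role -> {id: score}
    fits: dict = field(default_factory=dict)         # role -> LearnerFit
    ite: Optional[IteVector] = None
    seed: int = 0

    def metadata(self) -> dict:
        return {
            "g": self.g,
            "weighting": self.weighting,
            "featuresets": dict(self.featuresets),
            "cv_scores": {r: {k: float(v) for k, v in s.items()}
                          for r, s in self.cv_scores.items()},
            "ridge_fallback": {r: f.ridge_fallback for r, f in self.fits.items()},
            "seed": self.seed,
        }


@dataclass
class BootstrapResult:
    """Replicate summaries for overall / subgroup / difference statistics."""

    table: pd.DataFrame  # estimate, ci_lower, ci_upper, p_value, n per row
    n_boot: int
    seed: int
    replicates: Optional[pd.DataFrame] = None
    point: Optional[CateResult] = None


def compute_ite(records: pd.DataFrame, m0: LearnerFit, m1: LearnerFit,
                dms: Mapping[str, "pd.DataFrame"]) -> IteVector:
    """Impute per-record treatment effects from the cross-arm outcome models.

    ``dms`` maps featureset_id -> full-sample feature matrix so each model
    predicts on the feature set it was selected with.  Exposed rows get
    ``d1 = Y - M0(x)``; unexposed rows get ``d0 = M1(x) - Y``.  Values lie
    in [-1, 1] by construction since predictions are probabilities.
    """
    e = records["exposure"].to_numpy()
    y = records["y_mets_followup"].to_numpy(float)
    exp_idx = records.index[e == 1]
    unexp_idx = records.index[e == 0]
    p0 = m0.predict(dms[m0.featureset_id].loc[exp_idx])
    p1 = m1.predict(dms[m1.featureset_id].loc[unexp_idx])
    if not (np.all((p0 >= 0) & (p0 <= 1)) and np.all((p1 >= 0) & (p1 <= 1))):
        raise RuntimeError("outcome model produced a prediction outside [0, 1]")
    d1 = pd.Series(y[e == 1] - p0, index=exp_idx, name="d1")
    d0 = pd.Series(p1 - y[e == 0], index=unexp_idx, name="d0")
    r0, r1 = rescale_ite(d0), rescale_ite(d1)
    return IteVector(d0=d0, d1=d1, rescaled0=r0, rescaled1=r1)


def rescale_ite(d: pd.Series) -> pd.Series:
    """Map an ITE from [-1, 1] to (0, 1): ``(d+1)/2`` then compress any
    exact endpoint inward so the beta likelihood is defined."""
    from .learners import compress_boundaries
    return pd.Series(compress_boundaries((d.to_numpy(float) + 1.0) / 2.0),
                     index=d.index, name=d.name)


def combine_cate(tau0: np.ndarray, tau1: np.ndarray, g: float,
                 swap_weights: bool = False) -> np.ndarray:
    """Blend the two effect-model predictions with the marginal exposure
    probability: ``g*tau0 + (1-g)*tau1`` (or swapped)."""
    if not 0.0 < g < 1.0:
        raise ValueError(f"marginal exposure probability g={g} outside (0, 1)")
    tau0 = np.asarray(tau0, float)
    tau1 = np.asarray(tau1, float)
    if swap_weights:
        return (1.0 - g) * tau0 + g * tau1
    return g * tau0 + (1.0 - g) * tau1


def _build_candidates(records: pd.DataFrame, config: PipelineConfig,
                      featuresets: Sequence[str]) -> dict[str, pd.DataFrame]:
    dms = {}
    for fid in featuresets:
        dm = build_design_matrix(records, featureset=fid,
                                 interaction_shortlist=config.interaction_shortlist)
        dms[fid] = dm.X
    return dms


def estimate_pipeline(records: pd.DataFrame,
                      config: Optional[PipelineConfig] = None,
                      frozen_featuresets: Optional[Mapping[str, str]] = None) -> CateResult:
    """Run the full X-learner on a record table.

    With ``frozen_featuresets`` (role -> featureset_id) the CV selection
    stage is skipped and the given sets are fit directly — this is how
    bootstrap replicates reuse the original-sample selection.
    """
    config = config or PipelineConfig()
    _validate_records(records)
    e = records["exposure"].to_numpy()
    y = records["y_mets_followup"].to_numpy(float)
    n = len(records)
    g = float(e.sum()) / n
    if frozen_featuresets is not None:
        needed = sorted(set(frozen_featuresets.values()))
    else:
        needed = list(dict.fromkeys(config.featuresets))
    try:
        dms = _build_candidates(records, config, needed)
    except Exception as err:
        raise RuntimeError(f"stage 'preprocess' failed: {err}") from err

    unexp = records.index[e == 0]
    expd = records.index[e == 1]
    featuresets: dict[str, str] = {}
    cv_scores: dict[str, dict] = {}

    def _select(role, rows, response, metric):
        if frozen_featuresets is not None:
            return frozen_featuresets[role], {}
        if len(needed) == 1:
            return needed[0], {}
        cands = {fid: dms[fid].loc[rows] for fid in needed}
        try:
            return cv_select(cands, response, k=config.k_folds, metric=metric,
                             seed=config.seed)
        except Exception as err:
            raise RuntimeError(f"stage 'cv_select {role}' failed: {err}") from err

    fits: dict[str, LearnerFit] = {}
    for role, rows in (("M0", unexp), ("M1", expd)):
        fid, scores = _select(role, rows, y[records.index.isin(rows)], metric="auc")
        featuresets[role], cv_scores[role] = fid, scores
        try:
            fits[role] = fit_logistic(dms[fid].loc[rows], y[records.index.isin(rows)],
                                      role=role, featureset_id=fid)
        except Exception as err:
            raise RuntimeError(f"stage 'fit {role}' failed: {err}") from err
        fits[role].cv_score = scores.get(fid)

    try:
        ite = compute_ite(records, fits["M0"], fits["M1"], dms)
    except Exception as err:
        raise RuntimeError(f"stage 'compute_ite' failed: {err}") from err

    for role, rows, resp in (("M2", unexp, ite.rescaled0), ("M3", expd, ite.rescaled1)):
        fid, scores = _select(role, rows, resp.to_numpy(), metric="rmse")
        featuresets[role], cv_scores[role] = fid, scores
        try:
            fits[role] = fit_beta_regression(dms[fid].loc[rows], resp.to_numpy(),
                                             role=role, featureset_id=fid)
        except Exception as err:
            raise RuntimeError(f"stage 'fit {role}' failed: {err}") from err
        fits[role].cv_score = scores.get(fid)

    tau0 = 2.0 * fits["M2"].predict(dms[featuresets["M2"]]) - 1.0
    tau1 = 2.0 * fits["M3"].predict(dms[featuresets["M3"]]) - 1.0
    cate = combine_cate(tau0, tau1, g, swap_weights=config.swap_weights)
    weighting = ("(1-g)*tau0 + g*tau1" if config.swap_weights
                 else "g*tau0 + (1-g)*tau1")
    return CateResult(cate=pd.Series(cate, index=records.index, name="cate"),
                      g=g, overall=float(np.mean(cate)), weighting=weighting,
                      featuresets=featuresets, cv_scores=cv_scores, fits=fits,
                      ite=ite, seed=config.seed)


def _validate_records(records: pd.DataFrame) -> None:
    for col in ("exposure", "y_mets_followup"):
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")
        if not np.isin(records[col].to_numpy(), (0, 1)).all():
            raise ValueError(f"column {col!r} must be binary 0/1")
    e = records["exposure"].to_numpy()
    if e.sum() == 0 or e.sum() == len(e):
        raise ValueError("both exposure arms must be non-empty")


def _group_means(cate: pd.Series, records: pd.DataFrame,
                 groupings: Sequence[str]) -> dict[str, float]:
    stats = {"overall": float(cate.mean())}
    for gvar in groupings:
        for level, idx in records.groupby(gvar, observed=True).groups.items():
            stats[f"{gvar}={level}"] = float(cate.loc[idx].mean())
    return stats


def _difference_stats(stats: Mapping[str, float], records: pd.DataFrame,
                      differences: Mapping[str, str]) -> dict[str, float]:
    out = {}
    for gvar, ref in differences.items():
        ref_key = f"{gvar}={ref}"
        if ref_key not in stats:
            raise ValueError(f"reference level {ref!r} absent from {gvar!r}")
        for level in records[gvar].dropna().unique():
            key = f"{gvar}={level}"
            out[f"diff:{key}-{ref}"] = stats[key] - stats[ref_key]
    return out


def bootstrap_inference(records: pd.DataFrame,
                        config: Optional[PipelineConfig] = None,
                        n_boot: Optional[int] = None,
                        seed: Optional[int] = None,
                        groupings: Sequence[str] = ("department", "sex"),
                        differences: Optional[Mapping[str, str]] = None) -> BootstrapResult:
    """Percentile-bootstrap CIs and sign-fraction p-values for the CATE.

    Resampling is with replacement within each exposure arm; the feature
    sets selected on the original sample are frozen across replicates.
    ``differences`` maps grouping -> reference level (default: department
    vs medical, sex vs female) and adds between-level CATE differences.
    Two-sided p-values are ``2 * min(frac <= 0, frac >= 0)`` with add-one
    smoothing, floored at ``1 / n_boot`` and capped at 1.
    """
    config = config or PipelineConfig()
    n_boot = int(n_boot if n_boot is not None else config.n_boot)
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    seed = config.seed if seed is None else seed
    groupings = [gv for gv in groupings if gv in records.columns]
    if differences is None:
        differences = {}
        if "department" in groupings and (records["department"] == "medical").any():
            differences["department"] = "medical"
        if "sex" in groupings and (records["sex"] == "female").any():
            differences["sex"] = "female"

    point = estimate_pipeline(records, config)
    point_stats = _group_means(point.cate, records, groupings)
    point_stats.update(_difference_stats(point_stats, records, differences))

    rng = np.random.default_rng(seed)
    e = records["exposure"].to_numpy()
    arm_idx = [np.flatnonzero(e == 0), np.flatnonzero(e == 1)]
    rows = []
    for _ in range(n_boot):
        take = np.concatenate([rng.choice(a, size=len(a), replace=True)
                               for a in arm_idx])
        rep = records.iloc[take].reset_index(drop=True)
        res = estimate_pipeline(rep, config,
                                frozen_featuresets=point.featuresets)
        stats = _group_means(res.cate, rep, groupings)
        stats.update(_difference_stats(stats, rep, differences))
        rows.append(stats)
    reps = pd.DataFrame(rows)

    sizes = {"overall": len(records)}
    for gvar in groupings:
        for level, grp in records.groupby(gvar, observed=True):
            sizes[f"{gvar}={level}"] = len(grp)
    table_rows = []
    for key, est in point_stats.items():
        draw = reps[key].dropna().to_numpy() if key in reps else np.array([])
        if draw.size:
            lo, hi = np.percentile(draw, [2.5, 97.5])
            p = 2.0 * min((draw <= 0).mean(), (draw >= 0).mean())
            p = float(min(1.0, max(p, 1.0 / n_boot)))
        else:
            lo = hi = p = np.nan
        size_key = key.split("diff:")[-1].rsplit("-", 1)[0] if key.startswith("diff:") else key
        table_rows.append({"statistic": key, "n": sizes.get(size_key, len(records)),
                           "estimate": est, "ci_lower": float(lo),
                           "ci_upper": float(hi), "p_value": p})
    table = pd.DataFrame(table_rows).set_index("statistic")
    return BootstrapResult(table=table, n_boot=n_boot, seed=seed,
                           replicates=reps, point=point)


def subgroup_cate(result: CateResult, records: pd.DataFrame,
                  grouping: str) -> pd.DataFrame:
    """Mean per-record CATE by subgroup (or overall).

    The size-weighted mean of the subgroup rows equals the overall mean
    exactly — subgroups partition the cohort.
    """
    if grouping == "overall":
        return pd.DataFrame({"n": [len(records)], "cate": [result.overall]},
                            index=pd.Index(["overall"], name="group"))
    if grouping not in records.columns:
        raise ValueError(f"grouping variable {grouping!r} not in records")
    grp = result.cate.groupby(records[grouping], observed=True)
    out = pd.DataFrame({"n": grp.size(), "cate": grp.mean()})
    out.index.name = "group"
    empty = [lv for lv in records[grouping].dropna().unique() if lv not in out.index]
    if empty:
        import warnings
        warnings.warn(f"empty groups omitted: {empty}")
    return out


def cate_difference(result: CateResult, records: pd.DataFrame,
                    grouping: str, reference_level: str) -> pd.DataFrame:
    """Subgroup CATE minus the reference subgroup's CATE, per level."""
    sub = subgroup_cate(result, records, grouping)
    if reference_level not in sub.index:
        raise ValueError(f"reference level {reference_level!r} absent")
    ref = sub.loc[reference_level, "cate"]
    out = sub.copy()
    out["difference"] = out["cate"] - ref
    return out[["n", "difference"]]
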