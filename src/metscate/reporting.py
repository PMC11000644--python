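"""Descriptive and heterogeneity reporting.

Covers the standard presentation layer around the CATE estimates:
per-arm descriptive tables (means +/- sd for continuous items, counts and
percentages for categorical items, missing values excluded cell-wise), a
CATE histogram with an upper-tail count, per-department age-CATE curves by
locally weighted regression, and a comparison of the records in the upper
versus lower 10th percentile of CATE with standardized differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .preprocess import CATEGORICAL_VARS, CONTINUOUS_VARS

__all__ = [
    "standardized_difference",
    "DecileComparison",
    "decile_comparison",
    "lowess_age_curve",
    "cate_histogram",
    "descriptives",
    "plot_cate_histogram",
    "plot_age_curves",
]


def standardized_difference(values_a, values_b, kind: str = "continuous") -> float:
    """Scale-free between-group contrast of one covariate.

    * ``continuous``: ``|mean_a - mean_b| / sqrt((var_a + var_b) / 2)``;
    * ``binary``: same with ``p(1-p)`` variances of the two proportions;
    * ``multilevel``: the generalized (Yang-Dalton) Mahalanobis form over
      the k-1 level-proportion vectors, which yields the single value
      conventionally printed for a multi-level variable.

    Identical groups give 0; zero pooled variance with unequal means gives
    ``inf``.  Missing values are dropped.
    """
    if kind == "multilevel":
        a = pd.Series(values_a).dropna().astype(str)
        b = pd.Series(values_b).dropna().astype(str)
        levels = sorted(set(a.unique()) | set(b.unique()))
        if len(levels) < 2:
            return 0.0
        drop = levels[0]
        use = [lv for lv in levels if lv != drop]
        pa = np.array([(a == lv).mean() for lv in use])
        pb = np.array([(b == lv).mean() for lv in use])
        diff = pa - pb
        S = np.empty((len(use), len(use)))
        for i in range(len(use)):
            for j in range(len(use)):
                if i == j:
                    S[i, j] = (pa[i] * (1 - pa[i]) + pb[i] * (1 - pb[i])) / 2.0
                else:
                    S[i, j] = -(pa[i] * pa[j] + pb[i] * pb[j]) / 2.0
        if not diff.any():
            return 0.0
        try:
            return float(np.sqrt(diff @ np.linalg.pinv(S) @ diff))
        except np.linalg.LinAlgError:
            return float("inf")

    a = pd.Series(values_a, dtype=float).dropna().to_numpy()
    b = pd.Series(values_b, dtype=float).dropna().to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain observed values")
    ma, mb = a.mean(), b.mean()
    if kind == "binary":
        va, vb = ma * (1 - ma), mb * (1 - mb)
    elif kind == "continuous":
        va = a.var(ddof=1) if a.size > 1 else 0.0
        vb = b.var(ddof=1) if b.size > 1 else 0.0
    else:
        raise ValueError(f"unknown kind {kind!r}")
    pooled = (va + vb) / 2.0
    if pooled == 0.0:
        return 0.0 if ma == mb else float("inf")
    return float(abs(ma - mb) / np.sqrt(pooled))


@dataclass
class DecileComparison:
    """Low vs high CATE-decile groups and their covariate profile."""

    low_index: pd.Index
    high_index: pd.Index
    low_threshold: float
    high_threshold: float
    table: pd.DataFrame  # per-covariate summaries + standardized difference


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    """Nearest-rank empirical percentile (rank = ceil(q*n), 1-based)."""
    n = len(sorted_vals)
    rank = int(np.ceil(q * n))
    return float(sorted_vals[min(max(rank, 1), n) - 1])


def _nearest_rank_upper(sorted_vals: np.ndarray, q: float) -> float:
    """Mirrored nearest-rank cut so that ``x >= threshold`` captures the
    top ``q`` fraction (rank n - ceil(q*n) + 1, 1-based)."""
    n = len(sorted_vals)
    rank = n - int(np.ceil(q * n)) + 1
    return float(sorted_vals[min(max(rank, 1), n) - 1])


def _summarize(col: pd.Series, low: pd.Index, high: pd.Index) -> tuple[str, str, str, float]:
    a, b = col.loc[low], col.loc[high]
    if col.dtype.kind in "fiu" and col.dropna().nunique() > 2:
        if a.notna().sum() == 0 or b.notna().sum() == 0:
            # observed in one group only: contrast undefined
            sd = float("nan")
        else:
            sd = standardized_difference(a, b, "continuous")
        fmt = lambda v: f"{v.mean():.1f} ± {v.std(ddof=1):.1f} (n={v.notna().sum()})"
        return "continuous", fmt(a.astype(float)), fmt(b.astype(float)), sd
    uniq = col.dropna().unique()
    if len(uniq) <= 2 and set(map(str, uniq)) <= {"0", "1", "0.0", "1.0"}:
        sd = standardized_difference(a.astype(float), b.astype(float), "binary")
        fmt = lambda v: f"{int(v.sum())} ({100 * v.mean():.1f}%)"
        return "binary", fmt(a.astype(float).dropna()), fmt(b.astype(float).dropna()), sd
    sd = standardized_difference(a, b, "multilevel")
    fmt = lambda v: "; ".join(f"{lv}: {n}" for lv, n in
                              v.astype(object).where(v.notna(), "missing")
                              .value_counts().sort_index().items())
    return "multilevel", fmt(a), fmt(b), sd


def decile_comparison(cates: pd.Series, records: pd.DataFrame,
                      covariates: Optional[Sequence[str]] = None) -> DecileComparison:
    """Profile the records in the lower and upper 10th CATE percentiles.

    Thresholds use the nearest-rank rule; membership is ``cate <= low
    threshold`` / ``cate >= high threshold`` (ties kept, so under heavy
    ties a group can exceed 10%).  Each baseline covariate is summarized
    in both groups with its standardized difference.
    """
    if len(cates) < 20:
        raise ValueError("need at least 20 records for a stable decile split")
    cates = pd.Series(cates)
    srt = np.sort(cates.to_numpy(float))
    lo_thr = _nearest_rank(srt, 0.10)
    hi_thr = _nearest_rank_upper(srt, 0.10)
    low = cates.index[cates.to_numpy(float) <= lo_thr]
    high = cates.index[cates.to_numpy(float) >= hi_thr]
    if covariates is None:
        covariates = [c for c in (*CONTINUOUS_VARS, *CATEGORICAL_VARS, "y_mets_followup")
                      if c in records.columns]
    rows = []
    for cov in covariates:
        kind, sa, sb, sd = _summarize(records[cov], low, high)
        rows.append({"covariate": cov, "kind": kind, "low": sa, "high": sb,
                     "std_diff": sd})
    table = pd.DataFrame(rows).set_index("covariate")
    return DecileComparison(low_index=low, high_index=high,
                            low_threshold=lo_thr, high_threshold=hi_thr,
                            table=table)


def lowess_age_curve(ages, cates, department_labels, bandwidth: float = 0.8,
                     n_grid: int = 50, robust_iters: int = 1) -> pd.DataFrame:
    """Locally weighted age-CATE curve, separately per department.

    Returns a long table ``(department, age, cate_smooth)`` with the
    smoother evaluated on an equispaced age grid inside each department's
    observed range.  Requires >= 10 points per department.
    """
    df = pd.DataFrame({"age": np.asarray(ages, float),
                       "cate": np.asarray(cates, float),
                       "department": np.asarray(department_labels)})
    out = []
    for dept, grp in df.groupby("department", observed=True):
        if len(grp) < 10:
            raise ValueError(f"department {dept!r} has fewer than 10 points")
        sm_xy = lowess(grp["cate"], grp["age"], frac=bandwidth, it=robust_iters,
                       return_sorted=True)
        grid = np.linspace(grp["age"].min(), grp["age"].max(), n_grid)
        smooth = np.interp(grid, sm_xy[:, 0], sm_xy[:, 1])
        out.append(pd.DataFrame({"department": dept, "age": grid,
                                 "cate_smooth": smooth}))
    return pd.concat(out, ignore_index=True)


def cate_histogram(cates, bin_width: float = 0.05,
                   threshold: float = 0.25) -> dict:
    """Histogram of the per-record CATE distribution.

    Bins are aligned to multiples of ``bin_width``.  Also reports the
    count and fraction of records whose CATE exceeds ``threshold`` (the
    upper tail of strongly affected individuals).
    """
    x = np.asarray(cates, float)
    if x.size == 0:
        bins = np.array([0.0, bin_width])
    else:
        lo = np.floor(x.min() / bin_width) * bin_width
        hi = np.ceil(x.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        bins = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(x, bins=bins)
    table = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                          "count": counts})
    n_above = int((x > threshold).sum())
    return {"table": table, "n": int(x.size), "threshold": threshold,
            "n_above_threshold": n_above,
            "fraction_above_threshold": n_above / x.size if x.size else np.nan}


def plot_cate_histogram(cates, path, bin_width: float = 0.05,
                        threshold: float = 0.25) -> None:
    """Render the CATE histogram to an image file (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h = cate_histogram(cates, bin_width, threshold)
    fig, ax = plt.subplots(figsize=(6, 4))
    t = h["table"]
    ax.bar(t["bin_left"], t["count"], width=bin_width, align="edge",
           edgecolor="white")
    ax.axvline(threshold, color="firebrick", ls="--", lw=1,
               label=f"> {threshold}: {h['n_above_threshold']} records")
    ax.set_xlabel("estimated CATE (risk difference)")
    ax.set_ylabel("records")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_age_curves(ages, cates, department_labels, path,
                    bandwidth: float = 0.8) -> None:
    """Scatter of age vs CATE with per-department smoothing curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = lowess_age_curve(ages, cates, department_labels, bandwidth)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ages, cates, s=4, alpha=0.2, color="grey")
    for dept, grp in curves.groupby("department", observed=True):
        ax.plot(grp["age"], grp["cate_smooth"], lw=2, label=str(dept))
    ax.set_xlabel("age (years)")
    ax.set_ylabel("estimated CATE")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def descriptives(records: pd.DataFrame, by: str = "exposure",
                 continuous: Sequence[str] = ("age", "smoking_number",
                                              "smoking_years", *CONTINUOUS_VARS[3:]),
                 categorical: Sequence[str] = CATEGORICAL_VARS) -> pd.DataFrame:
    """Per-arm descriptive table: mean +/- sd over observed values for
    continuous items; level counts with percentages for categorical items.

    Returns a long table with columns ``variable, level, arm, n, value``;
    ``value`` is the mean (continuous) or count (categorical), ``n`` the
    observed count, plus ``sd`` / ``pct`` where applicable.
    """
    rows = []
    for arm, grp in records.groupby(by, observed=True):
        for var in continuous:
            if var not in records.columns:
                continue
            obs = grp[var].astype(float).dropna()
            rows.append({"variable": var, "level": "mean±sd", "arm": arm,
                         "n": int(obs.size),
                         "value": float(obs.mean()) if obs.size else np.nan,
                         "sd": float(obs.std(ddof=1)) if obs.size > 1 else np.nan,
                         "pct": np.nan})
        for var in categorical:
            if var not in records.columns:
                continue
            vals = grp[var].astype(object).where(grp[var].notna(), "missing")
            counts = vals.value_counts()
            for level, cnt in counts.sort_index().items():
                rows.append({"variable": var, "level": str(level), "arm": arm,
                             "n": int(cnt), "value": int(cnt), "sd": np.nan,
                             "pct": 100.0 * cnt / len(grp)})
    return pd.DataFrame(rows)
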