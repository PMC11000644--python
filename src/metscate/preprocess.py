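"""From raw checkup records to a fully numeric design matrix.

Continuous variables get single median imputation (medians computed on the
pooled analysis sample) paired with a 0/1 missingness-indicator column;
categorical variables get one-hot coding with an explicit ``missing`` level
and the most frequent level as the dropped reference.  Candidate feature
sets are then formed by optionally appending squared continuous columns
and/or pairwise interaction columns, with exact-duplicate and constant
columns pruned.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTINUOUS_VARS",
    "CATEGORICAL_VARS",
    "DesignMatrix",
    "impute_median",
    "encode_categorical",
    "expand_features",
    "build_design_matrix",
    "read_records",
]

#: Continuous checkup fields entering the design matrix.
CONTINUOUS_VARS = (
    "age", "smoking_number", "smoking_years", "sbp", "dbp", "bmi", "waist",
    "hgb", "rbc", "ast", "alt", "ggtp", "ldl", "hdl",
    "tg_fasting", "tg_casual", "hba1c", "bs_fasting", "bs_casual",
)

#: Categorical / binary checkup fields (missing becomes its own level).
CATEGORICAL_VARS = (
    "sex", "department", "smoking_status",
    "urinary_protein", "urinary_sugar", "urinary_blood",
    "eye_right_low", "eye_left_low",
    "hearing_right_1k", "hearing_left_1k", "hearing_right_4k", "hearing_left_4k",
    "exam_findings", "ecg_findings", "xray_findings",
    "history_dm", "history_hl", "history_ht",
)

#: Default shortlist for pairwise interactions: the clinically central
#: continuous measurements (unchecked all-pairs expansion is combinatorial).
INTERACTION_SHORTLIST = ("age", "bmi", "waist", "sbp", "hdl")

FEATURESETS = ("original", "squares", "interactions", "both")


@dataclass
class DesignMatrix:
    """Imputation-complete numeric feature matrix.

    ``X`` holds one float column per feature; ``indicator_columns`` names
    the missingness flags; ``base_continuous`` names the imputed continuous
    columns eligible for squaring/interacting; ``featureset_id`` records
    which expansion produced the matrix.
    """

    X: pd.DataFrame
    indicator_columns: list[str] = field(default_factory=list)
    base_continuous: list[str] = field(default_factory=list)
    featureset_id: str = "original"
    medians: dict = field(default_factory=dict)

    @property
    def row_ids(self):
        return self.X.index

    def to_csv(self, path) -> None:
        self.X.to_csv(path, index=True)

    def column_dictionary(self) -> dict:
        return {
            "featureset_id": self.featureset_id,
            "columns": list(self.X.columns),
            "indicator_columns": list(self.indicator_columns),
            "base_continuous": list(self.base_continuous),
            "medians": {k: float(v) for k, v in self.medians.items()},
        }

    def write_column_dictionary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.column_dictionary(), fh, indent=2)


def impute_median(frame: pd.DataFrame,
                  columns: Optional[Sequence[str]] = None,
                  medians: Optional[dict] = None) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Median-impute continuous columns, adding ``<col>_missing`` flags.

    Medians are computed over the observed values of the supplied frame
    (the pooled analysis sample) unless pre-computed ``medians`` are
    passed.  Returns ``(imputed, indicators, medians)``.  Raises if a
    column has no observed value at all.
    """
    if columns is None:
        columns = [c for c in frame.columns
                   if frame[c].dtype.kind in "fiu"]
    imputed = frame[list(columns)].astype(float).copy()
    flags = {}
    used = dict(medians) if medians else {}
    for col in columns:
        vals = imputed[col]
        miss = vals.isna()
        if col not in used:
            if miss.all():
                raise ValueError(f"column {col!r} has no observed values to impute from")
            used[col] = float(vals.median())
        flags[f"{col}_missing"] = miss.astype(float)
        imputed[col] = vals.fillna(used[col])
    indicators = pd.DataFrame(flags, index=frame.index)
    return imputed, indicators, used


def encode_categorical(frame: pd.DataFrame,
                       columns: Optional[Sequence[str]] = None,
                       reference: Optional[dict] = None) -> tuple[pd.DataFrame, dict]:
    """One-hot encode with an explicit ``missing`` level.

    The reference (dropped) level per variable is the most frequent
    observed level, unless overridden through ``reference``; a ``missing``
    level appears only when the column actually has missing values.
    Returns ``(encoded, reference_levels)``.
    """
    if columns is None:
        columns = [c for c in frame.columns if frame[c].dtype.kind in "Ob"]
    refs = dict(reference) if reference else {}
    pieces = []
    for col in columns:
        vals = frame[col].astype(object).where(frame[col].notna(), "missing")
        vals = vals.astype(str)
        counts = vals[vals != "missing"].value_counts()
        if col not in refs:
            # All-missing variables keep their single missing-level column
            # (reference is a phantom observed level).
            refs[col] = counts.index[0] if len(counts) else "__none__"
        levels = [lv for lv in sorted(vals.unique()) if lv != refs[col]]
        for lv in levels:
            pieces.append(pd.Series((vals == lv).astype(float),
                                    name=f"{col}[{lv}]", index=frame.index))
    encoded = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=frame.index)
    return encoded, refs


def _prune(X: pd.DataFrame, protect: Sequence[str] = ()) -> pd.DataFrame:
    """Drop constant columns and exact duplicates (keep first occurrence).

    For 0/1 columns the complement ``1 - v`` also counts as a duplicate:
    complementary missingness flags (e.g. the fasting vs casual channel of
    an exclusive lab pair) are perfectly collinear with the intercept.
    """
    keep = []
    seen: set[bytes] = set()
    for col in X.columns:
        v = X[col].to_numpy(float)
        if col not in protect and np.all(v == v[0]):
            continue
        key = v.tobytes()
        if key in seen:
            continue
        is_binary = np.isin(v, (0.0, 1.0)).all()
        if is_binary and (1.0 - v).tobytes() in seen:
            continue
        seen.add(key)
        keep.append(col)
    return X[keep]


def expand_features(dm: DesignMatrix, spec: str = "original",
                    interaction_shortlist: Optional[Sequence[str]] = None) -> DesignMatrix:
    """Append squared and/or pairwise-interaction columns.

    ``spec`` is one of ``original`` (no-op), ``squares``, ``interactions``,
    ``both``.  Squares cover the imputed continuous base columns;
    interactions cover all pairs in the shortlist (default
    :data:`INTERACTION_SHORTLIST` intersected with available columns).
    Constant and exactly duplicated expansion columns are dropped — e.g. a
    0/1 column squared duplicates itself and never survives.
    """
    if spec not in FEATURESETS:
        raise ValueError(f"spec must be one of {FEATURESETS}, got {spec!r}")
    if dm.X.isna().any().any():
        raise ValueError("design matrix must be imputation-complete before expansion")
    X = dm.X.copy()
    cont = list(dm.base_continuous)
    if spec in ("squares", "both"):
        for col in cont:
            X[f"{col}^2"] = X[col] ** 2
    if spec in ("interactions", "both"):
        short = [c for c in (interaction_shortlist or INTERACTION_SHORTLIST)
                 if c in cont]
        for a, b in itertools.combinations(short, 2):
            X[f"{a}*{b}"] = X[a] * X[b]
    X = _prune(X, protect=dm.X.columns)
    return DesignMatrix(X=X, indicator_columns=list(dm.indicator_columns),
                        base_continuous=cont, featureset_id=spec,
                        medians=dict(dm.medians))


def build_design_matrix(records: pd.DataFrame, featureset: str = "original",
                        continuous: Sequence[str] = CONTINUOUS_VARS,
                        categorical: Sequence[str] = CATEGORICAL_VARS,
                        interaction_shortlist: Optional[Sequence[str]] = None,
                        medians: Optional[dict] = None,
                        reference: Optional[dict] = None) -> DesignMatrix:
    """Full record table -> :class:`DesignMatrix` for one feature set."""
    cont_cols = [c for c in continuous if c in records.columns]
    cat_cols = [c for c in categorical if c in records.columns]
    imputed, indicators, used_medians = impute_median(records, cont_cols, medians)
    encoded, _ = encode_categorical(records, cat_cols, reference)
    X = pd.concat([imputed, indicators, encoded], axis=1)
    X = _prune(X)
    dm = DesignMatrix(X=X, indicator_columns=[c for c in indicators.columns
                                              if c in X.columns],
                      base_continuous=[c for c in cont_cols if c in X.columns],
                      featureset_id="original", medians=used_medians)
    if featureset != "original":
        dm = expand_features(dm, featureset, interaction_shortlist)
    return dm


def read_records(path) -> pd.DataFrame:
    """Read a checkup table from ``.csv`` or Stata ``.dta``."""
    path = str(path)
    if path.endswith(".dta"):
        return pd.read_stata(path)
    return pd.read_csv(path, comment="#")
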