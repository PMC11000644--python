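"""Metabolic syndrome classification under the Japanese (MHLW) criteria.

The rule: excess visceral fat, screened by abdominal (waist) circumference
at the umbilicus — >= 85 cm in males, >= 90 cm in females — plus at least
two of three cardiometabolic risk factors:

* dyslipidemia:     triglycerides >= 150 mg/dL  or  HDL cholesterol < 40 mg/dL
* elevated BP:      systolic >= 130 mmHg  or  diastolic >= 85 mmHg
* hyperglycemia:    fasting blood sugar >= 110 mg/dL

Health-checkup data are messy: glucose and triglycerides may be fasting or
casual (never both), HbA1c is measured only in a subset, and whole blocks
may be missing.  Each factor is therefore tri-state — positive / negative /
indeterminate — and the verdict is ``indeterminate`` whenever the missing
pieces could still swing the >= 2-of-3 decision either way.  Indeterminate
records are meant to be excluded from outcome analyses.

Casual (non-fasting) glucose is non-diagnostic by default; when fasting
glucose is absent, an HbA1c substitution cutoff (default 6.0 % NGSP) may
resolve the glycemia factor.  Both behaviours are configurable through
:class:`GlycemiaRule` because screening programmes differ on this branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "INDETERMINATE",
    "GlycemiaRule",
    "MetsAssessment",
    "visceral_fat_flag",
    "lipid_flag",
    "glycemia_flag",
    "pressure_flag",
    "classify_mets",
    "classify_frame",
]

POSITIVE = "positive"
NEGATIVE = "negative"
INDETERMINATE = "indeterminate"

WAIST_CUTOFF_CM = {"male": 85.0, "female": 90.0}
TG_CUTOFF_MGDL = 150.0
HDL_CUTOFF_MGDL = 40.0
FASTING_BS_CUTOFF_MGDL = 110.0
SBP_CUTOFF_MMHG = 130.0
DBP_CUTOFF_MMHG = 85.0


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class GlycemiaRule:
    """Configurable handling of the glycemia factor without fasting glucose.

    Parameters
    ----------
    hba1c_cutoff : float or None
        HbA1c (%, NGSP) at or above which the factor counts positive when
        fasting glucose is unavailable.  ``None`` disables the substitution.
    casual_bs_cutoff : float or None
        Casual glucose cutoff (mg/dL); ``None`` (default) treats casual
        glucose as non-diagnostic, leaving the factor indeterminate.
    """

    hba1c_cutoff: Optional[float] = 6.0
    casual_bs_cutoff: Optional[float] = None


DEFAULT_GLYCEMIA_RULE = GlycemiaRule()


@dataclass(frozen=True)
class MetsAssessment:
    """Outcome of the diagnostic rule for one record."""

    visceral_fat: Optional[bool]
    glycemia: str
    lipid: str
    pressure: str
    n_risk_factors: int
    verdict: str  # "mets" | "no_mets" | "indeterminate"


def visceral_fat_flag(waist, sex: str) -> Optional[bool]:
    """Waist-circumference screen; ``None`` when the waist is missing."""
    if _missing(waist):
        return None
    if waist <= 0:
        raise ValueError(f"waist must be positive, got {waist!r}")
    return bool(waist >= WAIST_CUTOFF_CM[sex])


def lipid_flag(tg_fasting, tg_casual, hdl) -> str:
    """Combined triglyceride / HDL-cholesterol factor (one item in Japan)."""
    if not _missing(tg_fasting) and not _missing(tg_casual):
        raise ValueError("fasting and casual triglycerides are mutually exclusive")
    tg = tg_casual if _missing(tg_fasting) else tg_fasting
    tg_pos = None if _missing(tg) else tg >= TG_CUTOFF_MGDL
    hdl_pos = None if _missing(hdl) else hdl < HDL_CUTOFF_MGDL
    if tg_pos or hdl_pos:
        return POSITIVE
    if tg_pos is None or hdl_pos is None:
        return INDETERMINATE
    return NEGATIVE


def glycemia_flag(bs_fasting, bs_casual, hba1c,
                  rule: GlycemiaRule = DEFAULT_GLYCEMIA_RULE) -> str:
    """Hyperglycemia factor; fasting glucose is authoritative when present."""
    if not _missing(bs_fasting) and not _missing(bs_casual):
        raise ValueError("fasting and casual blood sugar are mutually exclusive")
    if not _missing(bs_fasting):
        return POSITIVE if bs_fasting >= FASTING_BS_CUTOFF_MGDL else NEGATIVE
    # No fasting measurement: substitution branch.
    if rule.casual_bs_cutoff is not None and not _missing(bs_casual):
        if bs_casual >= rule.casual_bs_cutoff:
            return POSITIVE
    if rule.hba1c_cutoff is not None and not _missing(hba1c):
        return POSITIVE if hba1c >= rule.hba1c_cutoff else NEGATIVE
    return INDETERMINATE


def pressure_flag(sbp, dbp) -> str:
    """Blood-pressure factor, 130/85 mmHg; either component suffices."""
    sbp_pos = None if _missing(sbp) else sbp >= SBP_CUTOFF_MMHG
    dbp_pos = None if _missing(dbp) else dbp >= DBP_CUTOFF_MMHG
    if sbp_pos or dbp_pos:
        return POSITIVE
    if sbp_pos is None or dbp_pos is None:
        return INDETERMINATE
    return NEGATIVE


def _verdict(visceral: Optional[bool], factors: list[str]) -> tuple[int, str]:
    n_pos = sum(f == POSITIVE for f in factors)
    n_ind = sum(f == INDETERMINATE for f in factors)
    if visceral is False:
        return n_pos, "no_mets"
    if visceral is None:
        # Waist missing: MetS can never be confirmed, but absence can only be
        # confirmed if the factor count already rules it out for any waist.
        return n_pos, "no_mets" if n_pos + n_ind < 2 else "indeterminate"
    if n_pos >= 2:
        return n_pos, "mets"
    if n_pos + n_ind < 2:
        return n_pos, "no_mets"
    return n_pos, "indeterminate"


def classify_mets(record: Mapping, rule: GlycemiaRule = DEFAULT_GLYCEMIA_RULE) -> MetsAssessment:
    """Apply the full MHLW rule to one record (mapping or ``pd.Series``).

    Expected keys: ``waist, sex, tg_fasting, tg_casual, hdl, bs_fasting,
    bs_casual, hba1c, sbp, dbp``; absent keys count as missing values.
    """
    get = lambda k: record.get(k) if hasattr(record, "get") else record[k]
    visceral = visceral_fat_flag(get("waist"), get("sex"))
    lip = lipid_flag(get("tg_fasting"), get("tg_casual"), get("hdl"))
    gly = glycemia_flag(get("bs_fasting"), get("bs_casual"), get("hba1c"), rule)
    pre = pressure_flag(get("sbp"), get("dbp"))
    n_pos, verdict = _verdict(visceral, [lip, gly, pre])
    return MetsAssessment(
        visceral_fat=visceral, glycemia=gly, lipid=lip, pressure=pre,
        n_risk_factors=n_pos, verdict=verdict,
    )


def classify_frame(records: pd.DataFrame,
                   rule: GlycemiaRule = DEFAULT_GLYCEMIA_RULE) -> pd.DataFrame:
    """Classify every row of a checkup table.

    Returns a frame aligned to ``records`` with columns ``visceral_fat``,
    ``lipid``, ``glycemia``, ``pressure``, ``n_risk_factors``, ``verdict``.
    """
    rows = []
    for _, rec in records.iterrows():
        a = classify_mets(rec, rule)
        rows.append((a.visceral_fat, a.lipid, a.glycemia, a.pressure,
                     a.n_risk_factors, a.verdict))
    return pd.DataFrame(
        rows,
        columns=["visceral_fat", "lipid", "glycemia", "pressure",
                 "n_risk_factors", "verdict"],
        index=records.index,
    )
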