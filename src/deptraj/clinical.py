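"""Derived clinical indices and the metabolic-syndrome classifier.

Pure, total functions over their stated domains: HOMA-IR (Matthews
formula, glucose in mmol/L x insulin in uU/mL / 22.5), the AST/ALT
ratio, and the harmonised consensus metabolic-syndrome rule (any three
of five risk factors at the conventional thresholds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: consensus thresholds for the five metabolic-syndrome risk factors
METSYN_THRESHOLDS = {
    "waist_white_men_cm": 94.0,
    "waist_nonwhite_men_cm": 90.0,
    "waist_women_cm": 80.0,
    "triglycerides_mmol_L": 1.7,  # inclusive >=
    "hdl_mmol_L": 1.0,  # strict <
    "sbp_mmHg": 130.0,  # inclusive >=
    "dbp_mmHg": 85.0,  # inclusive >=
    "glucose_mmol_L": 5.6,  # inclusive >=
}


def homa_ir(fasting_glucose_mmol_l, fasting_insulin_uu_ml):
    """HOMA-IR = glucose x insulin / 22.5; missing for nonpositive input."""
    g = np.asarray(fasting_glucose_mmol_l, float)
    i = np.asarray(fasting_insulin_uu_ml, float)
    out = np.where((g > 0) & (i > 0), g * i / 22.5, np.nan)
    return float(out) if out.ndim == 0 else out


def ast_alt_ratio(ast, alt):
    """AST/ALT ratio; missing when ALT is nonpositive or either is missing."""
    a = np.asarray(ast, float)
    b = np.asarray(alt, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((b > 0) & (a >= 0), a / b, np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MetSynComponents:
    """Inputs to the metabolic-syndrome rule; None marks a missing value."""

    waist_cm: float | None = None
    triglycerides_mmol_L: float | None = None
    hdl_mmol_L: float | None = None
    sbp_mmHg: float | None = None
    dbp_mmHg: float | None = None
    fasting_glucose_mmol_L: float | None = None
    sex: str | None = None  # "male" | "female"
    ethnicity_white: bool | None = None


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _factor_waist(c: MetSynComponents, thresholds=METSYN_THRESHOLDS):
    if _is_missing(c.waist_cm):
        return None
    if c.sex == "female":
        return c.waist_cm >= thresholds["waist_women_cm"]
    if c.sex == "male":
        if c.ethnicity_white is None:
            # the two male cut-offs straddle the value -> undetermined
            if (
                thresholds["waist_nonwhite_men_cm"]
                <= c.waist_cm
                < thresholds["waist_white_men_cm"]
            ):
                return None
            return c.waist_cm >= thresholds["waist_white_men_cm"]
        cut = (
            thresholds["waist_white_men_cm"]
            if c.ethnicity_white
            else thresholds["waist_nonwhite_men_cm"]
        )
        return c.waist_cm >= cut
    return None  # unknown sex


def metsyn_factors(c: MetSynComponents, thresholds=METSYN_THRESHOLDS) -> list:
    """The five risk-factor indicators; None where undeterminable."""
    bp = None
    sbp_missing, dbp_missing = _is_missing(c.sbp_mmHg), _is_missing(c.dbp_mmHg)
    sbp_high = (not sbp_missing) and c.sbp_mmHg >= thresholds["sbp_mmHg"]
    dbp_high = (not dbp_missing) and c.dbp_mmHg >= thresholds["dbp_mmHg"]
    if sbp_high or dbp_high:
        bp = True
    elif not sbp_missing and not dbp_missing:
        bp = False
    return [
        _factor_waist(c, thresholds),
        None
        if _is_missing(c.triglycerides_mmol_L)
        else c.triglycerides_mmol_L >= thresholds["triglycerides_mmol_L"],
        None if _is_missing(c.hdl_mmol_L) else c.hdl_mmol_L < thresholds["hdl_mmol_L"],
        bp,
        None
        if _is_missing(c.fasting_glucose_mmol_L)
        else c.fasting_glucose_mmol_L >= thresholds["glucose_mmol_L"],
    ]


def metabolic_syndrome(
    components: MetSynComponents, thresholds=METSYN_THRESHOLDS
) -> str:
    """Classify as "positive" (>=3 of 5 factors), "negative", or "missing".

    A classification is only issued when it is invariant to every
    undetermined component; otherwise "missing".
    """
    factors = metsyn_factors(components, thresholds)
    n_pos = sum(1 for f in factors if f is True)
    n_unknown = sum(1 for f in factors if f is None)
    if n_pos >= 3:
        return "positive"
    if n_pos + n_unknown < 3:
        return "negative"
    return "missing"


def metsyn_table(df: pd.DataFrame, thresholds=METSYN_THRESHOLDS) -> pd.Series:
    """Column-in/column-out classifier over an outcomes-style table.

    Expects columns waist_cm, triglycerides_mmol_L, hdl_mmol_L, sbp_mmHg,
    dbp_mmHg, fasting_glucose_mmol_L, sex, ethnicity_white.
    """
    results = []
    for _, row in df.iterrows():
        eth = row.get("ethnicity_white")
        comp = MetSynComponents(
            waist_cm=row.get("waist_cm"),
            triglycerides_mmol_L=row.get("triglycerides_mmol_L"),
            hdl_mmol_L=row.get("hdl_mmol_L"),
            sbp_mmHg=row.get("sbp_mmHg"),
            dbp_mmHg=row.get("dbp_mmHg"),
            fasting_glucose_mmol_L=row.get("fasting_glucose_mmol_L"),
            sex=None if pd.isna(row.get("sex")) else row.get("sex"),
            ethnicity_white=None if pd.isna(eth) else bool(eth),
        )
        results.append(metabolic_syndrome(comp, thresholds))
    return pd.Series(results, index=df.index, name="metabolic_syndrome")
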