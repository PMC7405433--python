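"""Regression design construction shared by the generator and all estimators.

One fixed encoding is used everywhere: treatment-coded dummies against the
conventional reference levels (Caucasian, never-smoker, abstinent, no
activity restriction, no malignancy, female) and z-standardized continuous
confounders (age, income, calendar time).  The generator standardizes with
its own population constants; estimators standardize with constants
computed on the analysis sample actually fed to the model, which are
returned so they can be logged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CONFOUNDERS

#: Ordered design terms for the 14 confounders (27 columns).
CONFOUNDER_TERMS: list[str] = [
    "age_std",
    "sex_male",
    "eth_Asian",
    "eth_Black",
    "eth_Other",
    "income_std",
    "smoke_ex_gt1y",
    "smoke_ex_lt1y",
    "smoke_current",
    "alc_social",
    "alc_problematic",
    "pa_limited",
    "pa_chair_ridden",
    "pa_bed_ridden",
    "hypothyroidism",
    "glucocorticoids",
    "solid_non_metastatic",
    "solid_metastatic",
    "heme_ALL",
    "heme_AML",
    "heme_CLL",
    "heme_MM",
    "heme_NHL",
    "heme_other",
    "dementia",
    "hiv_aids",
    "calendar_std",
]

_DUMMY_MAP = {
    "sex_male": ("sex", "male"),
    "eth_Asian": ("ethnicity", "Asian"),
    "eth_Black": ("ethnicity", "Black"),
    "eth_Other": ("ethnicity", "Other"),
    "smoke_ex_gt1y": ("smoking", "ex_gt1y"),
    "smoke_ex_lt1y": ("smoking", "ex_lt1y"),
    "smoke_current": ("smoking", "current"),
    "alc_social": ("alcohol", "social"),
    "alc_problematic": ("alcohol", "problematic"),
    "pa_limited": ("physical_activity", "limited"),
    "pa_chair_ridden": ("physical_activity", "chair_ridden"),
    "pa_bed_ridden": ("physical_activity", "bed_ridden"),
    "solid_non_metastatic": ("solid_malignancy", "non_metastatic"),
    "solid_metastatic": ("solid_malignancy", "metastatic"),
    "heme_ALL": ("heme_malignancy", "ALL"),
    "heme_AML": ("heme_malignancy", "AML"),
    "heme_CLL": ("heme_malignancy", "CLL"),
    "heme_MM": ("heme_malignancy", "MM"),
    "heme_NHL": ("heme_malignancy", "NHL"),
    "heme_other": ("heme_malignancy", "other"),
}

_STD_MAP = {"age_std": "age", "income_std": "income", "calendar_std": "calendar_time"}

_BOOL_TERMS = ["hypothyroidism", "glucocorticoids", "dementia", "hiv_aids"]


def confounder_design(
    df: pd.DataFrame,
    standardization: dict[str, tuple[float, float]] | None = None,
    confounders: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Build the confounder design matrix (no intercept, no exposure).

    Parameters
    ----------
    df : cohort data frame (complete in the used fields).
    standardization : optional ``{field: (mean, sd)}`` constants; computed
        from ``df`` when not given.
    confounders : subset of confounder fields to include (default all 14).

    Returns the design frame (columns in :data:`CONFOUNDER_TERMS` order)
    and the standardization constants actually used.
    """
    use = CONFOUNDERS if confounders is None else list(confounders)
    consts: dict[str, tuple[float, float]] = {}
    cols: dict[str, np.ndarray] = {}
    for term in CONFOUNDER_TERMS:
        if term in _STD_MAP:
            fieldname = _STD_MAP[term]
            if fieldname not in use:
                continue
            x = pd.to_numeric(df[fieldname], errors="coerce").to_numpy(dtype=float)
            if standardization and fieldname in standardization:
                mu, sd = standardization[fieldname]
            else:
                mu, sd = float(np.nanmean(x)), float(np.nanstd(x))
                if sd == 0:
                    sd = 1.0
            consts[fieldname] = (mu, sd)
            cols[term] = (x - mu) / sd
        elif term in _DUMMY_MAP:
            fieldname, level = _DUMMY_MAP[term]
            if fieldname not in use:
                continue
            cols[term] = (df[fieldname] == level).fillna(False).to_numpy(dtype=float)
        elif term in _BOOL_TERMS:
            if term not in use:
                continue
            cols[term] = df[term].fillna(False).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index), consts


def full_design(
    df: pd.DataFrame,
    exposure: str | None = "obesity",
    standardization: dict[str, tuple[float, float]] | None = None,
    confounders: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Intercept + exposure + confounder main effects design.

    ``exposure=None`` omits the exposure column (intercept-only when the
    confounder list is also empty).
    """
    W, consts = confounder_design(df, standardization, confounders)
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    if exposure is not None:
        X[exposure] = df[exposure].astype("boolean").fillna(False).to_numpy(dtype=float)
    for c in W.columns:
        X[c] = W[c]
    return X, consts
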