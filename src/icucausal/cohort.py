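"""Patient-level data model for ICU obesity cohorts.

One row per ICU admission.  The exposure is obesity (BMI >= 30 kg/m^2 by
default), the outcome is in-hospital death, and fourteen baseline
confounders are carried: age, sex, ethnicity, income (sector-level proxy,
kEUR/year), smoking status, alcohol consumption, physical activity,
hypothyroidism, chronic glucocorticoid therapy, solid malignancy,
hematologic malignancy, dementia, HIV/AIDS, and calendar time (years since
study start).  Any non-derived field may be missing; missing is always the
pandas NA sentinel for the column's dtype (NaN for floats, pd.NA for
nullable booleans and categoricals), never an ad-hoc code.

A :class:`Cohort` wraps the data frame together with a provenance log of
the filters applied to it, so that exclusion-stage counts remain auditable
(they always telescope: output size = input size - stage exclusions).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidRecordError

# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

#: Levels of every categorical field, first level = reference level used by
#: the regression design (matching the conventional baseline categories).
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "sex": ["female", "male"],
    "ethnicity": ["Caucasian", "Asian", "Black", "Other"],
    "smoking": ["never", "ex_gt1y", "ex_lt1y", "current"],
    "alcohol": ["abstinent", "social", "problematic"],
    "physical_activity": ["none_restricted", "limited", "chair_ridden", "bed_ridden"],
    "solid_malignancy": ["none", "non_metastatic", "metastatic"],
    "heme_malignancy": ["none", "ALL", "AML", "CLL", "MM", "NHL", "other"],
    "admission_type": [
        "elective_surgery",
        "urgent_surgery",
        "trauma_burns",
        "monitoring",
        "organ_failure",
    ],
}

BOOLEAN_FIELDS = [
    "admission_reason_weight_related",
    "hypothyroidism",
    "glucocorticoids",
    "dementia",
    "hiv_aids",
    "obesity",
    "icu_death",
    "hospital_death",
]

CONTINUOUS_FIELDS = [
    "age",
    "income",
    "calendar_time",
    "height",
    "weight",
    "bmi",
    "saps2",
]

#: The 14 baseline confounders C adjusted for in every effect model.
CONFOUNDERS = [
    "age",
    "sex",
    "ethnicity",
    "income",
    "smoking",
    "alcohol",
    "physical_activity",
    "hypothyroidism",
    "glucocorticoids",
    "solid_malignancy",
    "heme_malignancy",
    "dementia",
    "hiv_aids",
    "calendar_time",
]

#: Continuous confounders that are z-standardized in regression designs.
STANDARDIZED_CONFOUNDERS = ["age", "income", "calendar_time"]

EXPOSURE = "obesity"
OUTCOME = "hospital_death"

ALL_FIELDS = (
    ["admission_id", "admission_seq"]
    + BOOLEAN_FIELDS
    + CONTINUOUS_FIELDS
    + list(CATEGORICAL_LEVELS)
)

#: BMI values outside this range are biologically implausible -> missing.
BMI_PLAUSIBLE_RANGE = (10.0, 80.0)

DEFAULT_BMI_CUTOFF = 30.0
DEFAULT_SAPS_THRESHOLD = 32.0


def is_missing(value) -> bool:
    """True for any of the package's missing sentinels (None, NaN, pd.NA)."""
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# BMI / obesity derivation
# ---------------------------------------------------------------------------

def clean_bmi(height, weight):
    """Derive BMI (kg/m^2) from height (m) and weight (kg).

    Returns NaN when either input is missing or when the derived value is
    biologically implausible (< 10 or > 80 kg/m^2, attributed to input
    error).  Raises :class:`InvalidRecordError` for non-positive height.
    """
    if not is_missing(height) and height <= 0:
        raise InvalidRecordError(f"non-positive height: {height!r}")
    if is_missing(height) or is_missing(weight):
        return float("nan")
    bmi = weight / (height * height)
    lo, hi = BMI_PLAUSIBLE_RANGE
    if bmi < lo or bmi > hi:
        return float("nan")
    return bmi


def derive_obesity(bmi, cutoff: float = DEFAULT_BMI_CUTOFF):
    """Dichotomize BMI at ``cutoff`` (default 30 kg/m^2); missing propagates."""
    if is_missing(bmi):
        return pd.NA
    return bool(bmi >= cutoff)


def derive_anthropometrics(df: pd.DataFrame, cutoff: float = DEFAULT_BMI_CUTOFF) -> pd.DataFrame:
    """Vectorized BMI cleaning + obesity derivation on a cohort frame.

    Recomputes the ``bmi`` and ``obesity`` columns in place (on a copy)
    from ``height`` and ``weight``; preserves the invariant that obesity is
    missing iff BMI is missing.
    """
    out = df.copy()
    h = pd.to_numeric(out["height"], errors="coerce").to_numpy(dtype=float)
    w = pd.to_numeric(out["weight"], errors="coerce").to_numpy(dtype=float)
    if np.any(h[~np.isnan(h)] <= 0):
        bad = np.where(~np.isnan(h) & (h <= 0))[0]
        raise InvalidRecordError(f"non-positive height at rows {bad[:5].tolist()}")
    with np.errstate(invalid="ignore"):
        bmi = w / (h * h)
    lo, hi = BMI_PLAUSIBLE_RANGE
    bmi = np.where((bmi < lo) | (bmi > hi), np.nan, bmi)
    out["bmi"] = bmi
    obesity = pd.array(bmi >= cutoff, dtype="boolean")
    obesity[np.isnan(bmi)] = pd.NA
    out["obesity"] = obesity
    return out


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A cohort of ICU admissions with a provenance log of applied filters."""

    data: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "admission_id" in self.data.columns and self.data["admission_id"].duplicated().any():
            raise InvalidRecordError("duplicate admission_id in cohort")

    def __len__(self) -> int:
        return len(self.data)

    def log(self, stage: str, n_removed: int, n_after: int, **extra) -> None:
        self.provenance.append(
            {"stage": stage, "n_removed": int(n_removed), "n_after": int(n_after), **extra}
        )

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the cohort as CSV (missing -> empty field) + JSON sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False, na_rep="")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        df = pd.read_csv(path, keep_default_na=True)
        for col in BOOLEAN_FIELDS:
            if col in df.columns:
                df[col] = df[col].map(
                    {True: True, False: False, "True": True, "False": False,
                     1: True, 0: False, 1.0: True, 0.0: False}
                ).astype("boolean")
        for col in CATEGORICAL_LEVELS:
            if col in df.columns:
                df[col] = df[col].astype("object")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        prov = json.loads(sidecar.read_text()) if sidecar.exists() else []
        return cls(df, prov)


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

def apply_exclusion_cascade(
    cohort: Cohort, saps_threshold: float = DEFAULT_SAPS_THRESHOLD
) -> Cohort:
    """Apply the study exclusion cascade, in fixed order.

    1. admissions whose reason is directly weight-related;
    2. repeat admissions (only each patient's first admission is kept);
    3. SAPS II below ``saps_threshold`` (monitoring-only admissions);
    4. SAPS II missing.

    Stage counts are order-dependent and recorded in the provenance log;
    they always telescope to the final size.
    """
    df = cohort.data
    out = Cohort(df, list(cohort.provenance))
    n0 = len(df)

    stages = [
        ("weight_related_admission_reason",
         lambda d: d["admission_reason_weight_related"].fillna(False).astype(bool)),
        ("repeat_admission", lambda d: d["admission_seq"].astype("Int64") > 1),
        ("saps2_below_threshold",
         lambda d: pd.to_numeric(d["saps2"], errors="coerce") < saps_threshold),
        ("saps2_missing", lambda d: pd.to_numeric(d["saps2"], errors="coerce").isna()),
    ]
    for name, rule in stages:
        if len(df) == 0:
            out.log(name, 0, 0)
            continue
        drop = rule(df).fillna(False).to_numpy(dtype=bool)
        df = df.loc[~drop]
        out.log(name, int(drop.sum()), len(df))
    out.data = df.reset_index(drop=True)
    assert n0 - sum(s["n_removed"] for s in out.provenance[-4:]) == len(out.data)
    return out


def complete_case_filter(
    cohort: Cohort, variables: Sequence[str]
) -> tuple[Cohort, int]:
    """Keep records with no missing value among ``variables``.

    Returns the filtered cohort and the number of discarded records.
    Unknown variable names raise :class:`ConfigError`.
    """
    unknown = [v for v in variables if v not in cohort.data.columns]
    if unknown:
        raise ConfigError(f"unknown field(s) in complete-case filter: {unknown}")
    mask = cohort.data[list(variables)].notna().all(axis=1).to_numpy(dtype=bool)
    n_discarded = int((~mask).sum())
    out = Cohort(cohort.data.loc[mask].reset_index(drop=True), list(cohort.provenance))
    out.log("complete_case_filter", n_discarded, len(out), variables=list(variables))
    return out, n_discarded


# ---------------------------------------------------------------------------
# Baseline summaries
# ---------------------------------------------------------------------------

def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    # linear-interpolation (type-7) quantiles
    return tuple(np.quantile(x, [0.25, 0.5, 0.75]))  # type: ignore[return-value]


def summarize_baseline(
    cohort: Cohort,
    continuous: Iterable[str] = ("bmi", "age", "income", "saps2", "calendar_time"),
    categorical: Iterable[str] | None = None,
    group_by: str = EXPOSURE,
) -> dict[str, pd.DataFrame]:
    """Baseline characteristic tables by exposure group.

    Returns ``{"continuous": ..., "categorical": ...}``.  Continuous
    variables get mean (SD) and median (Q1-Q3) per group; categorical
    variables get count (%) per level including an explicit ``Missing``
    level.  Percentages are of the group size (total / unexposed /
    exposed), so each variable's column sums to 100%.
    """
    df = cohort.data
    if categorical is None:
        categorical = [c for c in CATEGORICAL_LEVELS if c in df.columns]
    exposure = df[group_by].astype("boolean") if group_by in df.columns else None
    groups = {"total": df}
    if exposure is not None:
        groups["unexposed"] = df.loc[(exposure == False).fillna(False).to_numpy()]  # noqa: E712
        groups["exposed"] = df.loc[(exposure == True).fillna(False).to_numpy()]  # noqa: E712

    cont_rows = []
    for var in continuous:
        if var not in df.columns:
            continue
        for gname, gdf in groups.items():
            x = pd.to_numeric(gdf[var], errors="coerce").dropna().to_numpy(dtype=float)
            if len(x) == 0:
                row = dict(variable=var, group=gname, n=0, mean=math.nan, sd=math.nan,
                           median=math.nan, q1=math.nan, q3=math.nan)
            else:
                q1, med, q3 = _quartiles(x)
                row = dict(variable=var, group=gname, n=len(x), mean=float(np.mean(x)),
                           sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                           median=float(med), q1=float(q1), q3=float(q3))
            cont_rows.append(row)

    cat_rows = []
    bool_cats = [b for b in BOOLEAN_FIELDS if b not in (group_by,) and b in df.columns]
    for var in list(categorical) + bool_cats:
        if var in CATEGORICAL_LEVELS:
            levels = list(CATEGORICAL_LEVELS[var])
        else:
            levels = [True, False]
        for gname, gdf in groups.items():
            size = len(gdf)
            col = gdf[var]
            for level in levels + ["Missing"]:
                if level == "Missing":
                    count = int(col.isna().sum())
                else:
                    count = int((col == level).fillna(False).sum())
                pct = 100.0 * count / size if size else math.nan
                cat_rows.append(dict(variable=var, level=str(level), group=gname,
                                     count=count, pct=pct))

    return {
        "continuous": pd.DataFrame(cont_rows),
        "categorical": pd.DataFrame(cat_rows),
    }
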