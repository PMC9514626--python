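"""First-time MDD cohort construction.

Builds the incident cohort: earliest hospital MDD contact (ICD-10 F32.x/F33.x
severity-coded lists) per person within the study years, exclusion of persons
with prior competing diagnoses (bipolar, other/persistent affective disorders,
schizophrenia, dementia), of those younger than 18 at diagnosis, and of those
with prevalent TRD (second treatment shift on/before the diagnosis date).
Stratification attributes (sex, age group, diagnosis-year group, severity of
the first contact) are attached for matching, alongside the static descriptive
attributes.  An attrition log records every removal stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .registry_model import (
    SEVERITY_RANK,
    ClassificationError,
    CodeConfig,
    mark_exclusion_diagnoses,
)

__all__ = [
    "first_mdd_contact",
    "classify_severity",
    "apply_exclusions",
    "attach_strata",
    "comorbidity_flags",
    "build_cohort",
]


def classify_severity(icd_code: str, config: CodeConfig | None = None) -> str:
    """Severity {mild, moderate, severe} of an MDD code per the configured map."""
    return (config or CodeConfig()).severity_of(icd_code)


def first_mdd_contact(diagnoses: pd.DataFrame,
                      config: CodeConfig | None = None) -> pd.DataFrame:
    """Per-person earliest MDD-coded hospital contact within the study years.

    Same-day ties are broken by severity rank (severe > moderate > mild), then
    lexicographically by code.  Persons without any MDD contact are absent.
    Returns columns ``person_id, mdd_date, icd_code, severity``.
    """
    config = config or CodeConfig()
    codes = diagnoses["icd_code"].astype(str)
    is_mdd = codes.map({c: config.is_mdd(c) for c in codes.unique()})
    dx = diagnoses[is_mdd
                   & (diagnoses["date"] >= config.study_start)
                   & (diagnoses["date"] <= config.study_end)].copy()
    if not len(dx):
        return pd.DataFrame(columns=["person_id", "mdd_date", "icd_code", "severity"])
    sev_lookup = {c: config.severity_of(c) for c in dx["icd_code"].unique()}
    dx["severity"] = dx["icd_code"].map(sev_lookup)
    dx["_rank"] = dx["severity"].map(SEVERITY_RANK)
    dx = dx.sort_values(["person_id", "date", "_rank", "icd_code"],
                        ascending=[True, True, False, True], kind="stable")
    first = dx.drop_duplicates("person_id", keep="first")
    return (first.rename(columns={"date": "mdd_date"})
            [["person_id", "mdd_date", "icd_code", "severity"]]
            .reset_index(drop=True))


def _completed_years(later: pd.Series, earlier: pd.Series) -> pd.Series:
    """Age in completed years between two date series (vectorized)."""
    later = pd.to_datetime(later)
    earlier = pd.to_datetime(earlier)
    years = later.dt.year.values - earlier.dt.year.values
    before_birthday = (later.dt.month.values * 100 + later.dt.day.values) < \
                      (earlier.dt.month.values * 100 + earlier.dt.day.values)
    return pd.Series(years - before_birthday.astype(int), index=later.index)


def apply_exclusions(candidates: pd.DataFrame, diagnoses: pd.DataFrame,
                     persons: pd.DataFrame, trd_status: pd.DataFrame,
                     config: CodeConfig | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort exclusion rules; return ``(entries, attrition_log)``.

    Stages, in order: prior (on/before MDD date) exclusion-coded diagnosis;
    age < 18 at MDD date; prevalent TRD (second shift on/before MDD date).
    "Prior" includes same-day exclusion codes, since within-day events cannot
    be ordered.  The attrition log conserves counts:
    final entries + summed removals = candidate count.
    """
    config = config or CodeConfig()
    df = candidates.copy()
    log = [("mdd_candidates", len(df), 0)]

    excl_mask = mark_exclusion_diagnoses(diagnoses, config)
    excl_dx = diagnoses[excl_mask]
    if len(excl_dx):
        first_excl = excl_dx.groupby("person_id")["date"].min()
        m = df.merge(first_excl.rename("first_excl"), left_on="person_id",
                     right_index=True, how="left")
        keep = m["first_excl"].isna() | (m["first_excl"] > m["mdd_date"])
    else:
        keep = pd.Series(True, index=df.index)
    removed = int((~keep).sum())
    df = df[keep.values]
    log.append(("prior_exclusion_diagnosis", len(df), removed))

    df = df.merge(persons[["person_id", "birth_date"]], on="person_id", how="left")
    df["age_at_dx"] = _completed_years(df["mdd_date"], df["birth_date"])
    keep = df["age_at_dx"] >= 18
    removed = int((~keep).sum())
    df = df[keep].drop(columns=["birth_date"])
    log.append(("age_under_18", len(df), removed))

    prevalent = set(trd_status.loc[trd_status["prevalent_trd"], "person_id"])
    keep = ~df["person_id"].isin(prevalent)
    removed = int((~keep).sum())
    df = df[keep]
    log.append(("prevalent_trd", len(df), removed))

    attrition = pd.DataFrame(log, columns=["stage", "remaining", "removed"])
    return df.reset_index(drop=True), attrition


def attach_strata(entries: pd.DataFrame, persons: pd.DataFrame,
                  config: CodeConfig | None = None) -> pd.DataFrame:
    """Attach matching strata (age group, sex, year group, severity) and the
    descriptive attributes (education, cohabitation) to cohort entries."""
    config = config or CodeConfig()
    df = entries.merge(
        persons[["person_id", "sex", "birth_date", "education", "cohabiting"]],
        on="person_id", how="left")
    if "age_at_dx" not in df.columns:
        df["age_at_dx"] = _completed_years(df["mdd_date"], df["birth_date"])
    df["age_group"] = config.age_group(df["age_at_dx"]).values
    df["year_group"] = config.year_group(df["mdd_date"].dt.year).values
    return df.drop(columns=["birth_date"])


def comorbidity_flags(diagnoses: pd.DataFrame, index_dates: pd.DataFrame,
                      config: CodeConfig | None = None,
                      lookback_years: int = 5) -> pd.DataFrame:
    """Anxiety (F40–F48) and substance-abuse (F10–F19) flags within the
    lookback period before each person's index date (descriptive use only)."""
    config = config or CodeConfig()
    idx = index_dates[["person_id", "index_date"]]
    dx = diagnoses.merge(idx, on="person_id")
    lb = pd.to_timedelta(int(lookback_years * 365.25), unit="D")
    dx = dx[(dx["date"] >= dx["index_date"] - lb) & (dx["date"] < dx["index_date"])]
    codes = dx["icd_code"].astype(str).str.upper().str.replace(".", "", regex=False)
    num = pd.to_numeric(codes.str.lstrip("DF").str[:2], errors="coerce")
    is_f = codes.str.lstrip("D").str.startswith("F")
    dx = dx.assign(anxiety=(is_f & num.between(40, 48)).values,
                   substance_abuse=(is_f & num.between(10, 19)).values)
    flags = dx.groupby("person_id")[["anxiety", "substance_abuse"]].any()
    out = idx[["person_id"]].merge(flags, on="person_id", how="left")
    out[["anxiety", "substance_abuse"]] = (
        out[["anxiety", "substance_abuse"]].astype("boolean").fillna(False).astype(bool))
    return out


def build_cohort(bundle, trd_status: pd.DataFrame | None = None,
                 config: CodeConfig | None = None):
    """Convenience wrapper: first contact -> TRD status -> exclusions -> strata.

    Returns ``(entries, trd_status, attrition)``.
    """
    from .trd_classifier import classify_cohort

    config = config or bundle.config
    candidates = first_mdd_contact(bundle.diagnoses, config)
    if trd_status is None:
        trd_status = classify_cohort(candidates, bundle.prescriptions,
                                     bundle.procedures, config)
    entries, attrition = apply_exclusions(candidates, bundle.diagnoses,
                                          bundle.persons, trd_status, config)
    entries = attach_strata(entries, bundle.persons, config)
    return entries, trd_status, attrition
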