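"""Per-patient healthcare-resource-utilization counts and costs.

Aggregates contacts and prescription redemptions into the outcome grid of the
matched-cohort analysis, over the pre-index ([index−365 d, index−1 d]) and
post-index ([index+1 d, index+365 d]) years; the index day itself belongs to
neither window (the TRD-defining redemption is itself a cost event and would
otherwise contaminate the post year).

Count outcomes (21): psychiatric and somatic hospitalizations and hospital bed
days with acute/elective splits, ED visits, outpatient visits, psychiatric home
visits, private psychiatrist/psychologist visits, GP visits, other-specialist
visits.  Hospitalizations and visit-type contacts are counted at their start
date; bed days are in-window *nights* (clipped to the window), with a floor of
one bed day for completed same-day inpatient stays.

Cost outcomes (9, EUR): psychiatric (hospital psychiatric services + private
psychiatrist + private psychologist + home visits), somatic, GP,
other-specialist, three medicine groups by ATC prefix (antidepressant N06A;
other psychiatric N05A/N05B; remainder), and the two totals.  Additivity holds
per patient: acute + elective = overall; total excl. medicine = psychiatric +
somatic + GP + other specialist; total incl. medicine adds the three medicine
groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .registry_model import CodeConfig, ConfigError

__all__ = [
    "COUNT_OUTCOMES",
    "COST_OUTCOMES",
    "window_bounds",
    "count_hru",
    "cost_hru",
    "summarize_population",
    "summarize_by_group",
]

COUNT_OUTCOMES = [
    "psych_hospitalization", "psych_hospitalization_acute", "psych_hospitalization_elective",
    "psych_bed_days", "psych_bed_days_acute", "psych_bed_days_elective",
    "psych_ed", "psych_outpatient", "psych_home_visit",
    "private_psychiatrist", "private_psychologist",
    "somatic_hospitalization", "somatic_hospitalization_acute", "somatic_hospitalization_elective",
    "somatic_bed_days", "somatic_bed_days_acute", "somatic_bed_days_elective",
    "somatic_ed", "somatic_outpatient",
    "gp", "other_specialist",
]

COST_OUTCOMES = [
    "cost_total_excl_medicine", "cost_total_incl_medicine",
    "cost_psychiatric", "cost_somatic", "cost_gp", "cost_other_specialist",
    "cost_medicine_other", "cost_medicine_other_psychiatric",
    "cost_medicine_antidepressant",
]

ALL_OUTCOMES = COUNT_OUTCOMES + COST_OUTCOMES

_VISIT_CATEGORY = {
    ("psychiatric", "ed"): "psych_ed",
    ("psychiatric", "outpatient"): "psych_outpatient",
    ("psychiatric", "home_visit"): "psych_home_visit",
    ("somatic", "ed"): "somatic_ed",
    ("somatic", "outpatient"): "somatic_outpatient",
    ("primary", "gp"): "gp",
    ("primary", "private_psychiatrist"): "private_psychiatrist",
    ("primary", "private_psychologist"): "private_psychologist",
    ("primary", "other_specialist"): "other_specialist",
}

# cost bucket per (sector, contact_type); private psychiatrist/psychologist
# visits belong to the psychiatric cost category
_COST_CATEGORY = {
    ("psychiatric", "hospitalization"): "cost_psychiatric",
    ("psychiatric", "ed"): "cost_psychiatric",
    ("psychiatric", "outpatient"): "cost_psychiatric",
    ("psychiatric", "home_visit"): "cost_psychiatric",
    ("primary", "private_psychiatrist"): "cost_psychiatric",
    ("primary", "private_psychologist"): "cost_psychiatric",
    ("somatic", "hospitalization"): "cost_somatic",
    ("somatic", "ed"): "cost_somatic",
    ("somatic", "outpatient"): "cost_somatic",
    ("primary", "gp"): "cost_gp",
    ("primary", "other_specialist"): "cost_other_specialist",
}

_MED_COLUMN = {
    "antidepressant": "cost_medicine_antidepressant",
    "other_psychiatric": "cost_medicine_other_psychiatric",
    "other": "cost_medicine_other",
}


def window_bounds(index_date, which: str,
                  config: CodeConfig | None = None) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Inclusive date bounds of the pre- or post-index year."""
    config = config or CodeConfig()
    idx = pd.Timestamp(index_date)
    w = config.window_days
    if which == "pre":
        return idx - pd.Timedelta(days=w), idx - pd.Timedelta(days=1)
    if which == "post":
        start = 0 if config.include_index_day_in_post else 1
        return idx + pd.Timedelta(days=start), idx + pd.Timedelta(days=w)
    raise ValueError(f"window must be 'pre' or 'post', got {which!r}")


def _window_frame(members: pd.DataFrame, which: str, config: CodeConfig) -> pd.DataFrame:
    idx = pd.to_datetime(members["index_date"])
    w = config.window_days
    if which == "pre":
        start, end = idx - pd.Timedelta(days=w), idx - pd.Timedelta(days=1)
    else:
        s0 = 0 if config.include_index_day_in_post else 1
        start, end = idx + pd.Timedelta(days=s0), idx + pd.Timedelta(days=w)
    return pd.DataFrame({"person_id": members["person_id"].values,
                         "wstart": start.values, "wend": end.values})


def _aggregate_window(contacts: pd.DataFrame, prescriptions: pd.DataFrame,
                      members: pd.DataFrame, which: str,
                      config: CodeConfig) -> pd.DataFrame:
    """Wide per-person outcome table for one window (rows = members)."""
    win = _window_frame(members, which, config)
    contribs: list[pd.DataFrame] = []

    ct = contacts.merge(win, on="person_id") if len(contacts) else contacts.assign(
        wstart=pd.NaT, wend=pd.NaT)
    if len(ct):
        started = (ct["start_date"] >= ct["wstart"]) & (ct["start_date"] <= ct["wend"])

        is_hosp = ct["contact_type"] == "hospitalization"
        side = np.where(ct["sector"] == "psychiatric", "psych", "somatic")

        hosp = ct[started & is_hosp]
        if len(hosp):
            s = np.where(hosp["sector"] == "psychiatric", "psych", "somatic")
            for outcome in (s + "_hospitalization",
                            s + "_hospitalization_" + hosp["admission_mode"].values):
                contribs.append(pd.DataFrame({
                    "person_id": hosp["person_id"].values,
                    "outcome": outcome, "value": 1.0}))

        # bed days: any stay overlapping the window contributes clipped nights
        stays = ct[is_hosp]
        if len(stays):
            nights = (np.minimum(stays["end_date"].values, stays["wend"].values)
                      - np.maximum(stays["start_date"].values, stays["wstart"].values)
                      ) / np.timedelta64(1, "D")
            same_day = (stays["end_date"].values == stays["start_date"].values)
            in_start = ((stays["start_date"] >= stays["wstart"])
                        & (stays["start_date"] <= stays["wend"])).values
            nights = np.where(same_day, np.where(in_start, 1.0, 0.0),
                              np.clip(nights, 0, None))
            s = np.where(stays["sector"] == "psychiatric", "psych", "somatic")
            keep = nights > 0
            for outcome in (s + "_bed_days",
                            s + "_bed_days_" + stays["admission_mode"].values):
                contribs.append(pd.DataFrame({
                    "person_id": stays["person_id"].values[keep],
                    "outcome": outcome[keep], "value": nights[keep]}))

        visits = ct[started & ~is_hosp]
        if len(visits):
            cat = pd.MultiIndex.from_arrays(
                [visits["sector"], visits["contact_type"]]).map(_VISIT_CATEGORY)
            contribs.append(pd.DataFrame({
                "person_id": visits["person_id"].values,
                "outcome": np.asarray(cat, dtype=object), "value": 1.0}))

        # costs: contacts attributed at start date
        priced = ct[started]
        if len(priced):
            if config.cost_mode == "fixed":
                key = (priced["sector"] + ":" + priced["contact_type"]
                       + ":" + priced["admission_mode"])
                missing = sorted(set(key) - set(config.fixed_price_table))
                if missing:
                    raise ConfigError(f"no fixed price configured for {missing}")
                cost = key.map(config.fixed_price_table).values
            elif config.cost_mode == "recorded":
                cost = priced["cost_eur"].values
            else:
                raise ConfigError(f"unknown cost_mode {config.cost_mode!r}")
            bucket = pd.MultiIndex.from_arrays(
                [priced["sector"], priced["contact_type"]]).map(_COST_CATEGORY)
            contribs.append(pd.DataFrame({
                "person_id": priced["person_id"].values,
                "outcome": np.asarray(bucket, dtype=object),
                "value": np.asarray(cost, dtype=float)}))

    rx = prescriptions.merge(win, on="person_id") if len(prescriptions) else None
    if rx is not None and len(rx):
        rx = rx[(rx["redemption_date"] >= rx["wstart"])
                & (rx["redemption_date"] <= rx["wend"])]
        if len(rx):
            groups = {c: _MED_COLUMN[config.medicine_group(c)]
                      for c in rx["atc_code"].astype(str).unique()}
            contribs.append(pd.DataFrame({
                "person_id": rx["person_id"].values,
                "outcome": rx["atc_code"].astype(str).map(groups).values,
                "value": rx["cost_eur"].astype(float).values}))

    if contribs:
        long = pd.concat(contribs, ignore_index=True)
        wide = (long.groupby(["person_id", "outcome"])["value"].sum()
                .unstack(fill_value=0.0))
    else:
        wide = pd.DataFrame()
    wide = wide.reindex(index=members["person_id"].values,
                        columns=ALL_OUTCOMES, fill_value=0.0).fillna(0.0)
    wide["cost_total_excl_medicine"] = (
        wide["cost_psychiatric"] + wide["cost_somatic"]
        + wide["cost_gp"] + wide["cost_other_specialist"])
    wide["cost_total_incl_medicine"] = (
        wide["cost_total_excl_medicine"] + wide["cost_medicine_other"]
        + wide["cost_medicine_other_psychiatric"]
        + wide["cost_medicine_antidepressant"])
    wide.index.name = "person_id"
    wide.insert(0, "window", which)
    return wide.reset_index()


def count_hru(contacts: pd.DataFrame, person_id: str, index_date, which: str,
              config: CodeConfig | None = None) -> dict[str, float]:
    """Windowed HRU counts for a single person (convenience wrapper)."""
    config = config or CodeConfig()
    members = pd.DataFrame({"person_id": [person_id], "index_date": [pd.Timestamp(index_date)]})
    sub = contacts[contacts["person_id"] == person_id]
    empty_rx = pd.DataFrame(columns=["person_id", "redemption_date", "atc_code", "cost_eur"])
    wide = _aggregate_window(sub, empty_rx, members, which, config)
    return {k: float(wide.at[0, k]) for k in COUNT_OUTCOMES}


def cost_hru(contacts: pd.DataFrame, prescriptions: pd.DataFrame, person_id: str,
             index_date, which: str,
             config: CodeConfig | None = None) -> dict[str, float]:
    """Windowed EUR costs for a single person (convenience wrapper)."""
    config = config or CodeConfig()
    members = pd.DataFrame({"person_id": [person_id], "index_date": [pd.Timestamp(index_date)]})
    ct = contacts[contacts["person_id"] == person_id]
    rx = prescriptions[prescriptions["person_id"] == person_id]
    wide = _aggregate_window(ct, rx, members, which, config)
    return {k: float(wide.at[0, k]) for k in COST_OUTCOMES}


def summarize_population(bundle, matched: pd.DataFrame,
                         config: CodeConfig | None = None) -> pd.DataFrame:
    """Per-person windowed outcome summaries for the matched population.

    ``matched`` is the long matched cohort (from the matcher); returns one row
    per person and window with all count and cost outcome columns plus the
    member attributes (set id, group, role, strata).
    """
    config = config or bundle.config
    attrs = ["set_id", "person_id", "role", "group",
             "age_group", "sex", "year_group", "severity"]
    members = matched[[c for c in attrs if c in matched.columns] + ["index_date"]]
    frames = []
    for which in ("pre", "post"):
        wide = _aggregate_window(bundle.contacts, bundle.prescriptions,
                                 members, which, config)
        frames.append(members.drop(columns=["index_date"]).merge(wide, on="person_id"))
    return pd.concat(frames, ignore_index=True)


def summarize_by_group(summaries: pd.DataFrame,
                       outcomes: list[str] | None = None) -> pd.DataFrame:
    """Descriptive mean and sample SD per outcome, group and window.

    SD uses ddof=1; a single-patient cell reports sd 0.0 and is flagged in the
    ``note`` column.
    """
    outcomes = outcomes or ALL_OUTCOMES
    rows = []
    for (group, window), grp in summaries.groupby(["group", "window"]):
        n = len(grp)
        for outcome in outcomes:
            vals = grp[outcome]
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            rows.append({
                "outcome": outcome, "group": group, "window": window,
                "mean": float(vals.mean()) if n else np.nan,
                "sd": sd, "n": n,
                "note": "" if n > 1 else "single patient: sd undefined, reported as 0",
            })
    return pd.DataFrame(rows)
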