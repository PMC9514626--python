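"""1:2 exact matching of TRD cases to non-TRD MDD controls.

Cases and controls are matched exactly on the four stratification variables
(age group, sex, diagnosis-year group, depression severity).  Controls are
sampled without replacement; each control inherits the case's
diagnosis-to-index offset: control index date = control MDD date + (case index
date − case MDD date).  After matching, the cohort is conditioned on complete
follow-up — any member who dies, emigrates, or develops an exclusion diagnosis
on/before index + 365 days is removed, and sets that lose their case or all
controls are dissolved.

Matching is randomized but fully deterministic for a fixed seed: cases and
per-stratum control pools are sorted by person id before seeded shuffling, so
the matched cohort is byte-identical across runs regardless of input row order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .registry_model import CodeConfig, mark_exclusion_diagnoses

__all__ = ["match_cohort", "condition_followup"]

STRATUM_COLS = ["age_group", "sex", "year_group", "severity"]


def match_cohort(cases: pd.DataFrame, controls: pd.DataFrame, seed: int,
                 config: CodeConfig | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match each case to up to ``config.n_controls`` stratum-identical controls.

    ``cases`` must carry ``person_id``, the stratum columns, ``mdd_date`` and
    ``index_date``; ``controls`` must carry ``person_id``, the stratum columns
    and ``mdd_date``.  Cases are processed in seeded random order; controls are
    drawn uniformly without replacement from the unused pool of their stratum.
    With ``allow_partial_match`` (default) a case keeps a 1-control set when
    the pool holds only one; otherwise it is unmatched.

    Returns ``(matched, attrition)`` where ``matched`` is long format — one row
    per member with ``set_id``, ``role`` (case/control), ``group`` (TRD /
    nonTRD), ``case_offset_days`` and the member's own ``index_date``.
    """
    config = config or CodeConfig()
    rng = np.random.default_rng(seed)

    cases = cases.sort_values("person_id", kind="stable").reset_index(drop=True)
    controls = controls.sort_values("person_id", kind="stable").reset_index(drop=True)
    if not len(controls):
        import warnings
        warnings.warn("control pool is empty; no sets formed")

    offsets = (pd.to_datetime(cases["index_date"])
               - pd.to_datetime(cases["mdd_date"])).dt.days

    pools: dict[tuple, list[int]] = {}
    for key, grp in sorted(controls.groupby(list(STRATUM_COLS)).groups.items()):
        idx = np.asarray(sorted(grp))
        pools[key] = list(idx[rng.permutation(len(idx))])

    order = rng.permutation(len(cases))
    rows = []
    n_full = n_partial = n_unmatched = 0
    ctrl_records = controls.to_dict("records")
    case_records = cases.to_dict("records")
    for ci in order:
        case = case_records[ci]
        key = tuple(case[c] for c in STRATUM_COLS)
        pool = pools.get(key, [])
        take = min(config.n_controls, len(pool))
        if take == 0 or (take < config.n_controls and not config.allow_partial_match):
            n_unmatched += 1
            continue
        chosen = [pool.pop() for _ in range(take)]
        if take == config.n_controls:
            n_full += 1
        else:
            n_partial += 1
        off = int(offsets.iloc[ci])
        set_id = case["person_id"]
        rows.append({
            "set_id": set_id, "person_id": case["person_id"], "role": "case",
            "group": "TRD", "mdd_date": case["mdd_date"],
            "index_date": case["index_date"], "case_offset_days": off,
            **{c: case[c] for c in STRATUM_COLS},
        })
        for j in chosen:
            ctrl = ctrl_records[j]
            rows.append({
                "set_id": set_id, "person_id": ctrl["person_id"], "role": "control",
                "group": "nonTRD", "mdd_date": ctrl["mdd_date"],
                "index_date": pd.Timestamp(ctrl["mdd_date"]) + pd.Timedelta(days=off),
                "case_offset_days": off,
                **{c: ctrl[c] for c in STRATUM_COLS},
            })

    matched = pd.DataFrame(rows, columns=[
        "set_id", "person_id", "role", "group", "mdd_date", "index_date",
        "case_offset_days", *STRATUM_COLS])
    matched = matched.sort_values(["set_id", "role", "person_id"],
                                  kind="stable").reset_index(drop=True)
    attrition = pd.DataFrame(
        [("cases_total", len(cases), 0),
         ("cases_matched_full", n_full, 0),
         ("cases_matched_partial", n_partial, 0),
         ("cases_unmatched", n_unmatched, n_unmatched)],
        columns=["stage", "count", "removed"])
    return matched, attrition


def condition_followup(matched: pd.DataFrame, persons: pd.DataFrame,
                       diagnoses: pd.DataFrame,
                       config: CodeConfig | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict to members with complete one-year follow-up after index.

    Removes any member with death, emigration, or an exclusion-coded diagnosis
    dated on/before index + window days; dissolves sets losing their case or
    all controls.  Returns ``(matched, attrition_log)``.
    """
    config = config or CodeConfig()
    if not len(matched):
        return matched.copy(), pd.DataFrame(columns=["stage", "count", "removed"])
    w = pd.Timedelta(days=config.window_days)
    df = matched.merge(persons[["person_id", "death_date", "emigration_date"]],
                       on="person_id", how="left")
    limit = pd.to_datetime(df["index_date"]) + w
    dead = df["death_date"].notna() & (df["death_date"] <= limit)
    emigrated = df["emigration_date"].notna() & (df["emigration_date"] <= limit)

    excl_dx = diagnoses[mark_exclusion_diagnoses(diagnoses, config)]
    if len(excl_dx):
        first_excl = excl_dx.groupby("person_id")["date"].min()
        fe = df["person_id"].map(first_excl)
        excluded = fe.notna() & (fe <= limit)
    else:
        excluded = pd.Series(False, index=df.index)

    removed = dead | emigrated | excluded
    kept = df[~removed].drop(columns=["death_date", "emigration_date"])

    case_alive = set(kept.loc[kept["role"] == "case", "set_id"])
    ctrl_alive = set(kept.loc[kept["role"] == "control", "set_id"])
    valid_sets = case_alive & ctrl_alive
    before_sets = matched["set_id"].nunique()
    dissolved_case = matched["set_id"].nunique() - len(case_alive & set(matched["set_id"]))
    out = kept[kept["set_id"].isin(valid_sets)].reset_index(drop=True)

    attrition = pd.DataFrame(
        [("members_before_conditioning", len(matched), 0),
         ("removed_death", 0, int(dead.sum())),
         ("removed_emigration", 0, int((emigrated & ~dead).sum())),
         ("removed_exclusion_diagnosis", 0, int((excluded & ~dead & ~emigrated).sum())),
         ("sets_dissolved", 0, before_sets - len(valid_sets)),
         ("members_after_conditioning", len(out), 0)],
        columns=["stage", "count", "removed"])
    return out, attrition
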