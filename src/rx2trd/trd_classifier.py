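"""Treatment-shift detection and TRD classification.

Treatment-resistant depression is operationalized from prescription and
procedure sequences: within the window [MDD − 365 d, MDD + 365 d], the first
new-treatment event (first in-window redemption of an antidepressant substance
at ATC level 5, or the first in-window ECT) is treatment *initiation*; every
subsequent distinct new-treatment event is a *shift* (a switch to a new
substance, an add-on to ongoing therapy, or ECT initiation).  TRD is defined at
the second shift; its date is the TRD index date.

Two shift semantics are supported:

* default (*new-substance*): only first-time substances count, so the sequence
  A → B → A yields one shift;
* ``re_initiation_counts=True`` (*change-from-previous*): every transition to a
  substance different from the immediately preceding one counts, so A → B → A
  yields two shifts.

``shift_oracle`` is an independent brute-force re-derivation (explicit
day-by-day replay) used only for verification in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .registry_model import CodeConfig

__all__ = [
    "TreatmentShift",
    "TrdStatus",
    "substance_class",
    "detect_shifts",
    "classify_trd",
    "classify_cohort",
    "shift_oracle",
]

ECT = "ECT"


@dataclass(frozen=True)
class TreatmentShift:
    person_id: str | None
    date: pd.Timestamp
    kind: str                 # switch | add_on | ect
    new_treatment: str        # ATC level-5 code or "ECT"
    prior_active: frozenset   # substances redeemed within the activity window


@dataclass(frozen=True)
class TrdStatus:
    person_id: str | None
    is_trd: bool
    index_date: pd.Timestamp | None
    n_shifts_in_window: int
    prevalent_trd: bool


def substance_class(atc_code: str, config: CodeConfig | None = None) -> str:
    """Antidepressant class (SSRI/SNRI/TCA/MAOI) by longest matching configured
    ATC prefix; ``none`` for non-antidepressants."""
    return (config or CodeConfig()).atc_class(atc_code)


def _as_events(prescriptions, procedures, config: CodeConfig):
    """Normalize inputs to (date, substance) redemption pairs and ECT dates.

    Accepts DataFrames (``redemption_date``/``atc_code``, ``date``/``sks_code``)
    or iterables of ``(date, code)`` pairs.  Non-antidepressant redemptions are
    dropped; procedure rows whose code is not a configured ECT code are dropped.
    """
    def _ts(d):
        return pd.Timestamp(d)

    rx: list[tuple[pd.Timestamp, str]] = []
    if prescriptions is not None:
        if isinstance(prescriptions, pd.DataFrame):
            it = zip(prescriptions["redemption_date"], prescriptions["atc_code"])
        else:
            it = iter(prescriptions)
        for d, code in it:
            if config.atc_class(code) != "none":
                rx.append((_ts(d), str(code)))
    ect: list[pd.Timestamp] = []
    if procedures is not None:
        if isinstance(procedures, pd.DataFrame):
            it = zip(procedures["date"], procedures["sks_code"])
        else:
            it = iter(procedures)
        for d, code in it:
            if str(code) in config.ect_codes:
                ect.append(_ts(d))
    return rx, ect


def detect_shifts(prescriptions, procedures, mdd_date,
                  config: CodeConfig | None = None,
                  person_id: str | None = None) -> list[TreatmentShift]:
    """Ordered treatment shifts for one person inside the ±window around MDD.

    Output is sorted by date; same-day distinct new treatments each count once,
    ordered lexicographically by treatment name.  Shift kind is ``ect`` for
    ECT, ``add_on`` when any other substance was redeemed within the preceding
    ``activity_window_days``, else ``switch``.
    """
    config = config or CodeConfig()
    mdd = pd.Timestamp(mdd_date)
    lo = mdd - pd.Timedelta(days=config.window_days)
    hi = mdd + pd.Timedelta(days=config.window_days)
    rx, ect = _as_events(prescriptions, procedures, config)
    rx_in = sorted((d, s) for d, s in rx if lo <= d <= hi)
    ect_in = sorted(d for d in ect if lo <= d <= hi)

    events: list[tuple[pd.Timestamp, str]] = []
    if not config.re_initiation_counts:
        first: dict[str, pd.Timestamp] = {}
        for d, s in rx_in:
            if s not in first:
                first[s] = d
        events = [(d, s) for s, d in first.items()]
        if ect_in:
            events.append((ect_in[0], ECT))
        events.sort(key=lambda t: (t[0], t[1]))
    else:
        stream = sorted(
            [(d, s) for d, s in rx_in] + [(d, ECT) for d in ect_in],
            key=lambda t: (t[0], t[1]))
        last = None
        for d, s in stream:
            if s != last:
                events.append((d, s))
                last = s

    if config.min_days_between_shifts > 0:
        kept: list[tuple[pd.Timestamp, str]] = []
        for d, s in events:
            if not kept or (d - kept[-1][0]).days >= config.min_days_between_shifts:
                kept.append((d, s))
        events = kept

    if not events:
        return []
    if config.ect_always_shift:
        # every ECT event is a shift; initiation is the first substance event
        first_sub = next((i for i, (_, s) in enumerate(events) if s != ECT), None)
        shift_events = [e for i, e in enumerate(events) if i != first_sub]
    else:
        shift_events = events[1:]

    shifts: list[TreatmentShift] = []
    act = pd.Timedelta(days=config.activity_window_days)
    for d, s in shift_events:
        if s == ECT:
            kind = "ect"
            prior = frozenset(sub for rd, sub in rx_in if d - act <= rd <= d)
        else:
            prior = frozenset(
                sub for rd, sub in rx_in if sub != s and d - act <= rd <= d)
            kind = "add_on" if prior else "switch"
        shifts.append(TreatmentShift(person_id, d, kind, s, prior))
    return shifts


def classify_trd(mdd_date, shifts: Sequence[TreatmentShift],
                 person_id: str | None = None) -> TrdStatus:
    """TRD at the second shift; ``prevalent_trd`` when it falls on/before the
    MDD diagnosis date (such patients are excluded from the incident cohort)."""
    mdd = pd.Timestamp(mdd_date)
    n = len(shifts)
    if n >= 2:
        idx = shifts[1].date
        return TrdStatus(person_id, True, idx, n, idx <= mdd)
    return TrdStatus(person_id, False, None, n, False)


def classify_cohort(cohort: pd.DataFrame, prescriptions: pd.DataFrame,
                    procedures: pd.DataFrame,
                    config: CodeConfig | None = None) -> pd.DataFrame:
    """Vectorized TRD status for a whole cohort.

    ``cohort`` needs ``person_id`` and ``mdd_date``.  Returns one row per
    cohort person: ``is_trd``, ``index_date``, ``n_shifts_in_window``,
    ``prevalent_trd``.  Semantics match :func:`detect_shifts` exactly; the
    non-default flag combinations fall back to the per-person path.
    """
    config = config or CodeConfig()
    if config.re_initiation_counts or config.ect_always_shift \
            or config.min_days_between_shifts > 0:
        return _classify_cohort_slow(cohort, prescriptions, procedures, config)

    base = cohort[["person_id", "mdd_date"]]
    w = pd.Timedelta(days=config.window_days)

    parts = []
    if len(prescriptions):
        rx = prescriptions.merge(base, on="person_id")
        atc = rx["atc_code"].astype(str)
        mask = pd.Series(False, index=rx.index)
        for prefixes in config.antidepressant_class_prefixes.values():
            for p in prefixes:
                mask |= atc.str.startswith(p.upper())
        rx = rx[mask
                & (rx["redemption_date"] >= rx["mdd_date"] - w)
                & (rx["redemption_date"] <= rx["mdd_date"] + w)]
        parts.append(rx.rename(columns={"redemption_date": "date", "atc_code": "treatment"})[
            ["person_id", "date", "treatment", "mdd_date"]])
    if len(procedures):
        pr = procedures[procedures["sks_code"].isin(config.ect_codes)]
        pr = pr.merge(base, on="person_id")
        pr = pr[(pr["date"] >= pr["mdd_date"] - w) & (pr["date"] <= pr["mdd_date"] + w)]
        pr = pr.assign(treatment=ECT)[["person_id", "date", "treatment", "mdd_date"]]
        parts.append(pr)

    out = base.copy()
    out["is_trd"] = False
    out["index_date"] = pd.NaT
    out["n_shifts_in_window"] = 0
    out["prevalent_trd"] = False
    if not parts:
        return out

    ev = pd.concat(parts, ignore_index=True)
    # first in-window occurrence per distinct treatment
    ev = ev.sort_values(["person_id", "date", "treatment"], kind="stable")
    ev = ev.drop_duplicates(["person_id", "treatment"], keep="first")
    ev = ev.sort_values(["person_id", "date", "treatment"], kind="stable")
    ev["rank"] = ev.groupby("person_id").cumcount()

    counts = ev.groupby("person_id").size() - 1  # events minus initiation
    second = ev[ev["rank"] == 2].set_index("person_id")

    out = out.set_index("person_id")
    out["n_shifts_in_window"] = counts.reindex(out.index).fillna(0).astype(int).clip(lower=0)
    out["is_trd"] = out["n_shifts_in_window"] >= 2
    out.loc[second.index, "index_date"] = second["date"]
    out["prevalent_trd"] = out["is_trd"] & (out["index_date"] <= out["mdd_date"])
    return out.reset_index()[["person_id", "mdd_date", "is_trd", "index_date",
                              "n_shifts_in_window", "prevalent_trd"]]


def _classify_cohort_slow(cohort, prescriptions, procedures, config):
    rx_by = dict(tuple(prescriptions.groupby("person_id"))) if len(prescriptions) else {}
    pr_by = dict(tuple(procedures.groupby("person_id"))) if len(procedures) else {}
    rows = []
    for _, row in cohort.iterrows():
        pid = row["person_id"]
        shifts = detect_shifts(rx_by.get(pid), pr_by.get(pid), row["mdd_date"],
                               config, person_id=pid)
        st = classify_trd(row["mdd_date"], shifts, person_id=pid)
        rows.append((pid, row["mdd_date"], st.is_trd, st.index_date,
                     st.n_shifts_in_window, st.prevalent_trd))
    return pd.DataFrame(rows, columns=["person_id", "mdd_date", "is_trd",
                                       "index_date", "n_shifts_in_window",
                                       "prevalent_trd"])


def shift_oracle(prescriptions, procedures, mdd_date,
                 config: CodeConfig | None = None) -> list[pd.Timestamp]:
    """Brute-force reference: re-derive the shift dates by replaying every day
    of the window explicitly.  Intended for verification on small inputs only.
    """
    config = config or CodeConfig()
    mdd = pd.Timestamp(mdd_date)
    lo = mdd - pd.Timedelta(days=config.window_days)
    hi = mdd + pd.Timedelta(days=config.window_days)
    rx, ect = _as_events(prescriptions, procedures, config)
    by_day: dict[pd.Timestamp, list[str]] = {}
    for d, s in rx:
        if lo <= d <= hi:
            by_day.setdefault(d, []).append(s)
    for d in ect:
        if lo <= d <= hi:
            by_day.setdefault(d, []).append(ECT)

    events: list[tuple[pd.Timestamp, str]] = []
    if not config.re_initiation_counts:
        seen: set[str] = set()
        for day in sorted(by_day):
            for name in sorted(set(by_day[day])):
                if name not in seen:
                    seen.add(name)
                    events.append((day, name))
    else:
        last = None
        for day in sorted(by_day):
            for name in sorted(by_day[day]):
                if name != last:
                    events.append((day, name))
                    last = name

    if config.min_days_between_shifts > 0:
        kept = []
        for d, s in events:
            if not kept or (d - kept[-1][0]).days >= config.min_days_between_shifts:
                kept.append((d, s))
        events = kept

    if not events:
        return []
    if config.ect_always_shift:
        out = []
        initiation_taken = False
        for d, s in events:
            if s != ECT and not initiation_taken:
                initiation_taken = True
                continue
            out.append(d)
        return out
    return [d for d, _ in events[1:]]
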