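from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rx2trd import CodeConfig, RegistryBundle, SimulationConfig, run_pipeline

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def codes() -> CodeConfig:
    return CodeConfig()


def make_persons(ids, **overrides) -> pd.DataFrame:
    n = len(ids)
    df = pd.DataFrame({
        "person_id": ids,
        "sex": ["F"] * n,
        "birth_date": pd.to_datetime(["1970-01-01"] * n),
        "death_date": pd.NaT,
        "emigration_date": pd.NaT,
        "education": ["basic"] * n,
        "cohabiting": ["yes"] * n,
    })
    for col, values in overrides.items():
        df[col] = values
    return df


def make_bundle(persons=None, diagnoses=None, prescriptions=None,
                procedures=None, contacts=None, config=None) -> RegistryBundle:
    """Small hand-rolled bundle with schema-complete empty defaults."""
    if persons is None:
        persons = make_persons(["P1"])
    empty = {
        "diagnoses": pd.DataFrame({
            "person_id": pd.Series(dtype=object),
            "date": pd.Series(dtype="datetime64[ns]"),
            "icd_code": pd.Series(dtype=object),
            "setting": pd.Series(dtype=object)}),
        "prescriptions": pd.DataFrame({
            "person_id": pd.Series(dtype=object),
            "redemption_date": pd.Series(dtype="datetime64[ns]"),
            "atc_code": pd.Series(dtype=object),
            "cost_eur": pd.Series(dtype=float)}),
        "procedures": pd.DataFrame({
            "person_id": pd.Series(dtype=object),
            "date": pd.Series(dtype="datetime64[ns]"),
            "sks_code": pd.Series(dtype=object)}),
        "contacts": pd.DataFrame({
            "person_id": pd.Series(dtype=object),
            "start_date": pd.Series(dtype="datetime64[ns]"),
            "end_date": pd.Series(dtype="datetime64[ns]"),
            "sector": pd.Series(dtype=object),
            "contact_type": pd.Series(dtype=object),
            "admission_mode": pd.Series(dtype=object),
            "cost_eur": pd.Series(dtype=float)}),
    }
    return RegistryBundle(
        persons=persons,
        diagnoses=diagnoses if diagnoses is not None else empty["diagnoses"],
        prescriptions=prescriptions if prescriptions is not None else empty["prescriptions"],
        procedures=procedures if procedures is not None else empty["procedures"],
        contacts=contacts if contacts is not None else empty["contacts"],
        config=config or CodeConfig(),
    )


def rx_frame(rows) -> pd.DataFrame:
    """rows: (person_id, date, atc_code[, cost])"""
    recs = [(r + (10.0,))[:4] for r in rows]
    df = pd.DataFrame(recs, columns=["person_id", "redemption_date", "atc_code", "cost_eur"])
    df["redemption_date"] = pd.to_datetime(df["redemption_date"])
    return df


def proc_frame(rows) -> pd.DataFrame:
    """rows: (person_id, date, sks_code)"""
    df = pd.DataFrame(rows, columns=["person_id", "date", "sks_code"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def dx_frame(rows) -> pd.DataFrame:
    """rows: (person_id, date, icd_code[, setting])"""
    recs = [(r + ("psych_outpatient",))[:4] for r in rows]
    df = pd.DataFrame(recs, columns=["person_id", "date", "icd_code", "setting"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def contact_frame(rows) -> pd.DataFrame:
    """rows: (person_id, start, end, sector, contact_type, admission_mode, cost)"""
    df = pd.DataFrame(rows, columns=["person_id", "start_date", "end_date",
                                     "sector", "contact_type", "admission_mode",
                                     "cost_eur"])
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    return df


@pytest.fixture(scope="session")
def realistic_run():
    """A moderately sized realistic-mode pipeline run, reused across tests."""
    sim = SimulationConfig(n_persons=3000, seed=42)
    return run_pipeline(sim=sim)


@pytest.fixture(scope="session")
def calibration_run():
    """Calibration-mode run with a known any-use target (0.2 vs 0.4)."""
    sim = SimulationConfig.calibration(
        n_persons=6000, seed=11, p_resistant=1 / 3,
        any_use_probs={"psych_hospitalization_acute": (0.2, 0.4)})
    return run_pipeline(sim=sim)
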