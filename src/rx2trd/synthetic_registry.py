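"""Synthetic health-registry generator with known ground truth.

Emulates the joint structure the matched-cohort analysis assumes: every person
has one first-time MDD hospital diagnosis with a severity-coded ICD-10 code; a
latent *resistance* flag drives both antidepressant prescription switching
(and hence algorithmic TRD status) and healthcare-resource-utilization
intensity through per-category rate multipliers.  Death, emigration and
exclusion diagnoses can be injected after the index period to exercise the
complete-follow-up conditioning step.

Two regimes:

* ``realistic`` — stochastic redemption schedules with per-redemption switch
  hazards, over-dispersed (gamma-Poisson) contact counts, ECT among resistant
  severe patients.
* ``calibration`` — switching is deterministic: resistant persons redeem three
  distinct substances at fixed offsets (two treatment shifts inside the ±1-year
  window), non-resistant persons redeem a single substance; the TRD classifier
  then recovers the latent flag exactly, enabling clean parameter recovery.
  Optional ``any_use_probs`` replaces count generation for a category with a
  Bernoulli any-use draw in the post-index year, giving the two-part model a
  known binomial target.

Counts are generated over the three-year span [MDD−365 d, MDD+730 d] with event
dates uniform on the span, so the expected count in any 365-day window equals
the configured annual rate.  Fixed seed ⇒ byte-identical output; one RNG
substream per table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registry_model import CodeConfig, ConfigError, RegistryBundle

__all__ = [
    "SimulationConfig",
    "simulate_registry",
    "simulate_null",
    "GENERATOR_CATEGORIES",
    "SUBSTANCE_POOL",
]

# (category, sector, contact_type, admission_mode) for every generated
# contact stream; categories with an admission split are generated separately.
GENERATOR_CATEGORIES: list[tuple[str, str, str, str]] = [
    ("psych_hospitalization_acute", "psychiatric", "hospitalization", "acute"),
    ("psych_hospitalization_elective", "psychiatric", "hospitalization", "elective"),
    ("psych_ed", "psychiatric", "ed", "na"),
    ("psych_outpatient", "psychiatric", "outpatient", "na"),
    ("psych_home_visit", "psychiatric", "home_visit", "na"),
    ("private_psychiatrist", "primary", "private_psychiatrist", "na"),
    ("private_psychologist", "primary", "private_psychologist", "na"),
    ("somatic_hospitalization_acute", "somatic", "hospitalization", "acute"),
    ("somatic_hospitalization_elective", "somatic", "hospitalization", "elective"),
    ("somatic_ed", "somatic", "ed", "na"),
    ("somatic_outpatient", "somatic", "outpatient", "na"),
    ("gp", "primary", "gp", "na"),
    ("other_specialist", "primary", "other_specialist", "na"),
]

# Real ATC level-5 antidepressant codes; only the class prefix matters to the
# TRD classifier (SSRI N06AB, SNRI N06AX, TCA N06AA, MAOI N06AF/N06AG).
SUBSTANCE_POOL = [
    "N06AB03", "N06AB04", "N06AB05", "N06AB06", "N06AB10",   # SSRI
    "N06AX11", "N06AX16", "N06AX21",                          # SNRI
    "N06AA04", "N06AA09", "N06AA10",                          # TCA
    "N06AF03", "N06AG02",                                     # MAOI
]

# injected post-index exclusion diagnoses (bipolar, schizophrenia, persistent
# mood, dementia) and pre-index comorbidity noise (anxiety / substance abuse)
_EXCLUSION_DX = ["F31.0", "F20.9", "F34.1", "F31.8", "G30.9"]
_COMORBIDITY_DX = ["F41.9", "F40.1", "F43.1", "F10.2", "F12.1"]

_SPAN_PRE, _SPAN_POST = 365, 730  # contact-generation span around MDD, days


def _realistic_base_rates() -> dict[str, float]:
    # annual per-person contact rates for non-resistant patients, in the
    # vicinity of published non-TRD MDD utilization means
    return {
        "psych_hospitalization_acute": 0.10,
        "psych_hospitalization_elective": 0.03,
        "psych_ed": 0.10,
        "psych_outpatient": 4.0,
        "psych_home_visit": 0.5,
        "private_psychiatrist": 0.3,
        "private_psychologist": 0.15,
        "somatic_hospitalization_acute": 0.35,
        "somatic_hospitalization_elective": 0.10,
        "somatic_ed": 0.35,
        "somatic_outpatient": 3.0,
        "gp": 7.5,
        "other_specialist": 1.8,
    }


def _realistic_multipliers() -> dict[str, float]:
    return {
        "psych_hospitalization_acute": 2.4,
        "psych_hospitalization_elective": 2.5,
        "psych_ed": 1.9,
        "psych_outpatient": 1.6,
        "psych_home_visit": 2.3,
        "private_psychiatrist": 2.3,
        "private_psychologist": 1.3,
        "somatic_hospitalization_acute": 1.0,
        "somatic_hospitalization_elective": 1.0,
        "somatic_ed": 1.0,
        "somatic_outpatient": 1.0,
        "gp": 1.2,
        "other_specialist": 1.05,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic registry.

    ``switch_hazard`` is the per-redemption probability of initiating a new
    antidepressant substance as a ``(resistant, non_resistant)`` pair;
    ``hru_multiplier`` is the multiplicative effect of latent resistance on
    each category's annual contact rate.  ``any_use_probs`` maps a category to
    ``(p_non_resistant, p_resistant)`` and replaces count generation for that
    category by a Bernoulli any-use draw in the post-index year (calibration
    mode only).  ``hru_dispersion`` is the negative-binomial alpha
    (var = m + alpha·m²); 0 gives Poisson counts.
    """

    n_persons: int = 2000
    seed: int = 0
    sex_split: float = 0.62  # probability of F
    age_distribution: dict[str, float] = field(default_factory=lambda: {
        "18-24": 0.12, "25-44": 0.33, "45-64": 0.28, "65-84": 0.22, "85+": 0.05,
    })
    severity_distribution: dict[str, float] = field(default_factory=lambda: {
        "mild": 0.55, "moderate": 0.32, "severe": 0.13,
    })
    p_resistant: float = 0.158
    switch_hazard: tuple[float, float] = (0.35, 0.06)
    redemption_interval_days: float = 30.0
    n_redemptions: int = 12
    p_ect_severe: float = 0.2
    hru_base_rates: dict[str, float] = field(default_factory=_realistic_base_rates)
    hru_multiplier: dict[str, float] = field(default_factory=_realistic_multipliers)
    hru_dispersion: float = 1.0
    bed_days_mean: float = 7.0
    cost_noise_sigma: float = 0.0
    rx_cost_mean: float = 30.0
    any_use_probs: dict[str, tuple[float, float]] | None = None
    p_death: float = 0.02
    p_emigrate: float = 0.01
    p_exclusion_dx: float = 0.01
    p_comorbidity_dx: float = 0.25
    mode: str = "realistic"  # "realistic" | "calibration"
    shift_offsets: tuple[int, int] = (60, 120)  # calibration shift days after MDD

    def validate(self) -> None:
        probs = [self.sex_split, self.p_resistant, self.p_ect_severe, self.p_death,
                 self.p_emigrate, self.p_exclusion_dx, self.p_comorbidity_dx,
                 *self.switch_hazard]
        if self.any_use_probs:
            for pair in self.any_use_probs.values():
                probs.extend(pair)
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        for dist in (self.age_distribution, self.severity_distribution):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(f"distribution does not sum to 1: {dist}")
        for cat, m in self.hru_multiplier.items():
            if m <= 0:
                raise ConfigError(f"non-positive multiplier for {cat}")
        if self.mode not in ("realistic", "calibration"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.n_persons <= 0:
            raise ConfigError("n_persons must be positive")
        if self.hru_dispersion < 0:
            raise ConfigError("hru_dispersion must be >= 0")

    @classmethod
    def calibration(cls, n_persons: int, seed: int, p_resistant: float = 0.5,
                    **overrides) -> "SimulationConfig":
        """The calibration regime: deterministic two-shift schedules, Poisson
        counts at lean per-category rates, and no competing events."""
        base = dict(
            n_persons=n_persons,
            seed=seed,
            p_resistant=p_resistant,
            mode="calibration",
            hru_base_rates={cat: 0.25 for cat, *_ in GENERATOR_CATEGORIES} | {"gp": 1.0},
            hru_multiplier={cat: 2.0 for cat, *_ in GENERATOR_CATEGORIES},
            hru_dispersion=0.0,
            bed_days_mean=3.0,
            p_ect_severe=0.0,
            p_death=0.0,
            p_emigrate=0.0,
            p_exclusion_dx=0.0,
            p_comorbidity_dx=0.0,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["switch_hazard"] = list(self.switch_hazard)
        d["shift_offsets"] = list(self.shift_offsets)
        if self.any_use_probs is not None:
            d["any_use_probs"] = {k: list(v) for k, v in self.any_use_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d) -> "SimulationConfig":
        d = dict(d)
        for key in ("switch_hazard", "shift_offsets"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("any_use_probs"):
            d["any_use_probs"] = {k: tuple(v) for k, v in d["any_use_probs"].items()}
        return cls(**d)


_AGE_BOUNDS = {"18-24": (18, 24), "25-44": (25, 44), "45-64": (45, 64),
               "65-84": (65, 84), "85+": (85, 94)}


def simulate_registry(sim: SimulationConfig,
                      codes: CodeConfig | None = None
                      ) -> tuple[RegistryBundle, pd.DataFrame]:
    """Generate a registry bundle and its ground truth.

    Returns ``(bundle, ground_truth)`` where ``ground_truth`` has one row per
    person: ``person_id``, the latent ``resistant`` flag and the configured
    per-category multipliers echoed as ``mult_<category>`` columns.
    """
    sim.validate()
    codes = codes or CodeConfig()
    n = sim.n_persons
    ss = np.random.SeedSequence(sim.seed)
    (s_person, s_truth, s_dx, s_rx, s_proc, s_ct, s_vital) = ss.spawn(7)
    rng_person = np.random.default_rng(s_person)
    rng_truth = np.random.default_rng(s_truth)
    rng_dx = np.random.default_rng(s_dx)
    rng_rx = np.random.default_rng(s_rx)
    rng_proc = np.random.default_rng(s_proc)
    rng_ct = np.random.default_rng(s_ct)
    rng_vital = np.random.default_rng(s_vital)

    person_id = np.array([f"P{i:06d}" for i in range(n)], dtype=object)

    # ---------------------------------------------------------------- persons
    sex = np.where(rng_person.random(n) < sim.sex_split, "F", "M")
    age_labels = list(sim.age_distribution)
    age_grp = rng_person.choice(len(age_labels), size=n,
                                p=list(sim.age_distribution.values()))
    lo = np.array([_AGE_BOUNDS[age_labels[g]][0] for g in age_grp])
    hi = np.array([_AGE_BOUNDS[age_labels[g]][1] for g in age_grp])
    age = rng_person.integers(lo, hi + 1)

    span = (codes.study_end - codes.study_start).days
    mdd_offset = rng_person.integers(0, span + 1, size=n)
    mdd_date = codes.study_start + pd.to_timedelta(mdd_offset, unit="D")
    # birth placed so that completed age at MDD equals the drawn age
    birth_back = np.round(age * 365.25).astype(int) + rng_person.integers(3, 300, size=n)
    birth_date = mdd_date - pd.to_timedelta(birth_back, unit="D")

    education = rng_person.choice(["basic", "medium", "high", "unknown"], size=n,
                                  p=[0.38, 0.39, 0.15, 0.08])
    cohabiting = rng_person.choice(["yes", "no", "unknown"], size=n,
                                   p=[0.50, 0.49, 0.01])

    resistant = rng_truth.random(n) < sim.p_resistant

    death_mask = rng_vital.random(n) < sim.p_death
    death_off = rng_vital.integers(150, 900, size=n)
    emig_mask = rng_vital.random(n) < sim.p_emigrate
    emig_off = rng_vital.integers(150, 900, size=n)
    death_date = pd.Series(pd.NaT, index=range(n))
    death_date[death_mask] = (mdd_date[death_mask]
                              + pd.to_timedelta(death_off[death_mask], unit="D"))
    emigration_date = pd.Series(pd.NaT, index=range(n))
    emigration_date[emig_mask & ~death_mask] = (
        mdd_date[emig_mask & ~death_mask]
        + pd.to_timedelta(emig_off[emig_mask & ~death_mask], unit="D"))

    persons = pd.DataFrame({
        "person_id": person_id,
        "sex": sex,
        "birth_date": birth_date,
        "death_date": pd.to_datetime(death_date.values),
        "emigration_date": pd.to_datetime(emigration_date.values),
        "education": education,
        "cohabiting": cohabiting,
    })

    # -------------------------------------------------------------- diagnoses
    sev_labels = list(sim.severity_distribution)
    sev_idx = rng_dx.choice(len(sev_labels), size=n,
                            p=list(sim.severity_distribution.values()))
    severity = np.array(sev_labels, dtype=object)[sev_idx]
    icd = np.empty(n, dtype=object)
    for s in sev_labels:
        mask = severity == s
        pool = codes.severity_map[s]
        icd[mask] = rng_dx.choice(pool, size=int(mask.sum()))
    setting = np.where(rng_dx.random(n) < 0.3, "psych_inpatient", "psych_outpatient")
    dx_frames = [pd.DataFrame({
        "person_id": person_id, "date": mdd_date, "icd_code": icd, "setting": setting,
    })]

    excl_mask = rng_dx.random(n) < sim.p_exclusion_dx
    if excl_mask.any():
        k = int(excl_mask.sum())
        dx_frames.append(pd.DataFrame({
            "person_id": person_id[excl_mask],
            "date": mdd_date[excl_mask] + pd.to_timedelta(
                rng_dx.integers(30, 600, size=k), unit="D"),
            "icd_code": rng_dx.choice(_EXCLUSION_DX, size=k),
            "setting": "psych_outpatient",
        }))
    com_mask = rng_dx.random(n) < sim.p_comorbidity_dx
    if com_mask.any():
        k = int(com_mask.sum())
        dx_frames.append(pd.DataFrame({
            "person_id": person_id[com_mask],
            "date": mdd_date[com_mask] - pd.to_timedelta(
                rng_dx.integers(30, 1500, size=k), unit="D"),
            "icd_code": rng_dx.choice(_COMORBIDITY_DX, size=k),
            "setting": "somatic_outpatient",
        }))
    diagnoses = pd.concat(dx_frames, ignore_index=True)

    # ---------------------------------------------------------- prescriptions
    pool = np.array(SUBSTANCE_POOL, dtype=object)
    if sim.mode == "calibration":
        prescriptions = _calibration_prescriptions(
            sim, rng_rx, person_id, mdd_date, resistant, pool)
    else:
        prescriptions = _realistic_prescriptions(
            sim, rng_rx, person_id, mdd_date, resistant, pool)

    # --------------------------------------------------------------- ECT
    ect_mask = resistant & (severity == "severe") & (rng_proc.random(n) < sim.p_ect_severe)
    if ect_mask.any():
        k = int(ect_mask.sum())
        procedures = pd.DataFrame({
            "person_id": person_id[ect_mask],
            "date": mdd_date[ect_mask] + pd.to_timedelta(
                rng_proc.integers(150, 330, size=k), unit="D"),
            "sks_code": rng_proc.choice(codes.ect_codes, size=k),
        })
    else:
        procedures = pd.DataFrame({
            "person_id": pd.Series(dtype=object),
            "date": pd.Series(dtype="datetime64[ns]"),
            "sks_code": pd.Series(dtype=object),
        })

    # ------------------------------------------------------------- contacts
    post_index = mdd_date + pd.to_timedelta(sim.shift_offsets[1], unit="D")
    ct_frames = []
    for cat, sector, ctype, mode in GENERATOR_CATEGORIES:
        base = sim.hru_base_rates.get(cat, 0.0)
        mult = sim.hru_multiplier.get(cat, 1.0)
        price = codes.contact_price(sector, ctype, mode)
        if sim.any_use_probs and cat in sim.any_use_probs:
            p0, p1 = sim.any_use_probs[cat]
            p = np.where(resistant, p1, p0)
            use = rng_ct.random(n) < p
            k = int(use.sum())
            start = post_index[use] + pd.to_timedelta(
                1 + rng_ct.integers(0, 365, size=k), unit="D")
            dur = np.ones(k, dtype=int) if ctype == "hospitalization" else np.zeros(k, dtype=int)
            pid = person_id[use]
        else:
            m = base * (_SPAN_PRE + _SPAN_POST) / 365.0 * np.where(resistant, mult, 1.0)
            if sim.hru_dispersion > 0 and base > 0:
                lam = rng_ct.gamma(1.0 / sim.hru_dispersion, m * sim.hru_dispersion)
                counts = rng_ct.poisson(lam)
            else:
                counts = rng_ct.poisson(m)
            k = int(counts.sum())
            if k == 0:
                continue
            ridx = np.repeat(np.arange(n), counts)
            start = mdd_date[ridx] + pd.to_timedelta(
                rng_ct.integers(-_SPAN_PRE, _SPAN_POST + 1, size=k), unit="D")
            if ctype == "hospitalization":
                dur = rng_ct.geometric(1.0 / sim.bed_days_mean, size=k)
            else:
                dur = np.zeros(k, dtype=int)
            pid = person_id[ridx]
        if k == 0:
            continue
        if sim.cost_noise_sigma > 0:
            sigma = sim.cost_noise_sigma
            cost = price * np.exp(rng_ct.normal(-sigma**2 / 2, sigma, size=k))
        else:
            cost = np.full(k, price)
        ct_frames.append(pd.DataFrame({
            "person_id": pid,
            "start_date": start,
            "end_date": start + pd.to_timedelta(dur, unit="D"),
            "sector": sector,
            "contact_type": ctype,
            "admission_mode": mode,
            "cost_eur": cost,
        }))
    if ct_frames:
        contacts = pd.concat(ct_frames, ignore_index=True)
    else:
        contacts = pd.DataFrame({
            "person_id": pd.Series(dtype=object),
            "start_date": pd.Series(dtype="datetime64[ns]"),
            "end_date": pd.Series(dtype="datetime64[ns]"),
            "sector": pd.Series(dtype=object),
            "contact_type": pd.Series(dtype=object),
            "admission_mode": pd.Series(dtype=object),
            "cost_eur": pd.Series(dtype=float),
        })

    diagnoses = diagnoses.sort_values(
        ["person_id", "date", "icd_code"], kind="stable").reset_index(drop=True)
    prescriptions = prescriptions.sort_values(
        ["person_id", "redemption_date", "atc_code"], kind="stable").reset_index(drop=True)
    procedures = procedures.sort_values(
        ["person_id", "date", "sks_code"], kind="stable").reset_index(drop=True)
    contacts = contacts.sort_values(
        ["person_id", "start_date", "sector", "contact_type"], kind="stable"
    ).reset_index(drop=True)

    truth = pd.DataFrame({"person_id": person_id, "resistant": resistant})
    for cat, *_ in GENERATOR_CATEGORIES:
        truth[f"mult_{cat}"] = sim.hru_multiplier.get(cat, 1.0)

    bundle = RegistryBundle(
        persons=persons, diagnoses=diagnoses, prescriptions=prescriptions,
        procedures=procedures, contacts=contacts, config=codes)
    return bundle, truth


def _calibration_prescriptions(sim, rng, person_id, mdd_date, resistant, pool):
    off1, off2 = sim.shift_offsets
    res_idx = np.flatnonzero(resistant)
    non_idx = np.flatnonzero(~resistant)
    frames = []
    if len(res_idx):
        # three distinct substances at days 0 / off1 / off2 -> exactly 2 shifts
        order = np.argsort(rng.random((len(res_idx), len(pool))), axis=1)[:, :3]
        subs = pool[order]  # (k, 3)
        frames.append(pd.DataFrame({
            "person_id": np.repeat(person_id[res_idx], 3),
            "redemption_date": np.repeat(mdd_date[res_idx].values, 3)
            + pd.to_timedelta(np.tile([0, off1, off2], len(res_idx)), unit="D"),
            "atc_code": subs.ravel(),
            "cost_eur": sim.rx_cost_mean,
        }))
    if len(non_idx):
        # one substance redeemed twice -> zero shifts
        sub = pool[rng.integers(0, len(pool), size=len(non_idx))]
        frames.append(pd.DataFrame({
            "person_id": np.repeat(person_id[non_idx], 2),
            "redemption_date": np.repeat(mdd_date[non_idx].values, 2)
            + pd.to_timedelta(np.tile([0, 30], len(non_idx)), unit="D"),
            "atc_code": np.repeat(sub, 2),
            "cost_eur": sim.rx_cost_mean,
        }))
    return pd.concat(frames, ignore_index=True)


def _realistic_prescriptions(sim, rng, person_id, mdd_date, resistant, pool):
    n = len(person_id)
    K = sim.n_redemptions
    t0 = rng.integers(-60, 31, size=n)
    gaps = np.maximum(1, np.round(
        rng.exponential(sim.redemption_interval_days, size=(n, K - 1)))).astype(int)
    times = np.concatenate([t0[:, None], t0[:, None] + np.cumsum(gaps, axis=1)], axis=1)
    hazard = np.where(resistant, sim.switch_hazard[0], sim.switch_hazard[1])
    switch = rng.random((n, K)) < hazard[:, None]
    switch[:, 0] = False
    rank = np.minimum(np.cumsum(switch, axis=1), len(pool) - 1)
    perm = np.argsort(rng.random((n, len(pool))), axis=1)
    sub_idx = np.take_along_axis(perm, rank, axis=1)
    cost = rng.lognormal(np.log(sim.rx_cost_mean) - 0.125, 0.5, size=n * K)
    return pd.DataFrame({
        "person_id": np.repeat(person_id, K),
        "redemption_date": np.repeat(mdd_date.values, K)
        + pd.to_timedelta(times.ravel(), unit="D"),
        "atc_code": pool[sub_idx.ravel()],
        "cost_eur": np.round(cost, 2),
    })


def simulate_null(sim: SimulationConfig,
                  codes: CodeConfig | None = None
                  ) -> tuple[RegistryBundle, pd.DataFrame]:
    """Simulate under the no-effect null: all HRU multipliers forced to 1.0
    (and any-use probabilities equalized across arms); latent resistance then
    affects prescriptions only."""
    null_any = None
    if sim.any_use_probs is not None:
        null_any = {k: (v[0], v[0]) for k, v in sim.any_use_probs.items()}
    null_sim = dataclasses.replace(
        sim,
        hru_multiplier={cat: 1.0 for cat, *_ in GENERATOR_CATEGORIES},
        any_use_probs=null_any,
    )
    return simulate_registry(null_sim, codes)


def write_ground_truth(truth: pd.DataFrame, directory: str | Path) -> Path:
    path = Path(directory) / "ground_truth.csv"
    truth.to_csv(path, index=False)
    return path
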