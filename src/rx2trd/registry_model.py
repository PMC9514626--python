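"""Typed data model for person-level health-registry tables.

The analysis operates on five tables that emulate the joint structure of the
Danish national registers used for pharmacoepidemiological depression research:

* ``persons`` — one row per individual (sex, birth/death/emigration dates,
  static education and cohabitation attributes),
* ``diagnoses`` — dated hospital diagnosis contacts carrying ICD-10 (or legacy
  ICD-8) codes and a care setting,
* ``prescriptions`` — redeemed pharmacy prescriptions with 7-character ATC
  level-5 codes and total transaction prices,
* ``procedures`` — dated procedure events with SKS codes (used for ECT),
* ``contacts`` — healthcare contacts with sector, contact type, admission mode,
  start/end dates and a cost.

This module owns the CSV readers/writers, the code-list configuration
(:class:`CodeConfig`) shared by every pipeline stage, and schema/invariant
validation.  Validation is total: a malformed row yields a located error that
names the table and the offending row, never a silent drop.

All dates are serialized ISO 8601 (``YYYY-MM-DD``) and interval arithmetic is
done in whole days.  Costs are carried in EUR internally; an optional
``cost_dkk`` input column is divided by ``dkk_per_eur`` at load time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CodeConfig",
    "RegistryBundle",
    "RegistryValidationError",
    "ClassificationError",
    "ConfigError",
    "load_registry",
    "write_registry",
    "validate_bundle",
    "validate_code_config",
    "normalize_icd",
    "TABLE_NAMES",
]

SEVERITY_RANK = {"mild": 0, "moderate": 1, "severe": 2}

AGE_GROUP_LABELS = ["18-24", "25-44", "45-64", "65-84", "85+"]
YEAR_GROUP_LABELS = ["1996-2000", "2001-2005", "2006-2010", "2011-2015"]

TABLE_NAMES = ("persons", "diagnoses", "prescriptions", "procedures", "contacts")

_DATE_COLUMNS = {
    "persons": ["birth_date", "death_date", "emigration_date"],
    "diagnoses": ["date"],
    "prescriptions": ["redemption_date"],
    "procedures": ["date"],
    "contacts": ["start_date", "end_date"],
}

_REQUIRED_COLUMNS = {
    "persons": [
        "person_id", "sex", "birth_date", "death_date", "emigration_date",
        "education", "cohabiting",
    ],
    "diagnoses": ["person_id", "date", "icd_code", "setting"],
    "prescriptions": ["person_id", "redemption_date", "atc_code", "cost_eur"],
    "procedures": ["person_id", "date", "sks_code"],
    "contacts": [
        "person_id", "start_date", "end_date", "sector", "contact_type",
        "admission_mode", "cost_eur",
    ],
}

SETTINGS = {"psych_inpatient", "psych_outpatient", "somatic_inpatient", "somatic_outpatient"}
SECTORS = {"psychiatric", "somatic", "primary"}
CONTACT_TYPES = {
    "hospitalization", "ed", "outpatient", "home_visit",
    "gp", "private_psychiatrist", "private_psychologist", "other_specialist",
}
PRIMARY_TYPES = {"gp", "private_psychiatrist", "private_psychologist", "other_specialist"}
ADMISSION_MODES = {"acute", "elective", "na"}
EDUCATION_LEVELS = {"basic", "medium", "high", "unknown"}
COHABITING_LEVELS = {"yes", "no", "unknown"}


class RegistryValidationError(ValueError):
    """Raised when a registry table violates its schema or an invariant.

    ``problems`` is a list of human-readable strings, each naming the table and
    (where applicable) the row index or identifying value.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("registry validation failed:\n" + "\n".join(self.problems))


class ClassificationError(KeyError):
    """Raised when an ICD code has no configured severity class."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


def normalize_icd(code: str) -> str:
    """Canonicalize an ICD code for prefix matching.

    Uppercases, strips dots, and strips a single leading ``D`` when it is
    followed by another letter — Danish registers prefix ICD-10 codes with
    ``D`` (``DF32.1``), which collides with the genuine ICD-10 ``D`` chapter
    only when the next character is a digit.
    """
    c = str(code).strip().upper().replace(".", "")
    if len(c) >= 2 and c[0] == "D" and c[1].isalpha():
        c = c[1:]
    return c


def _expand_icd8_pattern(pattern: str) -> list[str]:
    """Expand an ICD-8 list entry into dot-stripped wildcard strings.

    Supports plain codes (``296.19``), single-character ``x`` wildcards
    (``295.x9``) and arithmetic ranges in steps of 0.10 (``298.29-298.99``).
    """
    p = pattern.strip().lower().replace("–", "-")
    if "-" in p:
        lo_s, hi_s = p.split("-")
        lo = int(lo_s.replace(".", ""))
        hi = int(hi_s.replace(".", ""))
        return [str(v) for v in range(lo, hi + 1, 10)]
    return [p.replace(".", "")]


def _wildcard_prefix_match(code: str, pattern: str) -> bool:
    """Prefix match where ``x`` in the pattern matches any single character."""
    if len(code) < len(pattern):
        return False
    return all(pc in ("x", cc) for pc, cc in zip(pattern, code.lower()))


@dataclass
class CodeConfig:
    """Code lists, price table and analysis constants shared by all stages.

    Defaults carry the standard claims-based TRD operationalization: first
    hospital-contact MDD defined on ICD-10 F32.x/F33.x severity-coded lists,
    antidepressant classes by ATC level-5 prefix (SSRI N06AB, SNRI N06AX, TCA
    N06AA, MAOI N06AF/N06AG), ECT by SKS codes BRTB1/BRXA1, a ±365-day
    shift-detection window around the MDD diagnosis, and EUR costs converted
    from DKK at 7.47.
    """

    severity_map: dict[str, list[str]] = field(default_factory=lambda: {
        "mild": ["F32.0", "F32.8", "F32.9", "F33.0", "F33.4", "F33.8", "F33.9"],
        "moderate": ["F32.1", "F33.1"],
        "severe": ["F32.2", "F32.3", "F33.2", "F33.3"],
    })
    mdd_codes: list[str] | None = None  # derived from severity_map when None
    exclusion_codes: dict[str, dict[str, list[str]]] = field(default_factory=lambda: {
        "bipolar": {
            "icd10": ["F30", "F31"],
            "icd8": ["296.19", "296.39", "296.89", "296.99", "298.19"],
        },
        "other_affective": {"icd10": ["F38", "F39"], "icd8": []},
        "persistent_mood": {"icd10": ["F34"], "icd8": []},
        "schizophrenia": {
            "icd10": ["F20", "F21", "F22", "F23", "F24", "F25", "F28", "F29"],
            "icd8": ["295.x9", "297.x9", "298.29-298.99", "299.04", "299.05", "299.09"],
        },
        "dementia": {
            "icd10": ["F00", "F01", "F02", "F03", "G30", "R54.9"],
            "icd8": ["290.x"],
        },
    })
    antidepressant_class_prefixes: dict[str, list[str]] = field(default_factory=lambda: {
        "SSRI": ["N06AB"],
        "SNRI": ["N06AX"],
        "TCA": ["N06AA"],
        "MAOI": ["N06AF", "N06AG"],
    })
    ect_codes: list[str] = field(default_factory=lambda: ["BRTB1", "BRXA1"])
    medicine_cost_groups: dict[str, list[str]] = field(default_factory=lambda: {
        "antidepressant": ["N06A"],
        "other_psychiatric": ["N05A", "N05B"],
    })
    # EUR per contact keyed "sector:contact_type:admission_mode".  Synthetic
    # plausible values; real fixed-price schedules are registry-internal.
    fixed_price_table: dict[str, float] = field(default_factory=lambda: {
        "psychiatric:hospitalization:acute": 5000.0,
        "psychiatric:hospitalization:elective": 4500.0,
        "psychiatric:ed:na": 300.0,
        "psychiatric:outpatient:na": 250.0,
        "psychiatric:home_visit:na": 150.0,
        "somatic:hospitalization:acute": 3500.0,
        "somatic:hospitalization:elective": 3000.0,
        "somatic:ed:na": 250.0,
        "somatic:outpatient:na": 200.0,
        "primary:gp:na": 20.0,
        "primary:private_psychiatrist:na": 100.0,
        "primary:private_psychologist:na": 80.0,
        "primary:other_specialist:na": 60.0,
    })
    dkk_per_eur: float = 7.47
    window_days: int = 365
    activity_window_days: int = 90
    min_days_between_shifts: int = 0
    re_initiation_counts: bool = False
    ect_always_shift: bool = False
    study_years: tuple[int, int] = (1996, 2015)
    age_group_edges: list[int] = field(default_factory=lambda: [18, 25, 45, 65, 85])
    age_group_labels: list[str] = field(default_factory=lambda: list(AGE_GROUP_LABELS))
    year_group_edges: list[int] = field(default_factory=lambda: [1996, 2001, 2006, 2011])
    year_group_labels: list[str] = field(default_factory=lambda: list(YEAR_GROUP_LABELS))
    n_controls: int = 2
    allow_partial_match: bool = True
    cost_mode: str = "recorded"  # "recorded" | "fixed"
    include_index_day_in_post: bool = False
    adjust_part1: bool = False
    cluster_by_set: bool = False

    # ------------------------------------------------------------------ codes
    def __post_init__(self) -> None:
        if self.mdd_codes is None:
            self.mdd_codes = sorted(
                c for codes in self.severity_map.values() for c in codes
            )
        self._severity_by_norm = {
            normalize_icd(c): sev
            for sev, codes in self.severity_map.items()
            for c in codes
        }
        self._mdd_norm = tuple(sorted(normalize_icd(c) for c in self.mdd_codes))
        self._excl_icd10 = tuple(
            normalize_icd(c)
            for group in self.exclusion_codes.values()
            for c in group.get("icd10", [])
        )
        self._excl_icd8 = tuple(
            e
            for group in self.exclusion_codes.values()
            for pat in group.get("icd8", [])
            for e in _expand_icd8_pattern(pat)
        )
        self._class_prefixes = sorted(
            ((p.upper(), cls) for cls, ps in self.antidepressant_class_prefixes.items() for p in ps),
            key=lambda t: -len(t[0]),
        )

    @classmethod
    def default(cls) -> "CodeConfig":
        return cls()

    def is_mdd(self, icd_code: str) -> bool:
        c = normalize_icd(icd_code)
        return any(c.startswith(m) for m in self._mdd_norm)

    def severity_of(self, icd_code: str) -> str:
        """Severity class of an MDD code; raises :class:`ClassificationError`
        for codes outside the configured lists."""
        c = normalize_icd(icd_code)
        # exact first, then longest configured prefix (handles sub-subcodes)
        if c in self._severity_by_norm:
            return self._severity_by_norm[c]
        for norm, sev in sorted(self._severity_by_norm.items(), key=lambda t: -len(t[0])):
            if c.startswith(norm):
                return sev
        raise ClassificationError(f"no severity configured for ICD code {icd_code!r}")

    def is_exclusion(self, icd_code: str) -> bool:
        c = normalize_icd(icd_code)
        if not c:
            return False
        if c[0].isdigit():  # ICD-8 dialect: printed numeric strings
            return any(_wildcard_prefix_match(c, p) for p in self._excl_icd8)
        return any(c.startswith(p) for p in self._excl_icd10)

    def atc_class(self, atc_code: str) -> str:
        """Antidepressant class by longest matching configured prefix, else ``none``."""
        code = str(atc_code).upper()
        for prefix, cls in self._class_prefixes:
            if code.startswith(prefix):
                return cls
        return "none"

    def medicine_group(self, atc_code: str) -> str:
        code = str(atc_code).upper()
        best, best_len = "other", 0
        for grp, prefixes in self.medicine_cost_groups.items():
            for p in prefixes:
                if code.startswith(p.upper()) and len(p) > best_len:
                    best, best_len = grp, len(p)
        return best

    def contact_price(self, sector: str, contact_type: str, admission_mode: str) -> float:
        key = f"{sector}:{contact_type}:{admission_mode}"
        try:
            return self.fixed_price_table[key]
        except KeyError:
            raise ConfigError(f"no fixed price configured for contact {key!r}") from None

    # ----------------------------------------------------------------- strata
    def age_group(self, age_years) -> str | pd.Series:
        edges = list(self.age_group_edges[1:]) + [np.inf]
        idx = np.searchsorted(edges, np.asarray(age_years), side="right")
        labels = np.asarray(self.age_group_labels, dtype=object)
        out = labels[idx]
        if np.isscalar(age_years):
            return str(out)
        return pd.Series(out, index=getattr(age_years, "index", None))

    def year_group(self, year) -> str | pd.Series:
        edges = list(self.year_group_edges[1:]) + [10**6]
        idx = np.searchsorted(edges, np.asarray(year), side="right")
        labels = np.asarray(self.year_group_labels, dtype=object)
        out = labels[idx]
        if np.isscalar(year):
            return str(out)
        return pd.Series(out, index=getattr(year, "index", None))

    @property
    def study_start(self) -> pd.Timestamp:
        return pd.Timestamp(f"{self.study_years[0]}-01-01")

    @property
    def study_end(self) -> pd.Timestamp:
        return pd.Timestamp(f"{self.study_years[1]}-12-31")

    # ------------------------------------------------------------------- yaml
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_years"] = list(self.study_years)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping) -> "CodeConfig":
        d = dict(d)
        if "study_years" in d:
            d["study_years"] = tuple(d["study_years"])
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_code_config(config: CodeConfig) -> list[str]:
    """Check the severity partition and prefix sanity; returns violations.

    * severity lists must be pairwise disjoint,
    * their union must equal the MDD code list (every MDD code classifiable),
    * antidepressant class prefixes must be pairwise non-nested.
    """
    problems: list[str] = []
    norm_lists = {
        sev: {normalize_icd(c) for c in codes}
        for sev, codes in config.severity_map.items()
    }
    sevs = sorted(norm_lists)
    for i, a in enumerate(sevs):
        for b in sevs[i + 1:]:
            overlap = norm_lists[a] & norm_lists[b]
            for code in sorted(overlap):
                problems.append(f"code {code} listed in both {a!r} and {b!r} severity")
    union = set().union(*norm_lists.values()) if norm_lists else set()
    mdd = {normalize_icd(c) for c in config.mdd_codes}
    for code in sorted(mdd - union):
        problems.append(f"MDD code {code} missing from all severity lists")
    for code in sorted(union - mdd):
        problems.append(f"severity code {code} not in MDD code list")
    prefixes = [p for ps in config.antidepressant_class_prefixes.values() for p in ps]
    for i, a in enumerate(prefixes):
        for b in prefixes[i + 1:]:
            if a.startswith(b) or b.startswith(a):
                problems.append(f"nested antidepressant class prefixes {a!r}/{b!r}")
    return problems


@dataclass
class RegistryBundle:
    """The five registry tables plus the code configuration."""

    persons: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    procedures: pd.DataFrame
    contacts: pd.DataFrame
    config: CodeConfig = field(default_factory=CodeConfig)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def row_counts(self) -> dict[str, int]:
        return {name: len(self.table(name)) for name in TABLE_NAMES}

    def equals(self, other: "RegistryBundle") -> bool:
        return all(
            self.table(n).reset_index(drop=True).equals(other.table(n).reset_index(drop=True))
            for n in TABLE_NAMES
        )


def _parse_dates(df: pd.DataFrame, table: str, problems: list[str]) -> pd.DataFrame:
    for col in _DATE_COLUMNS[table]:
        if col not in df.columns:
            continue
        raw = df[col].astype("string")
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = raw.notna() & (raw.str.len() > 0) & parsed.isna()
        for i in df.index[bad]:
            problems.append(f"{table}: row {i}: unparseable date {raw[i]!r} in column {col!r}")
        df[col] = parsed
    return df


def load_registry(paths: str | Path | Mapping[str, str | Path],
                  config: CodeConfig | None = None) -> RegistryBundle:
    """Read the five CSV tables, validate them, and return a bundle.

    ``paths`` is either a directory containing ``persons.csv`` ...
    ``contacts.csv`` or a mapping table-name -> file path.  An optional
    ``cost_dkk`` column in prescriptions/contacts is converted to EUR at
    ``config.dkk_per_eur`` when ``cost_eur`` is absent.
    """
    config = config or CodeConfig()
    if not isinstance(paths, Mapping):
        base = Path(paths)
        paths = {name: base / f"{name}.csv" for name in TABLE_NAMES}
    problems: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    for name in TABLE_NAMES:
        path = Path(paths[name])
        if not path.exists():
            raise FileNotFoundError(f"missing registry table file: {path}")
        df = pd.read_csv(path, dtype={"person_id": str})
        if "cost_dkk" in df.columns and "cost_eur" not in df.columns:
            df["cost_eur"] = pd.to_numeric(df["cost_dkk"]) / config.dkk_per_eur
            df = df.drop(columns=["cost_dkk"])
        missing = [c for c in _REQUIRED_COLUMNS[name] if c not in df.columns]
        if missing:
            problems.append(f"{name}: missing column(s) {missing}")
            tables[name] = df
            continue
        df = _parse_dates(df, name, problems)
        tables[name] = df
    if problems:
        raise RegistryValidationError(problems)
    bundle = RegistryBundle(config=config, **tables)
    validate_bundle(bundle)
    return bundle


def validate_bundle(bundle: RegistryBundle) -> None:
    """Validate all schema and domain invariants; raise with located errors."""
    problems: list[str] = []
    cfg = bundle.config

    persons = bundle.persons
    dup = persons["person_id"][persons["person_id"].duplicated()]
    for pid in dup.unique():
        problems.append(f"persons: duplicate person_id {pid!r}")
    for col, allowed in (("sex", {"F", "M"}), ("education", EDUCATION_LEVELS),
                         ("cohabiting", COHABITING_LEVELS)):
        bad = ~persons[col].isin(allowed)
        for i in persons.index[bad]:
            problems.append(f"persons: row {i}: invalid {col} {persons.at[i, col]!r}")
    for col in ("death_date", "emigration_date"):
        bad = persons[col].notna() & (persons[col] < persons["birth_date"])
        for i in persons.index[bad]:
            problems.append(
                f"persons: row {i}: {col} before birth_date for person "
                f"{persons.at[i, 'person_id']!r}"
            )

    known = set(persons["person_id"])
    lo = pd.Timestamp("1969-01-01")
    hi = cfg.study_end + pd.Timedelta(days=2 * cfg.window_days)

    dx = bundle.diagnoses
    if len(dx):
        bad = ~dx["setting"].isin(SETTINGS)
        for i in dx.index[bad]:
            problems.append(f"diagnoses: row {i}: invalid setting {dx.at[i, 'setting']!r}")
        bad = (dx["date"] < lo) | (dx["date"] > hi)
        for i in dx.index[bad]:
            problems.append(f"diagnoses: row {i}: date {dx.at[i, 'date'].date()} outside study horizon")
        for i in dx.index[~dx["person_id"].isin(known)]:
            problems.append(f"diagnoses: row {i}: unknown person_id {dx.at[i, 'person_id']!r}")

    rx = bundle.prescriptions
    if len(rx):
        bad = rx["atc_code"].astype(str).str.len() != 7
        for i in rx.index[bad]:
            problems.append(f"prescriptions: row {i}: ATC code {rx.at[i, 'atc_code']!r} not 7 characters")
        bad = pd.to_numeric(rx["cost_eur"]) < 0
        for i in rx.index[bad]:
            problems.append(f"prescriptions: row {i}: negative cost_eur")
        for i in rx.index[~rx["person_id"].isin(known)]:
            problems.append(f"prescriptions: row {i}: unknown person_id {rx.at[i, 'person_id']!r}")

    ct = bundle.contacts
    if len(ct):
        bad = ct["end_date"] < ct["start_date"]
        for i in ct.index[bad]:
            problems.append(f"contacts: row {i}: end_date before start_date")
        bad = ~ct["sector"].isin(SECTORS)
        for i in ct.index[bad]:
            problems.append(f"contacts: row {i}: invalid sector {ct.at[i, 'sector']!r}")
        bad = ~ct["contact_type"].isin(CONTACT_TYPES)
        for i in ct.index[bad]:
            problems.append(f"contacts: row {i}: invalid contact_type {ct.at[i, 'contact_type']!r}")
        bad = ~ct["admission_mode"].isin(ADMISSION_MODES)
        for i in ct.index[bad]:
            problems.append(f"contacts: row {i}: invalid admission_mode {ct.at[i, 'admission_mode']!r}")
        is_hosp = ct["contact_type"] == "hospitalization"
        bad = is_hosp ^ (ct["admission_mode"] != "na")
        for i in ct.index[bad]:
            problems.append(
                f"contacts: row {i}: admission_mode {ct.at[i, 'admission_mode']!r} "
                f"inconsistent with contact_type {ct.at[i, 'contact_type']!r}"
            )
        is_primary_type = ct["contact_type"].isin(PRIMARY_TYPES)
        bad = is_primary_type ^ (ct["sector"] == "primary")
        for i in ct.index[bad]:
            problems.append(
                f"contacts: row {i}: sector {ct.at[i, 'sector']!r} inconsistent "
                f"with contact_type {ct.at[i, 'contact_type']!r}"
            )
        bad = (ct["contact_type"] == "home_visit") & (ct["sector"] != "psychiatric")
        for i in ct.index[bad]:
            problems.append(f"contacts: row {i}: home_visit outside psychiatric sector")
        bad = pd.to_numeric(ct["cost_eur"]) < 0
        for i in ct.index[bad]:
            problems.append(f"contacts: row {i}: negative cost_eur")
        for i in ct.index[~ct["person_id"].isin(known)]:
            problems.append(f"contacts: row {i}: unknown person_id {ct.at[i, 'person_id']!r}")

    pr = bundle.procedures
    if len(pr):
        for i in pr.index[~pr["person_id"].isin(known)]:
            problems.append(f"procedures: row {i}: unknown person_id {pr.at[i, 'person_id']!r}")

    if problems:
        raise RegistryValidationError(problems)


def write_registry(bundle: RegistryBundle, directory: str | Path) -> dict[str, Path]:
    """Write all tables as UTF-8 comma-separated CSV with ISO-8601 dates.

    Round-trips losslessly through :func:`load_registry`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for name in TABLE_NAMES:
        df = bundle.table(name).copy()
        for col in _DATE_COLUMNS[name]:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        out[name] = path
    return out


def mark_exclusion_diagnoses(diagnoses: pd.DataFrame, config: CodeConfig) -> pd.Series:
    """Boolean mask over diagnosis rows matching any configured exclusion code."""
    if not len(diagnoses):
        return pd.Series(False, index=diagnoses.index)
    codes = diagnoses["icd_code"].astype(str)
    lookup = {c: config.is_exclusion(c) for c in codes.unique()}
    return codes.map(lookup)
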