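"""Two-part model for semicontinuous HRU and cost outcomes.

Utilization outcomes are zero-inflated: a point mass of non-users plus a
right-skewed positive distribution among users.  The two-part model therefore
splits each comparison into

1. **any use** — a modified Poisson regression: log-link regression of the
   binary any-use indicator on the TRD group (with optional matching
   covariates), with a heteroscedasticity-robust (HC0) sandwich variance, so
   that exp(β) is the relative risk directly; results are reported as
   (RR − 1) × 100, the percent change in risk of any utilization;
2. **amount among users** — a linear model of the natural-log outcome on group
   plus the matching covariates (age group, sex, diagnosis-year group,
   severity) restricted to users, back-transformed to the percent change
   (GMR − 1) × 100, where GMR is the geometric-mean ratio.

With a group-only design, part 1 equals the crude risk ratio and part 2 equals
the geometric-mean ratio exactly.  Stratified crude relative risks (by severity
or diagnosis-year group) and a baseline characteristics table with Pearson Chi²
tests complete the reporting surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .hru_outcomes import ALL_OUTCOMES, COST_OUTCOMES, COUNT_OUTCOMES
from .registry_model import CodeConfig

__all__ = [
    "EffectEstimate",
    "any_use_rr",
    "amount_among_users",
    "run_outcome_grid",
    "stratified_risk",
    "baseline_table",
    "percent",
]

log = logging.getLogger(__name__)

MATCHING_COVARIATES = ["age_group", "sex", "year_group", "severity"]
_Z = stats.norm.ppf(0.975)


@dataclass
class EffectEstimate:
    """One two-part result: percent change with Wald 95% CI.

    ``pct_change`` is (RR − 1) × 100 for the any-use part and (GMR − 1) × 100
    for the amount part.  ``note`` is non-empty for degenerate inputs (e.g.
    zero users in an arm), in which case the numeric fields are NaN.
    """

    outcome: str
    part: str  # "any_use" | "amount"
    pct_change: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int
    n_controls: int
    n_users: int
    note: str = ""

    @property
    def flagged(self) -> bool:
        return bool(self.note)


def _flagged(outcome, part, n1, n0, n_users, note) -> EffectEstimate:
    return EffectEstimate(outcome, part, np.nan, np.nan, np.nan, np.nan,
                          n1, n0, n_users, note)


def crude_rr_closed_form(x1: int, n1: int, x0: int, n0: int):
    """Crude risk ratio with the closed-form robust SE of log RR:
    sqrt((1−p1)/(n1·p1) + (1−p0)/(n0·p0)).  Used as fallback and test oracle."""
    p1, p0 = x1 / n1, x0 / n0
    log_rr = np.log(p1 / p0)
    se = np.sqrt((1 - p1) / (n1 * p1) + (1 - p0) / (n0 * p0))
    z = log_rr / se if se > 0 else np.inf
    p = 2 * stats.norm.sf(abs(z))
    return log_rr, se, p


def _design(df: pd.DataFrame, adjusted: bool) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, "trd": (df["group"] == "TRD").astype(float)},
                     index=df.index)
    if adjusted:
        for cov in MATCHING_COVARIATES:
            if cov in df.columns and df[cov].nunique() > 1:
                dummies = pd.get_dummies(df[cov], prefix=cov, drop_first=True,
                                         dtype=float)
                X = pd.concat([X, dummies], axis=1)
    return X


def _post(summaries: pd.DataFrame) -> pd.DataFrame:
    return summaries[summaries["window"] == "post"] if "window" in summaries.columns \
        else summaries


def any_use_rr(summaries: pd.DataFrame, outcome: str,
               adjusted: bool | None = None,
               config: CodeConfig | None = None) -> EffectEstimate:
    """Part 1: percent change in risk of any use, (RR − 1) × 100.

    Fits a log-link Poisson regression of the any-use indicator on the group
    (plus the matching covariates when ``adjusted``) with HC0 sandwich variance
    (cluster-robust on matched set when ``config.cluster_by_set``).  If the fit
    fails to converge, the unadjusted path falls back to the crude RR with its
    closed-form robust SE (logged notice).
    """
    config = config or CodeConfig()
    if adjusted is None:
        adjusted = config.adjust_part1
    df = _post(summaries)
    y = (df[outcome] > 0).astype(float)
    is_case = df["group"] == "TRD"
    n1, n0 = int(is_case.sum()), int((~is_case).sum())
    x1, x0 = int(y[is_case].sum()), int(y[~is_case].sum())
    n_users = x1 + x0
    if n1 == 0 or n0 == 0:
        return _flagged(outcome, "any_use", n1, n0, n_users, "empty arm")
    if x1 == 0 or x0 == 0:
        return _flagged(outcome, "any_use", n1, n0, n_users,
                        "zero users in one arm: relative risk undefined")

    X = _design(df, adjusted)
    cov_kwargs: dict = {"cov_type": "HC0"}
    if config.cluster_by_set and "set_id" in df.columns:
        cov_kwargs = {"cov_type": "cluster",
                      "cov_kwds": {"groups": df["set_id"]}}
    try:
        model = sm.GLM(y, X, family=sm.families.Poisson())
        res = model.fit(maxiter=200, tol=1e-12, **cov_kwargs)
        if not res.converged:
            raise RuntimeError("IRLS did not converge")
        b, se = res.params["trd"], res.bse["trd"]
        p = res.pvalues["trd"]
    except Exception as exc:  # rank-deficiency / separation on degenerate inputs
        if adjusted:
            return _flagged(outcome, "any_use", n1, n0, n_users,
                            f"model failed: {exc}")
        log.info("any_use_rr(%s): GLM failed (%s); using crude RR fallback",
                 outcome, exc)
        b, se, p = crude_rr_closed_form(x1, n1, x0, n0)
    return EffectEstimate(
        outcome, "any_use",
        pct_change=(np.exp(b) - 1) * 100,
        ci_low=(np.exp(b - _Z * se) - 1) * 100,
        ci_high=(np.exp(b + _Z * se) - 1) * 100,
        p_value=float(p), n_cases=n1, n_controls=n0, n_users=n_users)


def amount_among_users(summaries: pd.DataFrame, outcome: str,
                       config: CodeConfig | None = None,
                       adjusted: bool = True) -> EffectEstimate:
    """Part 2: percent change in amount among users, (GMR − 1) × 100.

    OLS of the natural-log outcome on group plus the matching covariates
    (categorical), restricted to patients with a positive outcome; normal-theory
    Wald CI back-transformed from the log scale.
    """
    config = config or CodeConfig()
    df = _post(summaries)
    users = df[df[outcome] > 0]
    is_case = users["group"] == "TRD"
    n1, n0 = int(is_case.sum()), int((~is_case).sum())
    if n1 < 2 or n0 < 2:
        return _flagged(outcome, "amount", n1, n0, n1 + n0,
                        "fewer than 2 users in an arm")
    y = np.log(users[outcome].astype(float))
    X = _design(users, adjusted)
    res = sm.OLS(y, X).fit()
    b, se, p = res.params["trd"], res.bse["trd"], res.pvalues["trd"]
    return EffectEstimate(
        outcome, "amount",
        pct_change=(np.exp(b) - 1) * 100,
        ci_low=(np.exp(b - _Z * se) - 1) * 100,
        ci_high=(np.exp(b + _Z * se) - 1) * 100,
        p_value=float(p), n_cases=n1, n_controls=n0, n_users=n1 + n0)


def _estimate_row(est: EffectEstimate, prefix: str) -> dict:
    return {
        f"{prefix}_pct_change": est.pct_change,
        f"{prefix}_ci_low": est.ci_low,
        f"{prefix}_ci_high": est.ci_high,
        f"{prefix}_p": est.p_value,
        f"{prefix}_note": est.note,
    }


def run_outcome_grid(summaries: pd.DataFrame,
                     config: CodeConfig | None = None) -> pd.DataFrame:
    """Full outcome grid: for every count and cost outcome, the post-index
    descriptive mean (sd) per group plus both two-part estimates (tidy rows)."""
    config = config or CodeConfig()
    post = _post(summaries)
    rows = []
    for outcome in ALL_OUTCOMES:
        row = {"outcome": outcome,
               "kind": "cost" if outcome in COST_OUTCOMES else "count"}
        for group, label in (("TRD", "trd"), ("nonTRD", "nontrd")):
            vals = post.loc[post["group"] == group, outcome]
            row[f"mean_{label}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"sd_{label}"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        row.update(_estimate_row(any_use_rr(post, outcome, config=config), "risk"))
        row.update(_estimate_row(amount_among_users(post, outcome, config=config),
                                 "amount"))
        rows.append(row)
    return pd.DataFrame(rows)


def stratified_risk(summaries: pd.DataFrame, outcome: str, by: str,
                    config: CodeConfig | None = None) -> pd.DataFrame:
    """Per-stratum user fractions by group and the crude relative risk with a
    robust 95% CI (subgroup analogue of the severity / calendar-period plots).

    Strata where either arm is empty or has zero users are omitted (logged).
    """
    config = config or CodeConfig()
    post = _post(summaries)
    rows = []
    for stratum, grp in post.groupby(by):
        y = (grp[outcome] > 0)
        is_case = grp["group"] == "TRD"
        n1, n0 = int(is_case.sum()), int((~is_case).sum())
        x1, x0 = int(y[is_case].sum()), int(y[~is_case].sum())
        if min(n1, n0) == 0 or min(x1, x0) == 0:
            log.info("stratified_risk(%s by %s): stratum %r omitted "
                     "(empty arm or zero users)", outcome, by, stratum)
            continue
        log_rr, se, p = crude_rr_closed_form(x1, n1, x0, n0)
        rows.append({
            by: stratum, "outcome": outcome,
            "n_cases": n1, "n_controls": n0,
            "users_cases": x1, "users_controls": x0,
            "frac_cases": x1 / n1, "frac_controls": x0 / n0,
            "rr": np.exp(log_rr),
            "rr_ci_low": np.exp(log_rr - _Z * se),
            "rr_ci_high": np.exp(log_rr + _Z * se),
            "p_value": p,
        })
    return pd.DataFrame(rows)


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Table percentage: count / column total × 100, rounded to one decimal."""
    return float(np.round(numerator / denominator * 100, decimals))


def baseline_table(matched_entries: pd.DataFrame,
                   pre_match_entries: pd.DataFrame | None = None,
                   variables: list[str] | None = None,
                   group_col: str = "group",
                   config: CodeConfig | None = None) -> pd.DataFrame:
    """Baseline characteristics with counts (percent) per group and a Pearson
    Chi² p-value per variable for the matched comparison.

    ``matched_entries`` has one row per matched person with ``group`` and the
    descriptive variables; ``pre_match_entries`` optionally supplies the
    pre-matching population (needs a ``group`` column too).  Expected cell
    counts below 5 set ``small_sample`` on the variable's rows.
    """
    variables = variables or [c for c in
                              ["sex", "age_group", "education", "cohabiting",
                               "year_group", "severity", "anxiety", "substance_abuse"]
                              if c in matched_entries.columns]
    rows = []
    for var in variables:
        tab = pd.crosstab(matched_entries[var], matched_entries[group_col])
        tab = tab.reindex(columns=["TRD", "nonTRD"], fill_value=0)
        if tab.shape[0] >= 2 and (tab.values.sum(axis=0) > 0).all():
            chi2, p, _, expected = stats.chi2_contingency(tab.values, correction=False)
            small = bool((expected < 5).any())
        else:
            chi2, p, small = np.nan, np.nan, False
        totals = tab.sum(axis=0)
        pre_tab = None
        if pre_match_entries is not None and var in pre_match_entries.columns:
            pre_tab = pd.crosstab(pre_match_entries[var], pre_match_entries[group_col])
            pre_tab = pre_tab.reindex(columns=["TRD", "nonTRD"], fill_value=0)
        for level in tab.index:
            row = {"variable": var, "level": level,
                   "matched_trd_n": int(tab.at[level, "TRD"]),
                   "matched_trd_pct": percent(tab.at[level, "TRD"], totals["TRD"])
                   if totals["TRD"] else np.nan,
                   "matched_nontrd_n": int(tab.at[level, "nonTRD"]),
                   "matched_nontrd_pct": percent(tab.at[level, "nonTRD"], totals["nonTRD"])
                   if totals["nonTRD"] else np.nan,
                   "chi2": chi2, "p_value": p, "small_sample": small}
            if pre_tab is not None and level in pre_tab.index:
                pre_totals = pre_tab.sum(axis=0)
                row["pre_trd_n"] = int(pre_tab.at[level, "TRD"])
                row["pre_trd_pct"] = percent(pre_tab.at[level, "TRD"], pre_totals["TRD"]) \
                    if pre_totals["TRD"] else np.nan
                row["pre_nontrd_n"] = int(pre_tab.at[level, "nonTRD"])
                row["pre_nontrd_pct"] = percent(pre_tab.at[level, "nonTRD"],
                                                pre_totals["nonTRD"]) \
                    if pre_totals["nonTRD"] else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
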