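import numpy as np
import pandas as pd
import pytest

from rx2trd import (
    amount_among_users,
    any_use_rr,
    baseline_table,
    run_outcome_grid,
    stratified_risk,
)
from rx2trd.twopart_analysis import crude_rr_closed_form, percent


def binary_summaries(x1, n1, x0, n0, outcome="gp"):
    """Post-window any-use data: x users of n per arm."""
    rows = []
    for group, x, n in (("TRD", x1, n1), ("nonTRD", x0, n0)):
        rows += [{"group": group, "window": "post", outcome: 1.0}] * x
        rows += [{"group": group, "window": "post", outcome: 0.0}] * (n - x)
    return pd.DataFrame(rows)


def amount_summaries(trd_values, nontrd_values, outcome="gp"):
    rows = [{"group": "TRD", "window": "post", outcome: v} for v in trd_values]
    rows += [{"group": "nonTRD", "window": "post", outcome: v} for v in nontrd_values]
    return pd.DataFrame(rows)


class TestAnyUseRR:
    def test_thirty_vs_fifteen_percent_users_doubles_risk(self, codes):
        est = any_use_rr(binary_summaries(30, 100, 15, 100), "gp", config=codes)
        assert est.pct_change == pytest.approx(100.0, abs=1e-8)
        assert est.n_users == 45

    def test_equal_arms_give_zero_change(self, codes):
        est = any_use_rr(binary_summaries(20, 100, 20, 100), "gp", config=codes)
        assert est.pct_change == pytest.approx(0.0, abs=1e-8)

    def test_group_only_model_equals_crude_risk_ratio(self, codes):
        # saturated log-link fit must reproduce the crude RR to high precision
        for x1, n1, x0, n0 in [(30, 100, 15, 100), (7, 40, 22, 80), (55, 60, 12, 90)]:
            est = any_use_rr(binary_summaries(x1, n1, x0, n0), "gp", config=codes)
            crude = (x1 / n1) / (x0 / n0)
            assert est.pct_change == pytest.approx((crude - 1) * 100, rel=1e-10)

    def test_sandwich_se_matches_closed_form(self, codes):
        x1, n1, x0, n0 = 30, 100, 15, 100
        est = any_use_rr(binary_summaries(x1, n1, x0, n0), "gp", config=codes)
        log_rr, se, _ = crude_rr_closed_form(x1, n1, x0, n0)
        ci_low = (np.exp(log_rr - 1.959963984540054 * se) - 1) * 100
        ci_high = (np.exp(log_rr + 1.959963984540054 * se) - 1) * 100
        assert est.ci_low == pytest.approx(ci_low, rel=1e-6)
        assert est.ci_high == pytest.approx(ci_high, rel=1e-6)

    def test_zero_users_in_an_arm_is_flagged_not_crash(self, codes):
        est = any_use_rr(binary_summaries(10, 100, 0, 100), "gp", config=codes)
        assert est.flagged and np.isnan(est.pct_change)

    def test_ci_brackets_estimate(self, codes):
        est = any_use_rr(binary_summaries(40, 90, 25, 110), "gp", config=codes)
        assert est.ci_low <= est.pct_change <= est.ci_high
        assert est.pct_change > -100


class TestAmountAmongUsers:
    def test_geometric_mean_ratio_exact(self, codes):
        # geometric means 4 and 2 -> +100%
        est = amount_among_users(amount_summaries([2, 8], [1, 4]), "gp", codes)
        assert est.pct_change == pytest.approx(100.0, abs=1e-9)

    def test_identical_vectors_give_zero_change(self, codes):
        est = amount_among_users(amount_summaries([3, 5, 9], [3, 5, 9]), "gp", codes)
        assert est.pct_change == pytest.approx(0.0, abs=1e-9)

    def test_zeros_are_excluded_as_non_users(self, codes):
        est = amount_among_users(
            amount_summaries([0, 0, 2, 8], [1, 4, 0]), "gp", codes)
        assert est.pct_change == pytest.approx(100.0, abs=1e-9)
        assert est.n_users == 4

    def test_single_user_arm_flagged(self, codes):
        est = amount_among_users(amount_summaries([5], [1, 2, 3]), "gp", codes)
        assert est.flagged

    def test_recovers_lognormal_ratio_within_3se(self, codes):
        rng = np.random.default_rng(2024)
        n = 5000
        trd = np.exp(rng.normal(np.log(1.5), 1.0, n))
        non = np.exp(rng.normal(0.0, 1.0, n))
        est = amount_among_users(amount_summaries(trd, non), "gp", codes)
        se_log = np.sqrt(2 / n)
        lo = (np.exp(np.log(1.5) - 3 * se_log) - 1) * 100
        hi = (np.exp(np.log(1.5) + 3 * se_log) - 1) * 100
        assert lo < est.pct_change < hi

    def test_covariate_adjustment_uses_matching_variables(self, codes):
        # confounded design: severity shifts the outcome and differs by group;
        # adjustment must remove the confounding that the crude GMR shows
        rng = np.random.default_rng(7)
        n = 4000
        severe = rng.random(n) < 0.5
        group = np.where(rng.random(n) < np.where(severe, 0.8, 0.2), "TRD", "nonTRD")
        y = np.exp(rng.normal(0, 0.3, n) + np.where(severe, 1.0, 0.0))
        df = pd.DataFrame({"group": group, "window": "post", "gp": y,
                           "severity": np.where(severe, "severe", "mild")})
        adjusted = amount_among_users(df, "gp", codes)
        crude = amount_among_users(df.drop(columns="severity"), "gp", codes)
        assert abs(adjusted.pct_change) < 10
        assert crude.pct_change > 30


class TestStratifiedRisk:
    def test_crude_rr_per_stratum(self, codes):
        df = pd.concat([
            binary_summaries(10, 50, 5, 50).assign(severity="mild"),
            binary_summaries(30, 50, 25, 50).assign(severity="severe"),
        ])
        out = stratified_risk(df, "gp", by="severity", config=codes)
        out = out.set_index("severity")
        assert out.at["mild", "rr"] == pytest.approx(2.0)
        assert out.at["severe", "rr"] == pytest.approx(1.2)

    def test_pooled_fractions_are_weighted_average_of_strata(self, codes):
        df = pd.concat([
            binary_summaries(10, 50, 5, 50).assign(severity="mild"),
            binary_summaries(30, 50, 25, 50).assign(severity="severe"),
        ])
        out = stratified_risk(df, "gp", by="severity", config=codes)
        pooled_cases = (out["frac_cases"] * out["n_cases"]).sum() / out["n_cases"].sum()
        assert pooled_cases == pytest.approx(40 / 100)

    def test_empty_stratum_omitted(self, codes):
        df = binary_summaries(10, 50, 0, 50).assign(severity="mild")
        out = stratified_risk(df, "gp", by="severity", config=codes)
        assert len(out) == 0


class TestBaselineTable:
    def test_perfectly_balanced_variable_p_near_one(self, codes):
        df = pd.DataFrame({
            "group": ["TRD"] * 40 + ["nonTRD"] * 80,
            "sex": (["F"] * 20 + ["M"] * 20) + (["F"] * 40 + ["M"] * 40)})
        out = baseline_table(df, config=codes)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)
        assert out["chi2"].iloc[0] == pytest.approx(0.0)

    def test_pearson_chi2_hand_computed(self, codes):
        # contingency [[30,10],[10,30]] -> Chi2 = 20.0 without correction
        df = pd.DataFrame({
            "group": ["TRD"] * 40 + ["nonTRD"] * 40,
            "sex": (["F"] * 30 + ["M"] * 10) + (["F"] * 10 + ["M"] * 30)})
        out = baseline_table(df, config=codes)
        assert out["chi2"].iloc[0] == pytest.approx(20.0)

    def test_percent_cells_rounded_to_one_decimal(self, codes):
        df = pd.DataFrame({
            "group": ["TRD"] * 3 + ["nonTRD"] * 3,
            "sex": ["F", "F", "M", "F", "M", "M"]})
        out = baseline_table(df, config=codes).set_index("level")
        assert out.at["F", "matched_trd_pct"] == 66.7
        assert out.at["M", "matched_nontrd_pct"] == 66.7

    def test_small_expected_cells_flagged(self, codes):
        df = pd.DataFrame({
            "group": ["TRD"] * 4 + ["nonTRD"] * 4,
            "sex": ["F", "F", "F", "M", "F", "F", "M", "M"]})
        out = baseline_table(df, config=codes)
        assert out["small_sample"].all()


class TestOutcomeGrid:
    def test_grid_covers_21_count_and_9_cost_rows(self, codes, calibration_run):
        grid = run_outcome_grid(calibration_run.summaries, codes)
        assert (grid["kind"] == "count").sum() == 21
        assert (grid["kind"] == "cost").sum() == 9

    def test_calibrated_any_use_effect_recovered_in_grid(self, codes, calibration_run):
        grid = run_outcome_grid(calibration_run.summaries, codes).set_index("outcome")
        row = grid.loc["psych_hospitalization_acute"]
        assert row["risk_ci_low"] < 100 < row["risk_ci_high"]

    def test_estimates_invariant_to_row_permutation(self, codes, calibration_run):
        s = calibration_run.summaries
        shuffled = s.sample(frac=1, random_state=9)
        a = any_use_rr(s, "psych_hospitalization_acute", config=codes)
        b = any_use_rr(shuffled, "psych_hospitalization_acute", config=codes)
        assert a.pct_change == pytest.approx(b.pct_change, rel=1e-9)


class TestPercent:
    @pytest.mark.parametrize("num, den, expected", [
        (1, 3, 33.3), (2, 3, 66.7), (1, 8, 12.5), (19407, 30162, 64.3),
    ])
    def test_percent_rounding_contract(self, num, den, expected):
        assert percent(num, den) == expected
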