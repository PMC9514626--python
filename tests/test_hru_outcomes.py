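import numpy as np
import pandas as pd
import pytest

from rx2trd import (
    COST_OUTCOMES,
    COUNT_OUTCOMES,
    cost_hru,
    count_hru,
    summarize_by_group,
    summarize_population,
    window_bounds,
)

from conftest import contact_frame, make_bundle, make_persons, rx_frame

INDEX = pd.Timestamp("2010-06-01")


class TestWindowBounds:
    def test_post_window(self, codes):
        assert window_bounds(INDEX, "post", codes) == \
            (pd.Timestamp("2010-06-02"), pd.Timestamp("2011-06-01"))

    def test_pre_window(self, codes):
        assert window_bounds(INDEX, "pre", codes) == \
            (pd.Timestamp("2009-06-01"), pd.Timestamp("2010-05-31"))

    def test_index_day_in_neither_window(self, codes):
        pre = window_bounds(INDEX, "pre", codes)
        post = window_bounds(INDEX, "post", codes)
        assert pre[1] < INDEX < post[0]

    def test_include_index_day_flag(self, codes):
        import dataclasses
        cfg = dataclasses.replace(codes, include_index_day_in_post=True)
        assert window_bounds(INDEX, "post", cfg)[0] == INDEX


class TestCounts:
    def test_hospitalization_fully_inside_window(self, codes):
        ct = contact_frame([("P1", "2010-07-01", "2010-07-11", "psychiatric",
                             "hospitalization", "acute", 5000.0)])
        counts = count_hru(ct, "P1", INDEX, "post", codes)
        assert counts["psych_hospitalization"] == 1
        assert counts["psych_hospitalization_acute"] == 1
        assert counts["psych_hospitalization_elective"] == 0
        assert counts["psych_bed_days"] == 10
        assert counts["psych_bed_days_acute"] == 10

    def test_stay_straddling_window_end_clipped(self, codes):
        # window ends 2011-06-01; stay runs 3 days past it
        ct = contact_frame([("P1", "2011-05-29", "2011-06-04", "somatic",
                             "hospitalization", "elective", 3000.0)])
        counts = count_hru(ct, "P1", INDEX, "post", codes)
        assert counts["somatic_hospitalization"] == 1
        assert counts["somatic_bed_days"] == 3  # nights 05-29..06-01

    def test_stay_straddling_window_start_counts_nights_not_admission(self, codes):
        ct = contact_frame([("P1", "2010-05-28", "2010-06-10", "psychiatric",
                             "hospitalization", "acute", 5000.0)])
        counts = count_hru(ct, "P1", INDEX, "post", codes)
        assert counts["psych_hospitalization"] == 0  # started before window
        assert counts["psych_bed_days"] == 8         # nights 06-02..06-10

    def test_same_day_inpatient_stay_counts_one_bed_day(self, codes):
        ct = contact_frame([("P1", "2010-08-01", "2010-08-01", "psychiatric",
                             "hospitalization", "acute", 5000.0)])
        counts = count_hru(ct, "P1", INDEX, "post", codes)
        assert counts["psych_bed_days"] == 1

    def test_event_on_index_day_in_neither_window(self, codes):
        ct = contact_frame([("P1", INDEX, INDEX, "primary", "gp", "na", 20.0)])
        for which in ("pre", "post"):
            assert count_hru(ct, "P1", INDEX, which, codes)["gp"] == 0

    def test_visit_types_mapped_to_outcomes(self, codes):
        ct = contact_frame([
            ("P1", "2010-07-01", "2010-07-01", "psychiatric", "ed", "na", 300.0),
            ("P1", "2010-07-02", "2010-07-02", "psychiatric", "home_visit", "na", 150.0),
            ("P1", "2010-07-03", "2010-07-03", "primary", "private_psychologist", "na", 80.0),
            ("P1", "2010-07-04", "2010-07-04", "somatic", "outpatient", "na", 200.0),
            ("P1", "2010-07-05", "2010-07-05", "primary", "other_specialist", "na", 60.0),
        ])
        counts = count_hru(ct, "P1", INDEX, "post", codes)
        for outcome in ("psych_ed", "psych_home_visit", "private_psychologist",
                        "somatic_outpatient", "other_specialist"):
            assert counts[outcome] == 1


class TestCosts:
    def test_medicine_costs_split_by_atc_group(self, codes):
        rx = rx_frame([
            ("P1", "2010-07-01", "N06AB06", 30.0),   # antidepressant
            ("P1", "2010-07-02", "N05BA01", 10.0),   # other psychiatric
            ("P1", "2010-07-03", "A10BA02", 7.0),    # other medicine
        ])
        ct = contact_frame([])
        costs = cost_hru(ct, rx, "P1", INDEX, "post", codes)
        assert costs["cost_medicine_antidepressant"] == 30.0
        assert costs["cost_medicine_other_psychiatric"] == 10.0
        assert costs["cost_medicine_other"] == 7.0
        assert costs["cost_total_incl_medicine"] == 47.0
        assert costs["cost_total_excl_medicine"] == 0.0

    def test_psychiatric_cost_includes_private_and_home_services(self, codes):
        ct = contact_frame([
            ("P1", "2010-07-01", "2010-07-05", "psychiatric", "hospitalization", "acute", 5000.0),
            ("P1", "2010-07-10", "2010-07-10", "primary", "private_psychiatrist", "na", 100.0),
            ("P1", "2010-07-11", "2010-07-11", "primary", "private_psychologist", "na", 80.0),
            ("P1", "2010-07-12", "2010-07-12", "psychiatric", "home_visit", "na", 150.0),
            ("P1", "2010-07-13", "2010-07-13", "primary", "gp", "na", 20.0),
        ])
        rx = rx_frame([])
        costs = cost_hru(ct, rx, "P1", INDEX, "post", codes)
        assert costs["cost_psychiatric"] == 5330.0
        assert costs["cost_gp"] == 20.0
        assert costs["cost_total_excl_medicine"] == 5350.0

    def test_fixed_price_mode_uses_price_table(self, codes):
        import dataclasses
        cfg = dataclasses.replace(codes, cost_mode="fixed")
        ct = contact_frame([("P1", "2010-07-01", "2010-07-01", "primary",
                             "gp", "na", 999.0)])  # recorded cost ignored
        costs = cost_hru(ct, rx_frame([]), "P1", INDEX, "post", cfg)
        assert costs["cost_gp"] == codes.fixed_price_table["primary:gp:na"]

    def test_no_events_all_zero(self, codes):
        costs = cost_hru(contact_frame([]), rx_frame([]), "P1", INDEX, "post", codes)
        assert all(v == 0.0 for v in costs.values())


class TestPopulationSummaries:
    def test_additivity_invariants_hold_per_person(self, realistic_run):
        s = realistic_run.summaries
        for side in ("psych", "somatic"):
            for what in ("hospitalization", "bed_days"):
                total = s[f"{side}_{what}"]
                parts = s[f"{side}_{what}_acute"] + s[f"{side}_{what}_elective"]
                assert np.allclose(total, parts)
        excl = (s["cost_psychiatric"] + s["cost_somatic"] + s["cost_gp"]
                + s["cost_other_specialist"])
        assert np.allclose(s["cost_total_excl_medicine"], excl)
        incl = (excl + s["cost_medicine_other"] + s["cost_medicine_other_psychiatric"]
                + s["cost_medicine_antidepressant"])
        assert np.allclose(s["cost_total_incl_medicine"], incl)
        assert (s[COUNT_OUTCOMES + COST_OUTCOMES] >= 0).all().all()

    def test_one_row_per_person_and_window(self, realistic_run):
        s = realistic_run.summaries
        assert not s.duplicated(["person_id", "window"]).any()
        assert set(s["window"]) == {"pre", "post"}

    def test_pre_and_post_windows_never_double_count(self, codes):
        # one visit per day across 2 years around the index
        days = pd.date_range(INDEX - pd.Timedelta(days=365),
                             INDEX + pd.Timedelta(days=365), freq="D")
        ct = contact_frame([("P1", d, d, "primary", "gp", "na", 20.0) for d in days])
        pre = count_hru(ct, "P1", INDEX, "pre", codes)["gp"]
        post = count_hru(ct, "P1", INDEX, "post", codes)["gp"]
        assert pre + post == len(days) - 1  # only the index-day visit uncounted

    def test_cost_totals_invariant_under_event_permutation(self, codes):
        rng = np.random.default_rng(4)
        ct = contact_frame([
            ("P1", "2010-07-01", "2010-07-01", "primary", "gp", "na", 20.0),
            ("P1", "2010-08-01", "2010-08-04", "somatic", "hospitalization", "acute", 3500.0),
            ("P1", "2010-09-01", "2010-09-01", "psychiatric", "ed", "na", 300.0),
        ])
        shuffled = ct.iloc[rng.permutation(len(ct))].reset_index(drop=True)
        a = cost_hru(ct, rx_frame([]), "P1", INDEX, "post", codes)
        b = cost_hru(shuffled, rx_frame([]), "P1", INDEX, "post", codes)
        assert a == b

    def test_group_means_match_generator_targets(self, calibration_run):
        # calibration: Poisson annual rate 0.25 (controls) / 0.5 (resistant)
        # for somatic outpatient visits; post-window mean within 3 SE
        s = calibration_run.summaries
        post = s[s.window == "post"]
        table = summarize_by_group(post, ["somatic_outpatient"])
        for group, mu in (("TRD", 0.5), ("nonTRD", 0.25)):
            cell = table[(table.group == group)
                         & (table.outcome == "somatic_outpatient")].iloc[0]
            se = cell["sd"] / np.sqrt(cell["n"])
            assert abs(cell["mean"] - mu) < 3 * se

    def test_single_patient_sd_reported_as_zero_with_note(self, codes):
        df = pd.DataFrame({"group": ["TRD"], "window": ["post"], "gp": [3.0]})
        out = summarize_by_group(df, ["gp"])
        assert out.loc[0, "sd"] == 0.0
        assert "single patient" in out.loc[0, "note"]
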