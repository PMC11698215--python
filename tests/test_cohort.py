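"""Cohort construction: index episodes, eligibility, outcome, censoring,
exposure panel and covariate balance."""
from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from sgarisk import (
    CohortConfig,
    DGPConfig,
    apply_eligibility,
    ascertain_outcome,
    build_cohort,
    compute_smd,
    determine_censoring,
    generate_claims,
    identify_index_episode,
)
from sgarisk.cohort import DataError
from sgarisk.simulate import PANEL_COLUMNS


def fills_df(rows):
    return pd.DataFrame(rows, columns=["person_id", "day", "drug_class",
                                       "days_supplied"])


def dx_df(rows):
    return pd.DataFrame(rows, columns=["person_id", "day", "setting",
                                       "position", "code_group"])


class TestIndexEpisode:
    def test_single_fill_with_empty_pre_period_indexes_at_that_day(self):
        ep, _ = identify_index_episode(
            fills_df([("p1", 0, "index_aripiprazole", 30)]), window_start=-180)
        assert ep is not None
        assert ep.index_day == 0 and ep.drug == "aripiprazole"
        assert ep.pre_period_days_supplied == 0

    def test_other_antipsychotic_in_pre_period_disqualifies(self):
        ep, reason = identify_index_episode(
            fills_df([("p1", -30, "other_antipsychotic", 30),
                      ("p1", 0, "index_olanzapine", 30)]), window_start=-180)
        assert ep is None and reason == "other_antipsychotic_pre_period"

    def test_supply_over_30_days_in_90_day_window_disqualifies(self):
        # 60 days supplied within a 90-day pre-period window: not a new user
        ep, reason = identify_index_episode(
            fills_df([("p1", -80, "index_aripiprazole", 30),
                      ("p1", -50, "index_aripiprazole", 30),
                      ("p1", 0, "index_aripiprazole", 30)]), window_start=-180)
        assert ep is None and reason == "not_new_user"

    def test_limited_pre_period_supply_is_allowed_and_summed(self):
        # historic other-antipsychotic use disqualifies the early fill, so the
        # day-0 fill indexes with its pre-period supply recorded
        ep, _ = identify_index_episode(
            fills_df([("p1", -290, "other_antipsychotic", 30),
                      ("p1", -150, "index_aripiprazole", 20),
                      ("p1", 0, "index_aripiprazole", 30)]), window_start=-330)
        assert ep is not None and ep.index_day == 0
        assert ep.pre_period_days_supplied == 20

    def test_negative_days_supplied_is_a_data_error(self):
        with pytest.raises(DataError):
            identify_index_episode(
                fills_df([("p1", 0, "index_aripiprazole", -5)]))


class TestEligibility:
    def _episode(self):
        ep, _ = identify_index_episode(
            fills_df([("p1", 0, "index_aripiprazole", 30)]), window_start=-180)
        return ep

    def _demo(self, birth=-40 * 365):
        return pd.Series({"birth_day": birth, "sex": "F",
                          "race_group": "white", "state": 0})

    def test_pre_period_enrolment_gap_excludes(self):
        enrol = pd.DataFrame([("p1", -120, 400)],
                             columns=["person_id", "start_day", "end_day"])
        res = apply_eligibility(self._episode(), dx_df([]), enrol, self._demo())
        assert (not res.eligible) and res.reason == "enrolment_gap"

    def test_pre_period_diabetes_claims_exclude(self):
        enrol = pd.DataFrame([("p1", -180, 400)],
                             columns=["person_id", "start_day", "end_day"])
        dx = dx_df([("p1", -100, "outpatient", "primary", "type2_diabetes"),
                    ("p1", -40, "outpatient", "secondary", "type2_diabetes")])
        res = apply_eligibility(self._episode(), dx, enrol, self._demo())
        assert res.reason == "prior_diabetes_or_cardiometabolic"

    def test_clean_record_is_eligible(self):
        enrol = pd.DataFrame([("p1", -180, 400)],
                             columns=["person_id", "start_day", "end_day"])
        res = apply_eligibility(self._episode(), dx_df([]), enrol, self._demo())
        assert res.eligible and res.reason == "none"

    def test_age_out_of_range_excludes(self):
        enrol = pd.DataFrame([("p1", -180, 400)],
                             columns=["person_id", "start_day", "end_day"])
        res = apply_eligibility(self._episode(), dx_df([]), enrol,
                                self._demo(birth=-17 * 365))
        assert res.reason == "age_out_of_range"

    def test_missing_birth_date_is_a_data_error(self):
        enrol = pd.DataFrame([("p1", -180, 400)],
                             columns=["person_id", "start_day", "end_day"])
        with pytest.raises(DataError):
            apply_eligibility(self._episode(), dx_df([]), enrol,
                              pd.Series({"birth_day": np.nan}))


class TestOutcome:
    def test_inpatient_primary_claim_qualifies(self):
        dx = dx_df([("p1", 185, "inpatient", "primary", "type2_diabetes")])
        res = ascertain_outcome(dx, fills_df([]), index_day=0)
        assert res.event_month == 7 and res.rule == "inpatient_primary"

    def test_outpatient_plus_oral_antidiabetic_qualifies(self):
        dx = dx_df([("p1", 130, "outpatient", "secondary", "type2_diabetes")])
        fills = fills_df([("p1", 140, "oral_antidiabetic", 30)])
        res = ascertain_outcome(dx, fills, index_day=0)
        assert res.event_month == 5
        assert res.rule == "outpatient_plus_oral_antidiabetic"

    def test_two_outpatient_claims_dated_at_the_first(self):
        dx = dx_df([("p1", 40, "outpatient", "primary", "type2_diabetes"),
                    ("p1", 300, "outpatient", "secondary", "type2_diabetes")])
        res = ascertain_outcome(dx, fills_df([]), index_day=0)
        assert res.event_month == 2 and res.rule == "two_outpatient_12mo"

    def test_pair_outside_12_months_does_not_qualify(self):
        dx = dx_df([("p1", 40, "outpatient", "primary", "type2_diabetes"),
                    ("p1", 410, "outpatient", "primary", "type2_diabetes")])
        res = ascertain_outcome(dx, fills_df([]), index_day=0)
        assert res.event_month is None and res.rule == "none"

    def test_insulin_only_treatment_never_qualifies(self):
        dx = dx_df([("p1", 70, "outpatient", "primary", "type2_diabetes")])
        fills = fills_df([("p1", 75, "insulin", 30), ("p1", 105, "insulin", 30)])
        res = ascertain_outcome(dx, fills, index_day=0)
        assert res.event_month is None and res.rule == "none"


class TestCensoring:
    def test_same_month_tie_resolved_by_hierarchy(self):
        assert determine_censoring([(5, "switch"), (5, "death")], 24).cause == "death"

    def test_no_events_is_administrative_end(self):
        out = determine_censoring([], 24)
        assert out.month == 24 and out.cause == "study_end"

    def test_earlier_month_beats_hierarchy(self):
        out = determine_censoring([(4, "augmentation"), (3, "discontinuation")], 24)
        assert (out.month, out.cause) == (3, "discontinuation")

    def test_unknown_cause_raises(self):
        with pytest.raises(ValueError):
            determine_censoring([(3, "moved_abroad")], 24)

    def test_recorded_cause_invariant_under_event_permutation(self):
        events = [(5, "death"), (5, "coverage_loss"), (5, "switch"),
                  (3, "augmentation"), (3, "discontinuation")]
        results = {(determine_censoring(list(p), 24).month,
                    determine_censoring(list(p), 24).cause)
                   for p in permutations(events)}
        assert results == {(3, "discontinuation")}


class TestPanelFromClaims:
    def _clean_bundle(self, n=200, seed=11, **overrides):
        cfg = DGPConfig(n_subjects=n, seed=seed, **overrides)
        return cfg, generate_claims(cfg)

    def test_round_trip_is_exact_on_clean_configs(self):
        cfg, bundle = self._clean_bundle()
        res = build_cohort(bundle, window_days=cfg.calendar.window_days)
        lat = bundle.latent_truth.reset_index(drop=True)
        built = res.panel.reset_index(drop=True)
        assert len(lat) == len(built)
        for col in PANEL_COLUMNS:
            a, b = lat[col], built[col]
            if col == "Y":
                assert a.fillna(-1.0).eq(b.fillna(-1.0)).all()
            else:
                assert a.eq(b).all(), col

    def test_exposure_months_form_a_prefix(self):
        cfg, bundle = self._clean_bundle(n=150, seed=12)
        res = build_cohort(bundle, window_days=cfg.calendar.window_days)
        for _, grp in res.panel.groupby("person_id"):
            a = grp.sort_values("month")["A"].to_numpy()
            assert np.all(np.diff(a) <= 0)

    def test_attrition_accounts_for_every_person(self):
        cfg = DGPConfig(n_subjects=150, seed=13, distractors={
            "other_antipsychotic_pre_period": 0.05, "not_new_user": 0.05,
            "enrolment_gap": 0.05, "prior_diabetes_or_cardiometabolic": 0.05,
            "pcos": 0.05, "age_out_of_range": 0.05})
        bundle = generate_claims(cfg)
        res = build_cohort(bundle, window_days=cfg.calendar.window_days)
        att = dict(zip(res.attrition["reason"], res.attrition["count"]))
        total_persons = len(bundle.demographics)
        assert sum(att.values()) == total_persons
        # each planted violation lands in its own bucket
        for reason in ("other_antipsychotic_pre_period", "not_new_user",
                       "enrolment_gap", "prior_diabetes_or_cardiometabolic",
                       "pcos", "age_out_of_range"):
            assert att[reason] == round(0.05 * 150), reason
        # exactly one exclusion reason per excluded person
        excl = res.cohort[res.cohort["eligible"] == 0]
        assert (excl["exclusion_reason"] != "none").all()

    def test_latent_recovery_rate_with_distractors(self):
        cfg = DGPConfig(n_subjects=800, seed=7, distractors={
            "enrolment_gap": 0.02, "insulin_only": 0.01})
        bundle = generate_claims(cfg)
        res = build_cohort(bundle, window_days=cfg.calendar.window_days)
        lat = bundle.latent_truth
        merged = lat.merge(res.panel, on=["person_id", "month"],
                           suffixes=("_l", "_b"), how="left", indicator=True)
        matched = merged["_merge"] == "both"
        ok = matched.copy()
        for col in ("A", "C", "cause", "Y", "comorb", "acute"):
            a, b = merged[col + "_l"], merged[col + "_b"]
            ok &= a.fillna(-1).eq(b.fillna(-1)) if a.dtype.kind == "f" \
                else a.eq(b).fillna(False)
        assert ok.mean() >= 0.99
        # insulin-only decoys must carry no diabetes event
        decoys = res.cohort[res.cohort["person_id"].str.startswith("d")
                            & (res.cohort["eligible"] == 1)]
        assert (decoys["event_month"] == 0).all()

    def test_augmentation_ends_exposure_while_supply_continues(self):
        index = 400
        fills = fills_df(
            [("p1", index + 30 * t, "index_olanzapine", 30) for t in range(8)]
            + [("p1", index + 5 * 30 + 12, "other_antipsychotic", 30)])
        enrol = pd.DataFrame([("p1", index - 180, 2190)],
                             columns=["person_id", "start_day", "end_day"])
        demo = pd.DataFrame([("p1", index - 40 * 365, "M", "white", 0,
                              "schizophrenia", np.nan)],
                            columns=["person_id", "birth_day", "sex",
                                     "race_group", "state", "dx", "death_day"])
        from sgarisk.simulate import RawClaimsBundle
        bundle = RawClaimsBundle(fills=fills, dx_claims=dx_df([]),
                                 enrolment=enrol,
                                 procedures=pd.DataFrame(
                                     columns=["person_id", "day", "kind"]),
                                 demographics=demo)
        res = build_cohort(bundle, window_days=2190)
        row = res.cohort.iloc[0]
        assert row["censor_cause"] == "augmentation" and row["censor_month"] == 6
        last = res.panel.sort_values("month").iloc[-1]
        assert last["month"] == 6 and last["A"] == 0 and last["C"] == 1


class TestBalance:
    def _cohort(self, ari_vals, olz_vals):
        rows = ([{"person_id": f"a{i}", "drug": "aripiprazole", "x": v,
                  "eligible": 1} for i, v in enumerate(ari_vals)]
                + [{"person_id": f"o{i}", "drug": "olanzapine", "x": v,
                    "eligible": 1} for i, v in enumerate(olz_vals)])
        return pd.DataFrame(rows)

    def test_identical_groups_have_zero_smd(self):
        c = self._cohort([0, 1, 0, 1], [1, 0, 1, 0])
        assert compute_smd(c, "x").smd == pytest.approx(0.0)

    def test_direct_formula_evaluation(self):
        rng = np.random.default_rng(0)
        # aripiprazole mean 0.5, olanzapine mean 0.6, sd(ari) forced by values
        ari = [0.0, 1.0] * 50           # mean .5, sd ~.5025
        olz = [0.2, 1.0] * 50           # mean .6
        c = self._cohort(ari, olz)
        sd = np.std(ari, ddof=1)
        assert compute_smd(c, "x").smd == pytest.approx((0.6 - 0.5) / sd)

    @pytest.mark.parametrize("shift,flag", [(0.11, True), (0.09, False)])
    def test_imbalance_flag_threshold(self, shift, flag):
        ari = [0.0, 1.0] * 200          # sd(ari) ~ 0.5006
        sd = float(np.std(ari, ddof=1))
        olz = [0.5 + shift * sd - 0.5, 0.5 + shift * sd + 0.5] * 200
        c = self._cohort(ari, olz)
        b = compute_smd(c, "x")
        assert b.smd == pytest.approx(shift, rel=1e-6)
        assert b.unbalanced is flag

    def test_zero_reference_variance_is_flagged_undefined(self):
        c = self._cohort([1.0, 1.0, 1.0], [0.5, 0.7, 0.9])
        b = compute_smd(c, "x")
        assert b.undefined and np.isnan(b.smd)
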