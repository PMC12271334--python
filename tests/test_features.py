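from datetime import datetime, timedelta

import numpy as np
import pytest

from ppgv.core_io import AGENT_CLASSES, FOOD_GROUPS, MedicationEvent
from ppgv.features import (
    ACTION_WINDOWS,
    assemble_matrix,
    any_medication_active,
    category_of,
    feature_category_map,
    meal_lag_features,
    medication_features,
    temporal_features,
)
from ppgv.labeling import label_participant
from ppgv.synthetic import SyntheticTruth, generate_participant

START = datetime(2021, 3, 1)


class TestTemporalFeatures:
    def test_first_meal_of_study_has_no_history(self):
        f = temporal_features(START + timedelta(hours=7, minutes=30), START, [])
        assert f["hour_of_day"] == 7
        assert f["time_in_study"] == 0
        assert f["ate_last_8h"] == 0 and f["ate_last_24h"] == 0
        assert f["slot_breakfast"] == 1

    def test_recent_prior_meal_sets_recency_and_slot(self):
        t = START + timedelta(hours=12, minutes=15)
        f = temporal_features(t, START, [START + timedelta(hours=7, minutes=30)])
        assert f["ate_last_8h"] == 1
        assert f["slot_lunch"] == 1

    def test_calendar_boundaries(self):
        t = datetime(2020, 12, 31, 23, 59)
        f = temporal_features(t, datetime(2020, 12, 20), [])
        assert f["month"] == 12
        assert f["day_of_month"] == 31
        assert f["slot_other"] == 1  # 23:59 outside all named slots

    def test_meal_before_study_start_rejected(self):
        with pytest.raises(ValueError):
            temporal_features(START - timedelta(hours=1), START, [])


class TestMealLagFeatures:
    def test_single_meal_no_history(self, meal_factory):
        t = START + timedelta(hours=12)
        meal = meal_factory(t, staples=150.0)
        f = meal_lag_features([meal], t, current=meal)
        assert f["staples_g_now"] == 150
        assert f["staples_g_8h"] == 0
        assert f["total_g_24h"] == 0

    def test_window_membership(self, meal_factory):
        t = START + timedelta(hours=20)
        m1 = meal_factory(t - timedelta(hours=9), vegetables=100.0)
        m2 = meal_factory(t - timedelta(hours=2), vegetables=50.0)
        cur = meal_factory(t)
        f = meal_lag_features([m1, m2, cur], t, current=cur)
        assert f["vegetables_g_8h"] == 50
        assert f["vegetables_g_24h"] == 150

    def test_all_zero_meal(self, meal_factory):
        t = START + timedelta(hours=8)
        meal = meal_factory(t)
        f = meal_lag_features([meal], t, current=meal)
        for g in FOOD_GROUPS:
            assert f[f"{g}_g_now"] == 0
            assert f[f"{g}_any_now"] == 0

    def test_lag_sums_match_brute_force_double_loop(self, meal_factory):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(2, 15)
            times = sorted(START + timedelta(minutes=float(m)) for m in rng.uniform(0, 3000, n))
            meals = [meal_factory(t, staples=float(rng.uniform(0, 200)), dairy=float(rng.uniform(0, 100))) for t in times]
            at = times[rng.integers(0, n)]
            f = meal_lag_features(meals, at, current=None)
            for g, win_h, key in (("staples", 8, "staples_g_8h"), ("dairy", 24, "dairy_g_24h")):
                brute = sum(
                    m.grams_by_group[g]
                    for m in meals
                    if at - timedelta(hours=win_h) < m.timestamp < at
                )
                assert f[key] == pytest.approx(brute)


class TestMedicationFeatures:
    def test_bolus_one_hour_ago_is_active(self):
        t = START + timedelta(hours=12)
        meds = [MedicationEvent("P", t - timedelta(hours=1), "bolus_insulin", 6.0)]
        f = medication_features(meds, t)
        assert f["bolus_insulin_active"] == 1
        assert f["bolus_insulin_active_dose"] == 6

    def test_bolus_ten_minutes_ago_not_yet_acting(self):
        t = START + timedelta(hours=12)
        meds = [MedicationEvent("P", t - timedelta(minutes=10), "bolus_insulin", 6.0)]
        f = medication_features(meds, t)
        assert f["bolus_insulin_active"] == 0
        assert f["bolus_insulin_dose_8h"] == 6

    def test_basal_thirty_hours_ago_fully_elapsed(self):
        t = START + timedelta(hours=40)
        meds = [MedicationEvent("P", t - timedelta(hours=30), "basal_insulin", 20.0)]
        f = medication_features(meds, t)
        assert all(f[f"basal_insulin_{s}"] == 0 for s in ("active", "active_dose", "dose_8h", "dose_24h"))

    def test_action_window_boundaries_are_half_open(self):
        t = START + timedelta(hours=12)
        onset, offset = ACTION_WINDOWS["non_insulin_agent"]
        at_offset = [MedicationEvent("P", t - timedelta(hours=offset), "non_insulin_agent", 500.0, "mg")]
        past_offset = [MedicationEvent("P", t - timedelta(hours=offset, seconds=1), "non_insulin_agent", 500.0, "mg")]
        assert medication_features(at_offset, t)["non_insulin_agent_active"] == 1
        assert medication_features(past_offset, t)["non_insulin_agent_active"] == 0
        assert any_medication_active(at_offset, t)


@pytest.fixture(scope="module")
def labeled_participant():
    truth = SyntheticTruth(
        participant_id="F1", driver_weights={"staples": 80.0}, seed=17, med_suppression=0.4
    )
    rec = generate_participant(truth, days=14)
    return rec, label_participant(rec)


class TestAssembleMatrix:
    def test_fully_observed_participant_has_no_missing_flags_set(self, labeled_participant):
        rec, obs = labeled_participant
        m = assemble_matrix(obs, rec.meals, rec.meds, "high_burden")
        flag_cols = [c for c in m.X.columns if c.endswith("_missing")]
        # only the first row's previous-excursion lag is structurally missing
        assert m.X[[c for c in flag_cols if c != "prev_excursion_missing"]].to_numpy().sum() == 0
        assert m.X["prev_excursion_missing"].iloc[0] == 1
        assert m.X["prev_excursion_missing"].iloc[1:].sum() == 0

    def test_low_burden_schema_has_no_gram_or_medication_columns(self, labeled_participant):
        rec, obs = labeled_participant
        m = assemble_matrix(obs, rec.meals, rec.meds, "low_burden")
        assert not any("_g_" in c or "insulin" in c or "agent" in c for c in m.X.columns)
        assert "prev_excursion" in m.X.columns
        assert "hour_of_day" in m.X.columns

    def test_planted_missingness_is_imputed_to_train_median_and_flagged(self):
        truth = SyntheticTruth(participant_id="F2", driver_weights={"staples": 80.0}, seed=23)
        rec = generate_participant(truth, days=14, gram_blank_rate=0.3)
        obs = label_participant(rec)
        m = assemble_matrix(obs, rec.meals, rec.meds, "high_burden")
        assert not m.X.isna().any().any()
        usable = [o for o in obs if o.usable]
        blanked_rows = [
            i for i, o in enumerate(usable) if np.isnan(rec.meals[o.meal_index].grams_by_group["vegetables"])
        ]
        assert blanked_rows, "expected some blanked vegetable grams"
        flags = m.X["vegetables_g_now_missing"].to_numpy()
        assert set(np.nonzero(flags)[0]) == set(blanked_rows)
        med = m.impute_values["vegetables_g_now"]
        assert (m.X["vegetables_g_now"].iloc[blanked_rows] == med).all()

    def test_no_event_at_or_after_meal_time_influences_its_row(self, labeled_participant):
        rec, obs = labeled_participant
        base = assemble_matrix(obs, rec.meals, rec.meds, "high_burden")
        usable = [o for o in obs if o.usable]
        probe = len(usable) // 2
        t_probe = usable[probe].meal_time
        # perturb every strictly later meal's grams and med doses
        meals2 = []
        for m in rec.meals:
            if m.timestamp > t_probe:
                g = {k: (v if np.isnan(v) else v + 500.0) for k, v in m.grams_by_group.items()}
                meals2.append(type(m)(m.participant_id, m.timestamp, g, m.total_grams + 3500.0, m.raw_text))
            else:
                meals2.append(m)
        meds2 = [
            MedicationEvent(d.participant_id, d.timestamp, d.agent_class, d.dose + 99.0, d.dose_unit)
            if d.timestamp > t_probe
            else d
            for d in rec.meds
        ]
        pert = assemble_matrix(obs, meals2, meds2, "high_burden")
        assert base.X.iloc[: probe + 1].equals(pert.X.iloc[: probe + 1])

    def test_deterministic_output(self, labeled_participant):
        rec, obs = labeled_participant
        a = assemble_matrix(obs, rec.meals, rec.meds, "high_burden")
        b = assemble_matrix(obs, rec.meals, rec.meds, "high_burden")
        assert a.X.equals(b.X)
        assert (a.y == b.y).all()

    def test_unknown_schema_rejected(self, labeled_participant):
        rec, obs = labeled_participant
        with pytest.raises(ValueError, match="schema"):
            assemble_matrix(obs, rec.meals, rec.meds, "medium_burden")


class TestCategoryMap:
    @pytest.mark.parametrize("schema", ["low_burden", "high_burden"])
    def test_every_matrix_column_is_covered_exactly_once(self, labeled_participant, schema):
        rec, obs = labeled_participant
        m = assemble_matrix(obs, rec.meals, rec.meds, schema)
        cmap = feature_category_map(schema)
        for col in m.X.columns:
            category_of(col, cmap)  # raises if uncovered

    def test_missing_flag_inherits_base_feature_category(self):
        cmap = feature_category_map("high_burden")
        assert category_of("vegetables_g_now_missing", cmap) == category_of("vegetables_g_now", cmap)
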