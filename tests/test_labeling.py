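from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgv.labeling import (
    PPGObservation,
    apply_eligibility,
    compute_iauc,
    label_excursions,
    label_participant,
    observations_frame,
)
from ppgv.synthetic import SyntheticTruth, generate_participant

MEAL = datetime(2021, 3, 1, 9, 0)


class TestComputeIauc:
    def test_constant_series_has_zero_iauc(self, series_factory):
        g = series_factory([140.0] * 12, start="2021-03-01T08:30")
        iauc, n, reason = compute_iauc(g, MEAL)
        assert iauc == pytest.approx(0.0)
        assert reason is None

    def test_linear_rise_equals_triangle_area(self, series_factory):
        # +36 mg/dL linearly over exactly 120 min, readings every 15 min
        values = [120 + 36 * k / 8 for k in range(9)]
        g = series_factory(values, start="2021-03-01T09:00")
        iauc, _, _ = compute_iauc(g, MEAL)
        assert iauc == pytest.approx(0.5 * 120 * 36)

    def test_dips_below_anchor_are_clipped_to_zero(self, series_factory):
        g = series_factory([140.0] + [120.0] * 9, start="2021-03-01T09:00")
        iauc, _, _ = compute_iauc(g, MEAL)
        assert iauc == pytest.approx(0.0)

    def test_positive_part_matches_brute_force_riemann_sum(self, series_factory):
        rng = np.random.default_rng(4)
        for _ in range(50):
            values = rng.uniform(90, 250, size=12)
            g = series_factory(values, start="2021-03-01T09:00")
            iauc, _, _ = compute_iauc(g, MEAL)
            # dense 0.01-min Riemann sum over the linear interpolant
            t = np.arange(9) * 15.0
            v = np.maximum(values[:9] - values[0], 0.0)
            tt = np.arange(0, 120, 0.01)
            assert iauc == pytest.approx(np.interp(tt, t, v).sum() * 0.01, rel=1e-3)

    def test_empty_series_undefined_with_reason(self, series_factory):
        g = series_factory([])
        iauc, _, reason = compute_iauc(g, MEAL)
        assert iauc is None
        assert reason == "empty_series"

    def test_no_anchor_within_tolerance_is_undefined(self, series_factory):
        g = series_factory([120.0] * 10, start="2021-03-01T10:00")  # first reading 60 min late
        iauc, _, reason = compute_iauc(g, MEAL)
        assert iauc is None
        assert reason == "no_anchor"

    def test_sparse_window_is_undefined_not_zero(self, series_factory):
        g = series_factory([120.0, 130.0, 140.0], start="2021-03-01T09:00", step_min=15)
        iauc, _, reason = compute_iauc(g, MEAL)
        assert iauc is None
        assert reason == "too_few_points"

    def test_window_must_be_positive(self, series_factory):
        with pytest.raises(ValueError):
            compute_iauc(series_factory([120.0]), MEAL, window_min=0)


class TestLabelExcursions:
    def test_hand_computed_expanding_mean(self):
        out = label_excursions([10, 20, 5, 30])
        baselines = [b for b, _ in out]
        labels = [l for _, l in out]
        assert baselines[0] is None and labels[0] is None
        assert baselines[1:] == pytest.approx([10, 15, 35 / 3])
        assert labels[1:] == [1, 0, 1]

    def test_strictly_increasing_sequence_all_excursions(self):
        out = label_excursions(list(range(1, 11)))
        assert [l for _, l in out[1:]] == [1] * 9

    def test_tie_with_baseline_is_not_an_excursion(self):
        out = label_excursions([7.0, 7.0, 7.0])
        assert [l for _, l in out] == [None, 0, 0]

    def test_empty_input_empty_output(self):
        assert label_excursions([]) == []

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=1, max_size=50))
    def test_labels_agree_with_prefix_mean_for_any_sequence(self, seq):
        out = label_excursions(seq)
        assert out[0] == (None, None)
        for i in range(1, len(seq)):
            baseline = sum(seq[:i]) / i
            assert out[i][0] == pytest.approx(baseline, rel=1e-12, abs=1e-12)
            assert out[i][1] == (1 if seq[i] > baseline else 0)

    def test_matches_brute_force_prefix_mean_loop(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            seq = rng.uniform(0, 5000, size=rng.integers(2, 40)).tolist()
            fast = label_excursions(seq)
            for i in range(1, len(seq)):
                baseline = sum(seq[:i]) / i  # literal prefix re-average
                assert fast[i][0] == pytest.approx(baseline)
                assert fast[i][1] == (1 if seq[i] > baseline else 0)


def _obs(pid, labels):
    out = []
    for i, lab in enumerate(labels):
        out.append(
            PPGObservation(pid, i, MEAL + timedelta(hours=4 * i), 100.0 * i, 50.0, lab, usable=lab is not None)
        )
    return out


class TestEligibility:
    def test_nineteen_usable_excluded_twenty_included(self):
        cohort = {
            "A": _obs("A", [None] + [i % 2 for i in range(19)]),
            "B": _obs("B", [None] + [i % 2 for i in range(20)]),
        }
        included, log = apply_eligibility(cohort)
        assert "B" in included and "A" not in included
        assert log == [{"participant_id": "A", "reason": "insufficient_obs"}]

    def test_single_class_excluded_for_no_variability(self):
        cohort = {"C": _obs("C", [None] + [1] * 25)}
        included, log = apply_eligibility(cohort)
        assert not included
        assert log[0]["reason"] == "no_variability"

    def test_no_usable_observations_reason(self):
        cohort = {"D": _obs("D", [None, None])}
        _, log = apply_eligibility(cohort)
        assert log[0]["reason"] == "no_ppg"

    def test_planted_short_records_are_the_exact_exclusions(self):
        cohort = {}
        for i in range(8):
            cohort[f"ok{i}"] = _obs(f"ok{i}", [None] + [j % 2 for j in range(24)])
        cohort["short1"] = _obs("short1", [None, 1, 0])
        cohort["short2"] = _obs("short2", [None, 0, 1, 0])
        included, log = apply_eligibility(cohort)
        assert len(included) == 8
        assert sorted(e["participant_id"] for e in log) == ["short1", "short2"]


class TestLabelParticipant:
    def test_first_defined_meal_has_no_baseline(self):
        truth = SyntheticTruth(participant_id="L1", driver_weights={"staples": 80.0}, seed=3)
        rec = generate_participant(truth, days=5)
        obs = label_participant(rec)
        defined = [o for o in obs if o.iauc is not None]
        assert not defined[0].usable
        assert defined[0].reason == "no_prior_baseline"
        assert all(o.usable for o in defined[1:])
        # labels agree with a direct expanding-mean recomputation
        iaucs = [o.iauc for o in defined]
        for i, o in enumerate(defined[1:], start=1):
            assert o.label == (1 if iaucs[i] > np.mean(iaucs[:i]) else 0)

    def test_observations_frame_has_one_row_per_meal(self):
        truth = SyntheticTruth(participant_id="L2", driver_weights={"staples": 80.0}, seed=4)
        rec = generate_participant(truth, days=4)
        obs = label_participant(rec)
        df = observations_frame({"L2": obs})
        assert len(df) == len(rec.meals)
        assert set(df.columns) >= {"iauc", "baseline_mean", "label", "usable"}
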