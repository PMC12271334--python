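"""Seedable synthetic cohort generator with known excursion drivers.

Each synthetic participant's CGM trace is a personal baseline plus a 24-h
circadian sinusoid, a piecewise-linear response pulse per meal, and Gaussian
sensor noise.  The pulse peaks 45 min after the meal and returns to baseline
at 180 min; its height is a weighted sum of standardized meal exposures
(grams per food group / 100, a late-evening risk-window indicator), damped by
(1 − med_suppression) when a glucose-lowering agent is pharmacodynamically
active at meal time.  The weights are stored per participant as ground truth
so that downstream driver-recovery can be tested.

Schedule and portion statistics emulate a free-living Chinese T2D cohort:
three clustered daily meal slots (plus an occasional afternoon snack, giving
≈3.23 meals/day), lognormal grams per food group scaled to daily totals of
roughly 222 g staples, 156 g vegetables, 145 g animal foods, 82 g dairy,
31 g fruits, 9 g legumes/nuts/seeds and 1.5 g sweets, 14 days of wear at
15-min CGM sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .core_io import (
    FOOD_GROUPS,
    GlucoseSeries,
    MealEvent,
    MedicationEvent,
    ParticipantRecord,
)
from .features import any_medication_active

#: driver categories the generator understands: the seven food groups plus
#: total grams and the hour-of-day risk window
DRIVER_KEYS: tuple[str, ...] = (*FOOD_GROUPS, "total_grams", "hour_of_day")

#: pulse shape timing, minutes post-meal
PULSE_PEAK_MIN = 45.0
PULSE_END_MIN = 180.0

#: per-meal presence probability and mean grams per food group, calibrated so
#: that daily totals land near the emulated cohort's printed averages
_GROUP_PRESENCE = {
    "staples": 0.95,
    "vegetables": 0.90,
    "animal_foods": 0.90,
    "dairy": 0.35,
    "fruits": 0.25,
    "legumes_nuts_seeds": 0.20,
    "sweets": 0.05,
}
_GROUP_MEAN_G = {
    "staples": 72.3,
    "vegetables": 53.6,
    "animal_foods": 49.8,
    "dairy": 72.8,
    "fruits": 38.4,
    "legumes_nuts_seeds": 13.6,
    "sweets": 9.5,
}
#: within-portion lognormal jitter and the small/large portion mixture:
#: each present group is eaten as a light portion (×0.45) or a generous one
#: (×1.55) with equal probability, emulating the strongly bimodal
#: meal-to-meal portion variation of real food logs (congee breakfast vs a
#: rice-heavy main meal); the mixture preserves the calibrated means
_LOGNORM_SIGMA = 0.35
_PORTION_FACTORS = (0.45, 1.55)
#: probability that a group's next portion size repeats the previous one —
#: dietary routine persistence, which is what makes the lagged
#: previous-excursion feature informative for passively sensed models
_PORTION_PERSISTENCE = 0.65

#: daily gram targets implied by the presence/mean calibration above
DAILY_GRAM_TARGETS = {
    g: 3.23 * _GROUP_PRESENCE[g] * _GROUP_MEAN_G[g] for g in _GROUP_PRESENCE
}

_STUDY_START = datetime(2021, 3, 1)


@dataclass
class SyntheticTruth:
    """Ground-truth excursion drivers for one synthetic participant."""

    participant_id: str
    driver_weights: dict[str, float]
    circadian_amplitude: float = 10.0  # mg/dL
    noise_sd: float = 4.0  # mg/dL
    med_suppression: float = 0.0  # fraction of pulse height removed
    seed: int = 0
    baseline: float = 150.0  # mg/dL fasting level
    risk_window: tuple[float, float] = (18.0, 24.0)  # hours of day
    kind: str = "custom"

    def __post_init__(self) -> None:
        unknown = set(self.driver_weights) - set(DRIVER_KEYS)
        if unknown:
            raise ValueError(f"unknown driver keys: {unknown}")
        if any(w < 0 for w in self.driver_weights.values()):
            raise ValueError("driver_weights must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.med_suppression <= 1:
            raise ValueError("med_suppression must lie in [0, 1]")

    @property
    def dominant_driver(self) -> str | None:
        if not self.driver_weights or max(self.driver_weights.values()) == 0:
            return None
        return max(self.driver_weights, key=lambda k: self.driver_weights[k])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["risk_window"] = list(self.risk_window)
        return d


#: mapping from generator driver keys to vulnerability-profile categories
DRIVER_TO_CATEGORY = {
    "staples": "staples",
    "vegetables": "vegetable intake",
    "fruits": "fruit intake",
    "animal_foods": "animal foods",
    "dairy": "dairy intake",
    "legumes_nuts_seeds": "legumes nuts seeds intake",
    "sweets": "sweets intake",
    "total_grams": "total grams intake",
    "hour_of_day": "hour of the day",
}


def pulse_value(minutes_post_meal: float, peak_height: float) -> float:
    """Piecewise-linear meal response: rise to peak at 45 min, back to 0 at 180."""
    u = minutes_post_meal
    if u <= 0 or u >= PULSE_END_MIN or peak_height == 0:
        return 0.0
    if u <= PULSE_PEAK_MIN:
        return peak_height * u / PULSE_PEAK_MIN
    return peak_height * (PULSE_END_MIN - u) / (PULSE_END_MIN - PULSE_PEAK_MIN)


def analytic_pulse_iauc(peak_height: float, window_min: float = 120.0) -> float:
    """Closed-form area of the pulse over [0, window] (the iAUC of an isolated
    noise-free meal on a flat baseline)."""
    rise_end = min(window_min, PULSE_PEAK_MIN)
    area = 0.5 * rise_end * pulse_value(rise_end, peak_height)
    if window_min > PULSE_PEAK_MIN:
        t1 = min(window_min, PULSE_END_MIN)
        v0 = peak_height
        v1 = pulse_value(t1, peak_height)
        area += 0.5 * (v0 + v1) * (t1 - PULSE_PEAK_MIN)
    return area


def meal_exposures(meal: MealEvent, hour: float, risk_window: tuple[float, float]) -> dict[str, float]:
    """Standardized exposures entering the pulse-height formula."""
    x = {}
    for g in FOOD_GROUPS:
        v = meal.grams_by_group[g]
        x[g] = 0.0 if np.isnan(v) else v / 100.0
    x["total_grams"] = 0.0 if np.isnan(meal.total_grams) else meal.total_grams / 100.0
    lo, hi = risk_window
    x["hour_of_day"] = 1.0 if lo <= hour < hi else 0.0
    return x


def peak_height(truth: SyntheticTruth, meal: MealEvent, suppressed: bool) -> float:
    x = meal_exposures(meal, meal.timestamp.hour + meal.timestamp.minute / 60.0, truth.risk_window)
    h = sum(truth.driver_weights.get(k, 0.0) * x[k] for k in DRIVER_KEYS)
    if suppressed:
        h *= 1.0 - truth.med_suppression
    return h


def _round_to_grid(t: datetime, sampling_min: float) -> datetime:
    day = datetime(t.year, t.month, t.day)
    minutes = (t - day).total_seconds() / 60.0
    snapped = round(minutes / sampling_min) * sampling_min
    return day + timedelta(minutes=snapped)


def generate_participant(
    truth: SyntheticTruth,
    days: int = 14,
    meals_per_day_mean: float = 3.23,
    sampling_min: float = 15.0,
    cgm_drop_rate: float = 0.0,
    gram_blank_rate: float = 0.0,
    emit_medication: bool | None = None,
) -> ParticipantRecord:
    """Simulate one participant's CGM trace, meal log and medication log.

    Deterministic under (truth.seed, parameters).  Meal timestamps are
    rounded to the CGM sampling grid, emulating the coarse clock resolution
    of self-logged meals.  ``cgm_drop_rate`` removes random CGM readings and
    ``gram_blank_rate`` blanks random gram fields, to exercise the coverage
    filters and imputation downstream.
    """
    if days < 3:
        raise ValueError("days must be at least 3")
    if not 5 <= sampling_min <= 15:
        raise ValueError("sampling_min must lie in [5, 15]")
    rng = np.random.default_rng(truth.seed)
    if emit_medication is None:
        emit_medication = truth.med_suppression > 0

    # --- meal schedule: clustered daily slots with jitter, snapped to grid
    slot_means_min = [7.5 * 60, 12.0 * 60, 18.5 * 60]  # breakfast, lunch, dinner
    snack_prob = max(0.0, meals_per_day_mean - 3.0)
    meals: list[MealEvent] = []
    meds: list[MedicationEvent] = []
    # persistent portion state per food group (True = generous portion)
    portion_state = {g: bool(rng.random() < 0.5) for g in FOOD_GROUPS}
    for day in range(days):
        day_start = _STUDY_START + timedelta(days=day)
        times_min: list[float] = []
        for mu in slot_means_min:
            times_min.append(float(np.clip(rng.normal(mu, 40.0), 5 * 60, 23 * 60)))
        if rng.random() < snack_prob:
            times_min.append(float(np.clip(rng.normal(15.5 * 60, 30.0), 14 * 60, 17 * 60)))
        for tm in sorted(times_min):
            t = _round_to_grid(day_start + timedelta(minutes=tm), sampling_min)
            grams = {}
            for g in FOOD_GROUPS:
                present = rng.random() < _GROUP_PRESENCE[g]
                if rng.random() >= _PORTION_PERSISTENCE:
                    portion_state[g] = not portion_state[g]
                if present:
                    mu_ln = np.log(_GROUP_MEAN_G[g]) - _LOGNORM_SIGMA**2 / 2
                    portion = _PORTION_FACTORS[int(portion_state[g])]
                    grams[g] = float(portion * rng.lognormal(mu_ln, _LOGNORM_SIGMA))
                else:
                    grams[g] = 0.0
            total = sum(grams.values())
            if gram_blank_rate > 0:
                for g in FOOD_GROUPS:
                    if rng.random() < gram_blank_rate:
                        grams[g] = float("nan")
            meals.append(MealEvent(truth.participant_id, t, grams, total))
        if emit_medication:
            if rng.random() < 0.6:
                meds.append(
                    MedicationEvent(
                        truth.participant_id,
                        day_start + timedelta(hours=7),
                        "non_insulin_agent",
                        500.0,
                        "mg",
                    )
                )
            if rng.random() < 0.5:
                meds.append(
                    MedicationEvent(
                        truth.participant_id,
                        day_start + timedelta(hours=18),
                        "bolus_insulin",
                        6.0,
                        "IU",
                    )
                )

    # --- pulse heights (medication damping via the shared action windows)
    heights = [peak_height(truth, m, any_medication_active(meds, m.timestamp)) for m in meals]

    # --- CGM trace
    n_samples = int(days * 24 * 60 / sampling_min)
    rel_min = np.arange(n_samples) * sampling_min
    timestamps = np.datetime64(_STUDY_START, "ns") + (rel_min * 60e9).astype("timedelta64[ns]")
    hours = (rel_min / 60.0) % 24.0
    values = truth.baseline + truth.circadian_amplitude * np.sin(2 * np.pi * (hours - 9.0) / 24.0)
    meal_rel = np.array(
        [(np.datetime64(m.timestamp, "ns") - np.datetime64(_STUDY_START, "ns")) / np.timedelta64(60, "s") for m in meals]
    )
    for m_rel, h in zip(meal_rel, heights):
        if h == 0:
            continue
        u = rel_min - m_rel
        mask = (u > 0) & (u < PULSE_END_MIN)
        pv = np.where(
            u[mask] <= PULSE_PEAK_MIN,
            h * u[mask] / PULSE_PEAK_MIN,
            h * (PULSE_END_MIN - u[mask]) / (PULSE_END_MIN - PULSE_PEAK_MIN),
        )
        values[mask] += pv
    if truth.noise_sd > 0:
        values = values + rng.normal(0.0, truth.noise_sd, size=n_samples)
    values = np.clip(values, 1.0, 999.0)

    if cgm_drop_rate > 0:
        keep = rng.random(n_samples) >= cgm_drop_rate
        timestamps = timestamps[keep]
        values = values[keep]

    glucose = GlucoseSeries(truth.participant_id, timestamps, values, nominal_interval=sampling_min)
    return ParticipantRecord(truth.participant_id, glucose, meals, meds)


# ---------------------------------------------------------------------------
# cohort scenarios


def _truth_for_kind(pid: str, kind: str, seed: int, rng: np.random.Generator) -> SyntheticTruth:
    baseline = float(rng.uniform(120.0, 180.0))
    common = dict(participant_id=pid, seed=seed, baseline=baseline, kind=kind)
    if kind == "staples_driven":
        w = {"staples": 90.0, "vegetables": 10.0}
        return SyntheticTruth(driver_weights=w, noise_sd=4.0, **common)
    if kind == "vegetables_driven":
        w = {"vegetables": 90.0, "staples": 10.0}
        return SyntheticTruth(driver_weights=w, noise_sd=4.0, **common)
    if kind == "animal_driven":
        w = {"animal_foods": 90.0, "staples": 10.0}
        return SyntheticTruth(driver_weights=w, noise_sd=4.0, **common)
    if kind == "timing_driven":
        w = {"hour_of_day": 70.0, "staples": 8.0}
        return SyntheticTruth(driver_weights=w, noise_sd=4.0, circadian_amplitude=5.0, **common)
    if kind == "medication_masked":
        w = {"staples": 80.0, "vegetables": 10.0}
        return SyntheticTruth(driver_weights=w, noise_sd=4.0, med_suppression=0.6, **common)
    if kind == "noise_only":
        return SyntheticTruth(driver_weights={"staples": 0.0}, noise_sd=10.0, **common)
    raise ValueError(f"unknown participant kind {kind!r}")


#: scenario name → list of (kind, fraction); fractions sum to 1
SCENARIOS: dict[str, list[tuple[str, float]]] = {
    "mixed": [
        ("staples_driven", 0.40),
        ("timing_driven", 0.30),
        ("medication_masked", 0.20),
        ("noise_only", 0.10),
    ],
    "staples_driven": [("staples_driven", 1.0)],
    "timing_driven": [("timing_driven", 1.0)],
    "medication_masked": [("medication_masked", 1.0)],
    "noise_only": [("noise_only", 1.0)],
    # one dominant driver per person, rotating over four driver categories
    "single_driver": [
        ("staples_driven", 0.25),
        ("vegetables_driven", 0.25),
        ("animal_driven", 0.25),
        ("timing_driven", 0.25),
    ],
}


def generate_cohort(
    n: int,
    scenario: str = "mixed",
    seed: int = 0,
    days: int = 14,
    meals_per_day_mean: float = 3.23,
    sampling_min: float = 15.0,
    cgm_drop_rate: float = 0.0,
    gram_blank_rate: float = 0.0,
) -> list[tuple[ParticipantRecord, SyntheticTruth]]:
    """Generate ``n`` participants under a named scenario mix.

    Per-participant seeds derive deterministically from the master seed; the
    scenario controls the mix of driver kinds (kind assignment rotates
    through the scenario's quotas so counts match the fractions as closely
    as integer division allows).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    mix = SCENARIOS[scenario]
    kinds: list[str] = []
    for kind, frac in mix:
        kinds.extend([kind] * int(round(frac * n)))
    while len(kinds) < n:
        kinds.append(mix[0][0])
    kinds = kinds[:n]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    master_rng = np.random.default_rng(ss.spawn(1)[0])
    out = []
    for i, (kind, child) in enumerate(zip(kinds, children)):
        pid = f"S{i + 1:03d}"
        pseed = int(child.generate_state(1)[0] % (2**31))
        truth = _truth_for_kind(pid, kind, pseed, master_rng)
        rec = generate_participant(
            truth,
            days=days,
            meals_per_day_mean=meals_per_day_mean,
            sampling_min=sampling_min,
            cgm_drop_rate=cgm_drop_rate,
            gram_blank_rate=gram_blank_rate,
        )
        out.append((rec, truth))
    return out


def write_truths(truths: list[SyntheticTruth], path: str | Path) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in truths], indent=1))
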