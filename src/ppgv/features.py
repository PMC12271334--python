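"""Feature engineering for the low- and high-burden model matrices.

Low-burden rows use only passively derivable information: temporal context
plus the previous excursion label.  High-burden rows add everything that
requires manual logging: grams per food group (current meal and 8 h / 24 h
lags) and time-varying glucose-lowering-agent features built from each agent
class's pharmacodynamic action window.

All lag windows are strictly historical — a feature computed at time t never
reads an event at or after t.  Imputation (per-feature median) is fit on the
chronological training portion only and applied to train and test alike;
every imputed cell carries a missingness indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import AGENT_CLASSES, FOOD_GROUPS, MealEvent, MedicationEvent
from .labeling import PPGObservation

#: pharmacodynamic action windows per agent class, hours after the dose,
#: as half-open intervals (onset, offset]
ACTION_WINDOWS: dict[str, tuple[float, float]] = {
    "basal_insulin": (2.0, 24.0),
    "intermediate_insulin": (2.0, 24.0),
    "bolus_insulin": (0.25, 4.0),
    "non_insulin_agent": (0.0, 6.0),
}

#: meal-slot clock boundaries (start hour inclusive, end hour inclusive)
MEAL_SLOTS: dict[str, tuple[int, int]] = {
    "breakfast": (5, 10),
    "lunch": (11, 15),
    "dinner": (16, 22),
}

SCHEMAS = ("low_burden", "high_burden")


def meal_slot(hour: int) -> str:
    for name, (lo, hi) in MEAL_SLOTS.items():
        if lo <= hour <= hi:
            return name
    return "other"


def temporal_features(
    meal_time: datetime, study_start: datetime, prior_meals: Sequence[datetime]
) -> dict[str, float]:
    """Clock/calendar context of a meal plus recency-of-eating indicators.

    ``prior_meals`` must contain only timestamps strictly before
    ``meal_time``; any others are ignored.
    """
    if meal_time < study_start:
        raise ValueError("meal_time precedes study_start")
    h = meal_time.hour
    slot = meal_slot(h)
    feats: dict[str, float] = {
        "hour_of_day": float(h),
        "day_of_week": float(meal_time.weekday()),
        "day_of_month": float(meal_time.day),
        "month": float(meal_time.month),
        "time_in_study": float((meal_time - study_start).days),
    }
    for s in ("breakfast", "lunch", "dinner", "other"):
        feats[f"slot_{s}"] = 1.0 if slot == s else 0.0
    t8 = meal_time - timedelta(hours=8)
    t24 = meal_time - timedelta(hours=24)
    feats["ate_last_8h"] = 1.0 if any(t8 < m < meal_time for m in prior_meals) else 0.0
    feats["ate_last_24h"] = 1.0 if any(t24 < m < meal_time for m in prior_meals) else 0.0
    return feats


def meal_lag_features(meals: Sequence[MealEvent], at: datetime, current: MealEvent | None = None) -> dict[str, float]:
    """Per-group grams for the current meal and 8 h / 24 h historical sums.

    ``current`` is the meal eaten at ``at`` (grams_now features); lag sums run
    over meals strictly before ``at``.  Missing gram fields propagate as NaN
    (to be flagged and imputed downstream); binary any_* features treat an
    unrecorded gram as absent.
    """
    feats: dict[str, float] = {}
    groups = list(FOOD_GROUPS) + ["total"]

    def gram_of(meal: MealEvent, g: str) -> float:
        return meal.total_grams if g == "total" else meal.grams_by_group[g]

    for g in groups:
        now = gram_of(current, g) if current is not None else 0.0
        feats[f"{g}_g_now"] = now
        feats[f"{g}_any_now"] = 1.0 if (not np.isnan(now) and now > 0) else 0.0
        for win_h, tag in ((8, "8h"), (24, "24h")):
            lo = at - timedelta(hours=win_h)
            vals = [gram_of(m, g) for m in meals if lo < m.timestamp < at]
            s = float(np.nansum(vals)) if vals else 0.0
            if vals and all(np.isnan(v) for v in vals):
                s = float("nan")
            feats[f"{g}_g_{tag}"] = s
            feats[f"{g}_any_{tag}"] = 1.0 if any((not np.isnan(v)) and v > 0 for v in vals) else 0.0
    return feats


def medication_features(meds: Sequence[MedicationEvent], at: datetime) -> dict[str, float]:
    """Time-varying medication features at a meal time.

    For each agent class: an active flag and active-dose sum over events
    whose elapsed time (at − dose time) lies inside the class's action
    window, plus plain 8 h / 24 h dose sums regardless of action window.
    Only doses strictly before ``at`` count.
    """
    feats: dict[str, float] = {}
    for cls in AGENT_CLASSES:
        onset, offset = ACTION_WINDOWS[cls]
        active_dose = 0.0
        dose_8h = 0.0
        dose_24h = 0.0
        for m in meds:
            if m.agent_class != cls or m.timestamp >= at:
                continue
            elapsed_h = (at - m.timestamp).total_seconds() / 3600.0
            if onset < elapsed_h <= offset:
                active_dose += m.dose
            if elapsed_h <= 8:
                dose_8h += m.dose
            if elapsed_h <= 24:
                dose_24h += m.dose
        feats[f"{cls}_active"] = 1.0 if active_dose > 0 else 0.0
        feats[f"{cls}_active_dose"] = active_dose
        feats[f"{cls}_dose_8h"] = dose_8h
        feats[f"{cls}_dose_24h"] = dose_24h
    return feats


def any_medication_active(meds: Sequence[MedicationEvent], at: datetime) -> bool:
    """True when any agent class is inside its action window at ``at``."""
    f = medication_features(meds, at)
    return any(f[f"{cls}_active"] > 0 for cls in AGENT_CLASSES)


# ---------------------------------------------------------------------------
# matrices


@dataclass
class PersonMatrix:
    """Model-ready matrix for one participant and one schema.

    ``X`` holds features plus missingness-indicator columns; rows are usable
    observations in chronological order.  ``train_idx`` / ``test_idx`` follow
    the chronological 70/30 convention; imputation medians were fit on the
    training rows only (recorded in ``impute_values``).
    """

    participant_id: str
    schema: str
    X: pd.DataFrame
    y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    impute_values: dict[str, float] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


#: features that may legitimately be missing and therefore always carry an
#: indicator column (gram amounts and the first previous-excursion lag)
def _imputable_features(schema: str) -> list[str]:
    feats = ["prev_excursion"]
    if schema == "high_burden":
        for g in list(FOOD_GROUPS) + ["total"]:
            feats += [f"{g}_g_now", f"{g}_g_8h", f"{g}_g_24h"]
    return feats


def assemble_matrix(
    observations: Sequence[PPGObservation],
    meals: Sequence[MealEvent],
    meds: Sequence[MedicationEvent],
    schema: str,
    study_start: datetime | None = None,
    train_frac: float = 0.70,
) -> PersonMatrix:
    """Build one participant's feature matrix for a schema.

    One row per usable labeled observation, chronological.  The low-burden
    schema contains temporal features and the previous usable excursion
    label; the high-burden schema adds meal-content and medication features.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"schema must be one of {SCHEMAS}")
    usable = [o for o in observations if o.usable]
    if not usable:
        raise ValueError("no usable observations")
    pid = usable[0].participant_id
    if study_start is None:
        t0 = min([m.timestamp for m in meals], default=usable[0].meal_time)
        study_start = datetime(t0.year, t0.month, t0.day)

    meal_by_index = {i: m for i, m in enumerate(meals)}
    all_meal_times = [m.timestamp for m in meals]

    rows: list[dict[str, float]] = []
    prev_label: float = float("nan")
    for o in usable:
        t = o.meal_time
        prior = [mt for mt in all_meal_times if mt < t]
        feats = temporal_features(t, study_start, prior)
        feats["prev_excursion"] = prev_label
        if schema == "high_burden":
            current = meal_by_index.get(o.meal_index)
            feats.update(meal_lag_features(meals, t, current))
            feats.update(medication_features(meds, t))
        rows.append(feats)
        prev_label = float(o.label)  # type: ignore[arg-type]

    X = pd.DataFrame(rows)
    y = np.array([o.label for o in usable], dtype=int)
    n = len(X)
    n_train = int(np.floor(train_frac * n))
    train_idx = np.arange(n_train)
    test_idx = np.arange(n_train, n)

    impute_values: dict[str, float] = {}
    for f in _imputable_features(schema):
        flag = X[f].isna().astype(float)
        X[f"{f}_missing"] = flag
        med = float(X[f].iloc[train_idx].median())
        if np.isnan(med):
            med = 0.0
        impute_values[f] = med
        X[f] = X[f].fillna(med)
    assert not X.isna().any().any(), "matrix contains NaN after imputation"

    return PersonMatrix(pid, schema, X, y, train_idx, test_idx, impute_values)


# ---------------------------------------------------------------------------
# feature → category map (mirrors the vulnerability-profile groupings)


def feature_category_map(schema: str = "high_burden") -> dict[str, str]:
    """Map every feature (and its missingness flag) to a category label."""
    cat: dict[str, str] = {
        "hour_of_day": "hour of the day",
        "day_of_week": "day of the week",
        "day_of_month": "day of the month",
        "month": "month of the year",
        "time_in_study": "time in study",
        "slot_breakfast": "mealtime",
        "slot_lunch": "mealtime",
        "slot_dinner": "mealtime",
        "slot_other": "mealtime",
        "ate_last_8h": "eating recency",
        "ate_last_24h": "eating recency",
        "prev_excursion": "previous PPG excursion",
    }
    group_labels = {
        "staples": "staples",
        "vegetables": "vegetable intake",
        "fruits": "fruit intake",
        "animal_foods": "animal foods",
        "dairy": "dairy intake",
        "legumes_nuts_seeds": "legumes nuts seeds intake",
        "sweets": "sweets intake",
        "total": "total grams intake",
    }
    if schema == "high_burden":
        for g, label in group_labels.items():
            for suffix in ("g_now", "g_8h", "g_24h", "any_now", "any_8h", "any_24h"):
                cat[f"{g}_{suffix}"] = label
        med_labels = {
            "basal_insulin": "basal insulin",
            "intermediate_insulin": "intermediate insulin",
            "bolus_insulin": "bolus insulin",
            "non_insulin_agent": "non-insulin agents",
        }
        for cls, label in med_labels.items():
            for suffix in ("active", "active_dose", "dose_8h", "dose_24h"):
                cat[f"{cls}_{suffix}"] = label
    for f in _imputable_features(schema):
        cat[f"{f}_missing"] = cat[f]
    return cat


def category_of(feature: str, category_map: dict[str, str]) -> str:
    """Category for a feature name, tolerating missing-flag suffixes."""
    if feature in category_map:
        return category_map[feature]
    if feature.endswith("_missing") and feature[: -len("_missing")] in category_map:
        return category_map[feature[: -len("_missing")]]
    raise KeyError(f"feature {feature!r} not covered by the category map")
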