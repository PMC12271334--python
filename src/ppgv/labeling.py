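"""Postprandial outcome labeling.

Each meal's 2-hour incremental area under the curve (iAUC) is computed from
the CGM trace relative to the anchor reading nearest the meal, negative
increments clipped to zero (the positive-part convention standard in the
glycemic-response literature).  A meal is labeled an excursion when its iAUC
exceeds the expanding mean of that participant's prior iAUCs — each person is
their own rolling baseline.  Cohort eligibility filters mirror a
train-test-split requirement of at least 20 labeled observations per person
and at least two outcome classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import GlucoseSeries, ParticipantRecord

#: default analysis window after a meal, minutes
WINDOW_MIN = 120.0
#: how far from the meal time the anchor CGM reading may be, minutes
ANCHOR_TOL_MIN = 20.0
#: minimum readings inside the window (tolerates one missed 15-min reading)
MIN_POINTS = 5
#: minimum minutes the in-window readings must span from the meal time
MIN_COVERAGE_MIN = 100.0
#: minimum usable observations for a participant to enter modeling
MIN_OBS = 20


@dataclass
class PPGObservation:
    """One meal's outcome: iAUC, personal baseline, binary excursion label."""

    participant_id: str
    meal_index: int
    meal_time: datetime
    iauc: float | None  # mg/dL·min, None when not computable
    baseline_mean: float | None = None
    label: int | None = None
    usable: bool = False
    n_cgm_points: int = 0
    reason: str | None = None  # why unusable, when applicable


def compute_iauc(
    glucose: GlucoseSeries,
    meal_time: datetime | np.datetime64,
    window_min: float = WINDOW_MIN,
    anchor_tol_min: float = ANCHOR_TOL_MIN,
    min_points: int = MIN_POINTS,
    min_coverage_min: float = MIN_COVERAGE_MIN,
) -> tuple[float | None, int, str | None]:
    """Trapezoidal 2-h incremental AUC after ``meal_time``.

    Returns ``(iauc, n_points, reason)``; ``iauc`` is ``None`` (never 0) when
    no anchor reading lies within ±``anchor_tol_min`` of the meal, fewer than
    ``min_points`` readings fall in the window, or the readings span less
    than ``min_coverage_min`` of the window.  The anchor glucose G0 is the
    reading nearest the meal time; the integrand is max(G(t) − G0, 0) on
    [meal, meal + window], with the boundary value at the window end linearly
    interpolated when a reading exists beyond it.
    """
    if window_min <= 0:
        raise ValueError("window_min must be positive")
    ts = glucose.timestamps
    if len(ts) == 0:
        return None, 0, "empty_series"
    t0 = np.datetime64(pd.Timestamp(meal_time), "ns")
    rel_min = (ts - t0) / np.timedelta64(60, "s")  # minutes relative to meal

    near = np.abs(rel_min) <= anchor_tol_min
    if not near.any():
        return None, 0, "no_anchor"
    anchor_idx = int(np.argmin(np.abs(rel_min) + np.where(near, 0, np.inf)))
    g0 = glucose.values[anchor_idx]

    in_win = (rel_min > 0) & (rel_min <= window_min)
    n_in = int(in_win.sum())
    if n_in < min_points:
        return None, n_in, "too_few_points"
    t_in = rel_min[in_win]
    v_in = glucose.values[in_win]
    if t_in[-1] < min_coverage_min:
        return None, n_in, "poor_coverage"

    t_grid = [0.0]
    v_grid = [0.0]  # increment at the anchor is zero by construction
    for t, v in zip(t_in, v_in):
        t_grid.append(float(t))
        v_grid.append(max(float(v) - g0, 0.0))
    # extend to the window end by interpolation if a later reading exists
    beyond = rel_min > window_min
    if t_in[-1] < window_min and beyond.any():
        j = int(np.argmax(beyond))  # first reading past the window
        t_a, v_a = t_in[-1], v_in[-1]
        t_b, v_b = float(rel_min[j]), glucose.values[j]
        v_end = v_a + (v_b - v_a) * (window_min - t_a) / (t_b - t_a)
        t_grid.append(window_min)
        v_grid.append(max(float(v_end) - g0, 0.0))
    iauc = float(np.trapezoid(v_grid, t_grid))
    return iauc, n_in, None


def label_excursions(iaucs: Sequence[float]) -> list[tuple[float | None, int | None]]:
    """Expanding-mean excursion labels for an ordered list of defined iAUCs.

    Observation i (i ≥ 2, 1-based) is compared against the mean of all prior
    iAUCs; strictly greater ⇒ label 1, ties ⇒ 0.  The first observation has
    no baseline and gets ``(None, None)``.
    """
    out: list[tuple[float | None, int | None]] = []
    cumsum = 0.0
    for i, x in enumerate(iaucs):
        if i == 0:
            out.append((None, None))
        else:
            baseline = cumsum / i
            out.append((baseline, 1 if x > baseline else 0))
        cumsum += x
    return out


def label_participant(
    record: ParticipantRecord,
    window_min: float = WINDOW_MIN,
    anchor_tol_min: float = ANCHOR_TOL_MIN,
    min_points: int = MIN_POINTS,
    min_coverage_min: float = MIN_COVERAGE_MIN,
) -> list[PPGObservation]:
    """Compute one PPGObservation per logged meal, in meal order.

    Meals whose iAUC is undefined are flagged unusable with the reason from
    :func:`compute_iauc`; among defined-iAUC meals, the first has no prior
    baseline and is unusable; the rest carry expanding-mean labels.
    """
    obs: list[PPGObservation] = []
    defined: list[int] = []
    for i, meal in enumerate(record.meals):
        iauc, n, reason = compute_iauc(
            record.glucose, meal.timestamp, window_min, anchor_tol_min, min_points, min_coverage_min
        )
        o = PPGObservation(record.participant_id, i, meal.timestamp, iauc, n_cgm_points=n, reason=reason)
        if iauc is not None:
            defined.append(i)
        obs.append(o)
    labels = label_excursions([obs[i].iauc for i in defined])  # type: ignore[misc]
    for (idx, (baseline, label)) in zip(defined, labels):
        obs[idx].baseline_mean = baseline
        obs[idx].label = label
        if label is None:
            obs[idx].usable = False
            obs[idx].reason = "no_prior_baseline"
        else:
            obs[idx].usable = True
    return obs


def apply_eligibility(
    cohort: dict[str, list[PPGObservation]],
    min_obs: int = MIN_OBS,
) -> tuple[dict[str, list[PPGObservation]], list[dict[str, str]]]:
    """Cohort filters: no usable observations, too few, or a single class.

    A participant with exactly ``min_obs`` usable observations is included
    (the threshold is a minimum, not a strict bound).  Returns the included
    subset (insertion order preserved) and an exclusion log of
    ``{"participant_id", "reason"}`` rows with reasons ``no_ppg``,
    ``insufficient_obs`` or ``no_variability``.
    """
    included: dict[str, list[PPGObservation]] = {}
    log: list[dict[str, str]] = []
    for pid, obs in cohort.items():
        usable = [o for o in obs if o.usable]
        if len(usable) == 0:
            log.append({"participant_id": pid, "reason": "no_ppg"})
        elif len(usable) < min_obs:
            log.append({"participant_id": pid, "reason": "insufficient_obs"})
        elif len({o.label for o in usable}) < 2:
            log.append({"participant_id": pid, "reason": "no_variability"})
        else:
            included[pid] = obs
    return included, log


def observations_frame(cohort: Iterable[PPGObservation] | dict[str, list[PPGObservation]]) -> pd.DataFrame:
    """Flat table (one row per meal) for observations.csv."""
    if isinstance(cohort, dict):
        rows: Iterable[PPGObservation] = [o for obs in cohort.values() for o in obs]
    else:
        rows = cohort
    return pd.DataFrame(
        [
            {
                "participant_id": o.participant_id,
                "meal_index": o.meal_index,
                "meal_time": pd.Timestamp(o.meal_time).isoformat(),
                "iauc": o.iauc,
                "baseline_mean": o.baseline_mean,
                "label": o.label,
                "usable": o.usable,
                "n_cgm_points": o.n_cgm_points,
                "reason": o.reason or "",
            }
            for o in rows
        ]
    )
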