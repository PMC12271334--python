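"""Test-set metrics, low- vs high-burden comparison, and cohort summaries.

Precision is undefined when a model makes no positive prediction and recall
when the test block contains no positive label; an undefined component makes
F1 undefined, and undefined values are excluded from aggregates rather than
coerced to zero.

The burden comparison replicates a subgroup-then-test procedure: participants
are grouped by the sign of (F1_low − F1_high) and a paired two-sided Wilcoxon
signed-rank test (normal approximation with continuity correction, average
ranks for ties, zero differences dropped) is run within each non-tie
subgroup.  Testing inside a subgroup selected by the sign of the very
difference under test is circular — the resulting p-values describe the
subgroup, not the cohort — and the report says so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

SUBGROUP_CAVEAT = (
    "Note: the within-subgroup Wilcoxon tests condition on the sign of the "
    "difference that defines each subgroup; they describe the magnitude of "
    "the difference within the subgroup and must not be read as cohort-level "
    "significance tests."
)


@dataclass
class EvalResult:
    """Confusion counts and derived metrics for one participant × schema."""

    participant_id: str
    schema: str
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def score(test_labels, test_predictions, participant_id: str = "", schema: str = "") -> EvalResult:
    """Precision / recall / F1 of the positive class, undefined propagated."""
    y = np.asarray(test_labels, dtype=int)
    p = np.asarray(test_predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalResult(participant_id, schema, tp, fp, tn, fn, precision, recall, f1)


def best_of_two(f1_low: float | None, f1_high: float | None) -> tuple[str, float | None]:
    """Pick the better schema by F1; single-defined wins; exact ties tie.

    Both undefined → ('incomparable', None); such participants are excluded
    from best-model summaries.
    """
    if f1_low is None and f1_high is None:
        return "incomparable", None
    if f1_high is None:
        return "low_burden", f1_low
    if f1_low is None:
        return "high_burden", f1_high
    if f1_low == f1_high:
        return "tie", f1_low
    return ("low_burden", f1_low) if f1_low > f1_high else ("high_burden", f1_high)


def wilcoxon_signed_rank(before, after) -> dict:
    """Paired two-sided Wilcoxon signed-rank test, normal approximation.

    Zero differences are dropped; tied absolute differences get average
    ranks; the tie-corrected variance and a 0.5 continuity correction toward
    the null mean are used.  Returns W+ (sum of positive ranks), Z, p and
    the number of non-zero pairs.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    d = after - before
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return {"w_plus": 0.0, "z": 0.0, "p": 1.0, "n": 0}
    ranks = stats.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return {"w_plus": w_plus, "z": 0.0, "p": 1.0, "n": n}
    diff = w_plus - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = float((diff - cc) / math.sqrt(var)) if diff != 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return {"w_plus": w_plus, "z": z, "p": min(p, 1.0), "n": n}


def subgroup_and_test(pairs: dict[str, tuple[float | None, float | None]]) -> dict:
    """Burden-comparison report over per-participant (f1_low, f1_high) pairs.

    Participants with both F1s defined are assigned to low_better /
    high_better / tie; those with an undefined F1 on either side are
    'incomparable' and excluded from subgroup tests.  Within each non-tie
    subgroup the signed-rank test compares the losing schema ('before') to
    the winning one ('after'); subgroup medians per schema are reported.
    Cohort summaries (mean, median, SD) cover the best-of-two F1 over all
    participants with a defined best F1.
    """
    assignment: dict[str, str] = {}
    per_participant: dict[str, dict] = {}
    for pid, (lo, hi) in pairs.items():
        schema, best = best_of_two(lo, hi)
        if lo is None or hi is None:
            group = "incomparable" if best is None else "incomparable"
        elif lo > hi:
            group = "low_better"
        elif hi > lo:
            group = "high_better"
        else:
            group = "tie"
        assignment[pid] = group
        per_participant[pid] = {"f1_low": lo, "f1_high": hi, "best_schema": schema, "best_f1": best, "subgroup": group}

    def _subgroup_stats(group: str, before_key: int, after_key: int) -> dict | None:
        members = [pid for pid, g in assignment.items() if g == group]
        if not members:
            return None
        lows = np.array([pairs[pid][0] for pid in members], dtype=float)
        highs = np.array([pairs[pid][1] for pid in members], dtype=float)
        before = (lows, highs)[before_key]
        after = (lows, highs)[after_key]
        test = wilcoxon_signed_rank(before, after)
        return {
            **test,
            "n_members": len(members),
            "median_before": float(np.median(before)),
            "median_after": float(np.median(after)),
            "median_improvement": float(np.median(after) - np.median(before)),
        }

    # low_better: high-burden is 'before', low-burden 'after' (the improvement)
    low_better = _subgroup_stats("low_better", before_key=1, after_key=0)
    high_better = _subgroup_stats("high_better", before_key=0, after_key=1)

    best_f1s = np.array(
        [v["best_f1"] for v in per_participant.values() if v["best_f1"] is not None], dtype=float
    )
    counts = {g: sum(1 for x in assignment.values() if x == g) for g in ("low_better", "high_better", "tie", "incomparable")}
    n_total = len(pairs)
    report = {
        "per_participant": per_participant,
        "subgroup_counts": counts,
        "subgroup_pct": {g: (100.0 * c / n_total if n_total else 0.0) for g, c in counts.items()},
        "wilcoxon_low_better": low_better,
        "wilcoxon_high_better": high_better,
        "best_f1_mean": float(best_f1s.mean()) if len(best_f1s) else None,
        "best_f1_median": float(np.median(best_f1s)) if len(best_f1s) else None,
        "best_f1_sd": float(best_f1s.std(ddof=1)) if len(best_f1s) > 1 else None,
        "n_best_defined": int(len(best_f1s)),
        "caveat": SUBGROUP_CAVEAT,
    }
    return report


def base_rate_f1(labels) -> float | None:
    """F1 of the trivial always-positive predictor: 2p/(1+p) at prevalence p."""
    y = np.asarray(labels, dtype=int)
    if len(y) == 0:
        return None
    p = y.mean()
    if p == 0:
        return None  # no positives: recall undefined for any predictor
    return float(2 * p / (1 + p))
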