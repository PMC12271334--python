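"""Per-individual PPG vulnerability profiles.

A vulnerability profile expresses each feature's share of a fitted booster's
total gain (the loss reduction attributed to splits on that feature) as a
percentage, then aggregates features into interpretable categories (staples,
vegetable intake, hour of the day, ...).  A parallel profile from mean
absolute SHAP values is reported alongside — gain is a global quantity,
SHAP a per-prediction one, and the two need not agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .features import category_of
from .modeling import FitResult


@dataclass
class VulnerabilityProfile:
    """Normalized percent importance per feature and per category."""

    participant_id: str
    schema: str
    per_feature_pct: dict[str, float]
    per_category_pct: dict[str, float]
    ranking: list[str]  # categories, descending percent
    zero_gain: bool = False  # constant/fallback model: all-zero profile
    flavor: str = "gain"

    def top_k(self, k: int = 5) -> list[tuple[str, float]]:
        return [(c, self.per_category_pct[c]) for c in self.ranking[:k]]


def _normalize_and_rank(
    raw: dict[str, float], category_map: dict[str, str], pid: str, schema: str, flavor: str
) -> VulnerabilityProfile:
    total = sum(raw.values())
    zero = total <= 0
    pct = {f: (0.0 if zero else 100.0 * v / total) for f, v in raw.items()}
    cat_pct: dict[str, float] = {}
    for f, v in pct.items():
        c = category_of(f, category_map)
        cat_pct[c] = cat_pct.get(c, 0.0) + v
    ranking = sorted(cat_pct, key=lambda c: (-cat_pct[c], c))
    return VulnerabilityProfile(pid, schema, pct, cat_pct, ranking, zero_gain=zero, flavor=flavor)


def gain_profile(fit: FitResult, category_map: dict[str, str]) -> VulnerabilityProfile:
    """Total-gain importance normalized to percent contributions.

    Features never used in a split get 0.  A fallback (majority-class) model
    has no splits at all and yields an all-zero profile, flagged.
    """
    raw = {f: 0.0 for f in fit.feature_names}
    if fit.booster is not None:
        for f, g in fit.booster.get_score(importance_type="total_gain").items():
            raw[f] = float(g)
    return _normalize_and_rank(raw, category_map, fit.participant_id, fit.schema, "gain")


def shap_profile(fit: FitResult, X: pd.DataFrame, category_map: dict[str, str]) -> VulnerabilityProfile:
    """Mean |SHAP| per feature over the participant's rows, as percents.

    Uses the booster's built-in TreeSHAP (``pred_contribs``); the last
    contribution column is the bias and is excluded.
    """
    raw = {f: 0.0 for f in fit.feature_names}
    if fit.booster is not None:
        d = xgb.DMatrix(X[fit.feature_names], feature_names=fit.feature_names)
        contribs = fit.booster.predict(d, pred_contribs=True)
        mean_abs = np.abs(contribs[:, :-1]).mean(axis=0)
        for f, v in zip(fit.feature_names, mean_abs):
            raw[f] = float(v)
    return _normalize_and_rank(raw, category_map, fit.participant_id, fit.schema, "shap")


def cohort_heterogeneity(profiles: list[VulnerabilityProfile], top_k: int = 5) -> dict:
    """Cross-participant summary of category importances.

    Per category: mean, min, max percent and the share count (participants
    with percent > 0).  Also the top-k categories by mean percent and a
    distinctness check listing pairs of participants with identical category
    rankings.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    categories = sorted({c for p in profiles for c in p.per_category_pct})
    rows = []
    for c in categories:
        vals = np.array([p.per_category_pct.get(c, 0.0) for p in profiles])
        rows.append(
            {
                "category": c,
                "mean_pct": float(vals.mean()),
                "min_pct": float(vals.min()),
                "max_pct": float(vals.max()),
                "share_count": int((vals > 0).sum()),
                "n": len(profiles),
            }
        )
    table = pd.DataFrame(rows).sort_values("mean_pct", ascending=False, ignore_index=True)

    dup_pairs = []
    rankings = [tuple(p.ranking) for p in profiles]
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            if rankings[i] == rankings[j]:
                dup_pairs.append((profiles[i].participant_id, profiles[j].participant_id))
    return {
        "table": table,
        "top_categories": list(table["category"].head(top_k)),
        "duplicate_ranking_pairs": dup_pairs,
        "all_rankings_distinct": len(dup_pairs) == 0,
    }


def profiles_frame(profiles: list[VulnerabilityProfile]) -> pd.DataFrame:
    """Wide table: one row per participant, one column per category percent."""
    categories = sorted({c for p in profiles for c in p.per_category_pct})
    rows = []
    for p in profiles:
        row: dict[str, object] = {"participant_id": p.participant_id, "schema": p.schema, "flavor": p.flavor}
        for c in categories:
            row[c] = p.per_category_pct.get(c, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
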