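#!/usr/bin/env python
"""Summarize per-individual PPG vulnerability profiles and their diversity.

Reads the gain-based category-importance profiles written by
03_fit_and_evaluate.py, reports the top categories, their ranges and share
counts, checks profile distinctness across participants, and — because this
cohort is synthetic — scores how often the planted dominant driver is the
top-ranked category.
"""

import json
from pathlib import Path

import pandas as pd

from ppgv.synthetic import DRIVER_TO_CATEGORY

ROOT = Path(__file__).resolve().parents[1]
PIPE = ROOT / "results" / "pipeline"
TRUTH = ROOT / "scratch" / "cohort" / "truth.json"


def main() -> None:
    prof_path = PIPE / "profiles.csv"
    if not prof_path.exists():
        raise SystemExit("run analysis/03_fit_and_evaluate.py first")
    profiles = pd.read_csv(prof_path)
    het = pd.read_csv(PIPE / "heterogeneity.csv")

    print("Top 5 vulnerability categories by mean importance:")
    for _, row in het.head(5).iterrows():
        print(
            f"  {row['category']}: mean {row['mean_pct']:.1f}% "
            f"(range {row['min_pct']:.1f}-{row['max_pct']:.1f}%), shared by {row['share_count']}/{row['n']}"
        )

    cat_cols = [c for c in profiles.columns if c not in ("participant_id", "schema", "flavor")]
    rankings = profiles[cat_cols].apply(lambda r: tuple(r.sort_values(ascending=False).index), axis=1)
    n_dup = len(rankings) - rankings.nunique()
    print(f"identical category rankings across participants: {n_dup} duplicate(s) of {len(rankings)}")

    if TRUTH.exists():
        truths = {t["participant_id"]: t for t in json.loads(TRUTH.read_text())}
        hits = total = 0
        for _, row in profiles.iterrows():
            t = truths.get(row["participant_id"])
            if not t or not t["driver_weights"]:
                continue
            dom_key = max(t["driver_weights"], key=lambda k: t["driver_weights"][k])
            if t["driver_weights"][dom_key] == 0:
                continue
            total += 1
            top = max(cat_cols, key=lambda c: row[c])
            hits += top == DRIVER_TO_CATEGORY[dom_key]
        if total:
            print(f"planted dominant driver top-ranked for {hits}/{total} driver-bearing participants "
                  f"({100 * hits / total:.0f}%)")

    out = ROOT / "results" / "vulnerability_summary.csv"
    het.to_csv(out, index=False, float_format="%.4g")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
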