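#!/usr/bin/env python
"""Label each meal as a postprandial excursion (or not) and filter the cohort.

Reads the canonical cohort written by 01_simulate_cohort.py, computes every
meal's 2-h incremental AUC and expanding-mean personal baseline, applies the
eligibility filters (≥20 usable observations, both outcome classes present),
and writes observations.csv / exclusions.csv under results/.
"""

from pathlib import Path

from ppgv.core_io import read_canonical
from ppgv.labeling import apply_eligibility, label_participant, observations_frame

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    if not COHORT_DIR.is_dir():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    cohort = {}
    for d in sorted(p for p in COHORT_DIR.iterdir() if p.is_dir()):
        rec = read_canonical(d)
        cohort[rec.participant_id] = label_participant(rec)

    included, log = apply_eligibility(cohort)
    df = observations_frame(cohort)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "observations.csv", index=False, float_format="%.10g")
    import pandas as pd

    pd.DataFrame(log, columns=["participant_id", "reason"]).to_csv(RESULTS / "exclusions.csv", index=False)

    usable = df[df["usable"]]
    per_person = usable.groupby("participant_id").size()
    print(f"{len(cohort)} participants, {len(df)} meals, {len(usable)} usable PPG observations")
    print(f"usable per participant: mean {per_person.mean():.1f}, min {per_person.min()}, max {per_person.max()}")
    print(f"excursion rate among usable observations: {100 * usable['label'].mean():.1f}%")
    print(f"included {len(included)}, excluded {len(log)} ({[e['participant_id'] for e in log]})")


if __name__ == "__main__":
    main()
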