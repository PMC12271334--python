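#!/usr/bin/env python
"""Compare low- vs high-burden models per person (subgroups + signed-rank).

Reads results/pipeline/comparison.json (written by 03_fit_and_evaluate.py)
and reports subgroup sizes, the within-subgroup Wilcoxon signed-rank tests,
and the median F1 shift, writing a compact summary to
results/burden_comparison.md.
"""

import json
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
COMP = ROOT / "results" / "pipeline" / "comparison.json"


def main() -> None:
    if not COMP.exists():
        raise SystemExit("run analysis/03_fit_and_evaluate.py first")
    comp = json.loads(COMP.read_text())

    lines = ["# Low- vs high-burden model comparison", ""]
    counts = comp["subgroup_counts"]
    pct = comp["subgroup_pct"]
    for grp in ("low_better", "high_better", "tie", "incomparable"):
        lines.append(f"- {grp}: n = {counts[grp]} ({pct[grp]:.1f}%)")
    lines.append("")
    for grp, key in (("low-burden-better", "wilcoxon_low_better"), ("high-burden-better", "wilcoxon_high_better")):
        w = comp.get(key)
        if not w:
            lines.append(f"- {grp} subgroup empty; test omitted")
            continue
        lines.append(
            f"- {grp} subgroup (n = {w['n_members']}): median F1 "
            f"{100 * w['median_before']:.2f}% -> {100 * w['median_after']:.2f}% "
            f"(Z = {w['z']:.2f}, p = {w['p']:.2g}, non-zero pairs = {w['n']})"
        )
    lines += ["", comp["caveat"], ""]
    out = ROOT / "results" / "burden_comparison.md"
    out.write_text("\n".join(lines))
    print("\n".join(lines))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
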