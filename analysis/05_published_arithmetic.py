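#!/usr/bin/env python
"""Recompute the published aggregate arithmetic from its inputs.

Collapses the published fine-resolution event counts through the ethogram
hierarchy (sedentary / moving stalk / active / inactive aggregates) and
recomputes all per-behaviour accuracy differences and mean differences
between the two loggers from the published per-behaviour accuracies.
Writes results/published_arithmetic.json.
"""

import json
from pathlib import Path

from collaraccel.ethogram import collapse_counts, default_hierarchy
from collaraccel.evaluate import mean_difference
from collaraccel.studydata import CATEGORISATION_ACCURACY, FINE_EVENT_COUNTS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    h = default_hierarchy()
    out = {"aggregates": {}, "mean_differences": {}}
    for device, counts in FINE_EVENT_COUNTS.items():
        med = collapse_counts(counts, "medium", h)
        coa = collapse_counts(counts, "coarse", h)
        out["aggregates"][device] = {
            "sedentary": med["sedentary"],
            "moving stalk": med["moving stalk"],
            "active": coa["active"],
            "inactive": coa["inactive"],
        }
        print(f"{device}: sedentary {med['sedentary']:,}, moving stalk "
              f"{med['moving stalk']:,}, active {coa['active']:,}, "
              f"inactive {coa['inactive']:,}")
    for level, acc in CATEGORISATION_ACCURACY.items():
        diffs = {b: acc["CEFAS"][b] - acc["GCDC"][b] for b in acc["CEFAS"]}
        md = mean_difference(list(diffs.values()))
        out["mean_differences"][level] = round(md, 2)
        print(f"{level}-scale mean accuracy difference (CEFAS - GCDC): "
              f"{md:+.2f} pp over {len(diffs)} behaviours")
    path = ROOT / "results" / "published_arithmetic.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=2))
    print(f"-> {path}")


if __name__ == "__main__":
    main()
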