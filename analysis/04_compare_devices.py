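#!/usr/bin/env python
"""Per-behaviour device comparison on the synthetic experiment.

Reads the experiment report written by 03_train_and_evaluate.py and prints
the per-behaviour accuracy differences with their 2x2 test statistics
(Pearson chi-square, or Fisher's exact test for sparse tables), plus the
mean difference per resolution; a flat summary CSV goes to results/.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    report = json.loads(
        (ROOT / "results" / "experiment" / "report.json").read_text())
    frames = []
    for level, comp in report["comparisons"].items():
        df = pd.DataFrame(comp["table"])
        df.insert(0, "resolution", level)
        frames.append(df)
        print(f"\n{level}-scale comparison (CEFAS - GCDC, validation):")
        for row in comp["table"]:
            stat = (f"chi2={row['statistic']:.2f}" if row["test"] == "chi2"
                    else f"OR={row['statistic']:.2f}")
            print(f"  {row['behaviour']:16s} {row['percent_difference']:+6.1f}"
                  f" pp  {stat:12s} p={row['p']:.3f}  {row['verdict']}")
        print(f"  mean difference: {comp['mean_difference']:+.2f} pp")
    out = ROOT / "results" / "comparison_summary.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    print(f"\nsummary table -> {out}")


if __name__ == "__main__":
    main()
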