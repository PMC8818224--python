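#!/usr/bin/env python
"""Simulate one full exercise bout and record it through both loggers.

Writes a ground-truthed session to results/session/: one trace CSV per
device profile (30 Hz / ±2.3 g and 50 Hz / ±8.6 g / 0.001 g), the fine
behaviour-label intervals, and the session plan (with its seed), all
derived from a single 100 samples/s ideal recording.
"""

import argparse
from pathlib import Path

from collaraccel import io as caio
from collaraccel.pipeline import make_fixture

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--size", choices=["small", "full"], default="full")
    args = ap.parse_args()

    outdir = ROOT / "results" / "session"
    paths = make_fixture(outdir, size=args.size, seed=args.seed)
    labels = caio.read_labels_csv(paths["labels"])
    covered = (labels["end_s"] - labels["start_s"]).sum()
    print(f"simulated a {args.size} bout: {covered:.0f} s of labelled "
          f"behaviour over {len(labels)} segments "
          f"({labels['behaviour'].nunique()} distinct behaviours)")
    for key in ("CEFAS", "GCDC"):
        tr = caio.read_trace_csv(paths[key])
        print(f"  {key}: {len(tr)} samples at {tr.rate:.0f} samples/s "
              f"-> {paths[key]}")


if __name__ == "__main__":
    main()
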