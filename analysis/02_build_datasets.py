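#!/usr/bin/env python
"""Calibrate each logger's trace, derive the 14 predictor channels, and
attach behaviour labels.

Reads the session written by 01_simulate_session.py, corrects each trace
for the (simulated) non-centred collar mount using the leading rail
window, derives the per-sample feature frame, aligns the label intervals,
and drops unassignable rows. One labelled dataset CSV per device goes to
results/datasets/.
"""

from pathlib import Path

from collaraccel import io as caio
from collaraccel.calibrate import CalibrationReference, calibrate
from collaraccel.devicesim import builtin_profiles
from collaraccel.ethogram import align_labels, drop_unassignable
from collaraccel.features import derive_features

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    session = ROOT / "results" / "session"
    outdir = ROOT / "results" / "datasets"
    outdir.mkdir(parents=True, exist_ok=True)
    plan = caio.read_plan_yaml(session / "plan.yaml")
    intervals = caio.read_labels_csv(session / "labels.csv")
    ref = CalibrationReference(window=(0.5, plan.rail_window - 0.5))

    for device in builtin_profiles():
        trace = caio.read_trace_csv(
            session / f"trace_{device.name.lower()}.csv", device)
        corrected, corr = calibrate(trace, ref)
        feats = derive_features(corrected)
        feats["behaviour"] = align_labels(intervals, corrected).labels
        dataset, removed = drop_unassignable(feats)
        path = outdir / f"{device.name.lower()}.csv"
        dataset.to_csv(path, index=False)
        print(f"{device.name}: calibration residual "
              f"{corr.residual_angle:.3f} deg; {len(dataset)} labelled "
              f"events kept, {removed} unassignable removed -> {path}")


if __name__ == "__main__":
    main()
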