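"""Plain-text readers and writers for traces, labels, corrections, plans.

Formats:
  trace CSV   — header ``time_s,heave_g,surge_g,sway_g``, one file per device
  label CSV   — header ``start_s,end_s,behaviour``, half-open [start, end)
  correction  — one CSV row: nine rotation entries (row-major) + residual
  plan YAML   — seed (mandatory), rail_window, noise_sd, segments,
                optional mounting_offset (3x3 nested list)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import MountingCorrection
from .devicesim import AccelTrace, DeviceProfile, SessionPlan

TRACE_COLUMNS = ["time_s", "heave_g", "surge_g", "sway_g"]
LABEL_COLUMNS = ["start_s", "end_s", "behaviour"]


def write_trace_csv(trace: AccelTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_trace_csv(path, device: DeviceProfile | None = None) -> AccelTrace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing column(s): {missing}")
    return AccelTrace(time=df["time_s"].to_numpy(float),
                      heave=df["heave_g"].to_numpy(float),
                      surge=df["surge_g"].to_numpy(float),
                      sway=df["sway_g"].to_numpy(float),
                      device=device)


def write_labels_csv(intervals: pd.DataFrame, path) -> None:
    intervals[LABEL_COLUMNS].to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"label CSV missing column(s): {missing}")
    return df


def write_correction_csv(corr: MountingCorrection, path) -> None:
    flat = np.asarray(corr.rotation, float).ravel()
    cols = [f"r{i}{j}" for i in range(3) for j in range(3)]
    pd.DataFrame([list(flat) + [corr.residual_angle]],
                 columns=cols + ["residual_angle_deg"]).to_csv(path,
                                                              index=False)


def read_correction_csv(path) -> MountingCorrection:
    row = pd.read_csv(path).iloc[0]
    R = row[[f"r{i}{j}" for i in range(3) for j in range(3)]]
    return MountingCorrection(
        rotation=np.asarray(R, float).reshape(3, 3),
        residual_angle=float(row["residual_angle_deg"]))


def write_plan_yaml(plan: SessionPlan, path) -> None:
    doc = {
        "seed": int(plan.seed),
        "rail_window": float(plan.rail_window),
        "noise_sd": float(plan.noise_sd),
        "segments": [[name, float(dur)] for name, dur in plan.segments],
    }
    if plan.mounting_offset is not None:
        doc["mounting_offset"] = np.asarray(plan.mounting_offset,
                                            float).tolist()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_plan_yaml(path) -> SessionPlan:
    doc = yaml.safe_load(Path(path).read_text())
    if "seed" not in doc:
        raise ValueError("session plan file must state a seed")
    offset = doc.get("mounting_offset")
    return SessionPlan(
        segments=tuple((str(n), float(d)) for n, d in doc["segments"]),
        rail_window=float(doc.get("rail_window", 10.0)),
        mounting_offset=None if offset is None else np.asarray(offset, float),
        noise_sd=float(doc.get("noise_sd", 0.05)),
        seed=int(doc["seed"]))
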