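"""Per-sample predictor channels from a calibrated tri-axial trace.

Fourteen channels per logging event (one accelerometer sample):

====================  =========================================================
raw                   heave, surge, sway (g) as recorded
static                2-s centred rolling mean per axis — the gravity
                      (postural) component
dynamic               |raw − static| per axis — movement intensity
VeDBA                 Euclidean norm of the three dynamic components
VeSBA                 Euclidean norm of the three static components (≈1 g at
                      rest)
Anim.stat             angle (deg) between the static vector and the calibrated
                      resting orientation — postural deviation
pitch, roll           arcsin of static surge / sway against VeSBA (deg) —
                      nose-down tilt and lateral tilt
====================  =========================================================

Conventions: the rolling window is centred (no phase lag) with shrinking
edges; an upright stance (gravity entirely in heave) gives pitch = roll = 0,
and a head-to-ground posture with gravity in surge gives pitch = 90°.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .devicesim import AccelTrace

FEATURE_COLUMNS = [
    "heave", "surge", "sway",
    "static_heave", "static_surge", "static_sway",
    "dynamic_heave", "dynamic_surge", "dynamic_sway",
    "vedba", "vesba", "anim_stat", "pitch", "roll",
]

DEFAULT_REFERENCE = (1.0, 0.0, 0.0)  # resting orientation: gravity in heave


def rolling_static(signal: np.ndarray, rate: float,
                   window: float = 2.0) -> np.ndarray:
    """Centred rolling mean over ``window`` seconds (static acceleration).

    The window holds ``round(window * rate)`` samples, centred so sample i
    averages indices [i - n//2, i + (n-1)//2]; at the edges the window
    shrinks to the available samples.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    n = int(round(window * rate))
    if n < 2:
        raise ValueError("window must span >= 2 samples")
    lo = np.arange(len(signal)) - n // 2
    hi = np.arange(len(signal)) + (n - 1) // 2 + 1
    lo = np.clip(lo, 0, len(signal))
    hi = np.clip(hi, 0, len(signal))
    csum = np.concatenate([[0.0], np.cumsum(signal)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def dynamic_component(raw: np.ndarray, static: np.ndarray) -> np.ndarray:
    """|raw − static| per sample: the movement-driven residual, g."""
    raw = np.asarray(raw, float)
    static = np.asarray(static, float)
    if raw.shape != static.shape:
        raise ValueError("raw/static length mismatch")
    return np.abs(raw - static)


def _norm3(a, b, c) -> np.ndarray:
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    if not (a.shape == b.shape == c.shape):
        raise ValueError("axis series length mismatch")
    return np.sqrt(a * a + b * b + c * c)


def vedba(dyn_heave, dyn_surge, dyn_sway) -> np.ndarray:
    """Vectorial Dynamic Body Acceleration: per-sample norm of dynamics."""
    return _norm3(dyn_heave, dyn_surge, dyn_sway)


def vesba(static_heave, static_surge, static_sway) -> np.ndarray:
    """Vectorial Static Body Acceleration: per-sample norm of statics."""
    return _norm3(static_heave, static_surge, static_sway)


def pitch_roll(static_heave, static_surge, static_sway
               ) -> tuple[np.ndarray, np.ndarray]:
    """Postural pitch and roll, degrees, from the static vector.

    pitch = arcsin(static_surge / VeSBA); roll = arcsin(static_sway /
    VeSBA). Invariant to uniform scaling of the static vector; undefined
    where the static vector vanishes.
    """
    v = vesba(static_heave, static_surge, static_sway)
    if np.any(v <= 0):
        raise ValueError("zero static vector: pitch/roll undefined")
    pitch = np.degrees(np.arcsin(np.clip(
        np.asarray(static_surge, float) / v, -1.0, 1.0)))
    roll = np.degrees(np.arcsin(np.clip(
        np.asarray(static_sway, float) / v, -1.0, 1.0)))
    return pitch, roll


def anim_stat(static_heave, static_surge, static_sway,
              reference=DEFAULT_REFERENCE) -> np.ndarray:
    """Angle (deg) between the static vector and the resting orientation.

    The reference is the calibrated resting gravity direction (default
    +heave); 0° means the posture matches rest, 90° orthogonal.
    """
    v = vesba(static_heave, static_surge, static_sway)
    if np.any(v <= 0):
        raise ValueError("zero static vector: angle undefined")
    ref = np.asarray(reference, float)
    ref = ref / np.linalg.norm(ref)
    dots = (np.asarray(static_heave, float) * ref[0]
            + np.asarray(static_surge, float) * ref[1]
            + np.asarray(static_sway, float) * ref[2]) / v
    return np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))


def derive_features(trace: AccelTrace, window: float = 2.0,
                    reference=DEFAULT_REFERENCE) -> pd.DataFrame:
    """Full 14-channel predictor frame for a calibrated trace.

    Returns a DataFrame with ``time_s`` plus the 14 channels in
    FEATURE_COLUMNS order; one row per logging event.
    """
    rate = trace.rate
    if len(trace) < int(round(window * rate)):
        raise ValueError("trace shorter than one rolling window")
    stat = {ax: rolling_static(getattr(trace, ax), rate, window)
            for ax in ("heave", "surge", "sway")}
    dyn = {ax: dynamic_component(getattr(trace, ax), stat[ax])
           for ax in ("heave", "surge", "sway")}
    p, r = pitch_roll(stat["heave"], stat["surge"], stat["sway"])
    return pd.DataFrame({
        "time_s": trace.time,
        "heave": trace.heave, "surge": trace.surge, "sway": trace.sway,
        "static_heave": stat["heave"], "static_surge": stat["surge"],
        "static_sway": stat["sway"],
        "dynamic_heave": dyn["heave"], "dynamic_surge": dyn["surge"],
        "dynamic_sway": dyn["sway"],
        "vedba": vedba(dyn["heave"], dyn["surge"], dyn["sway"]),
        "vesba": vesba(stat["heave"], stat["surge"], stat["sway"]),
        "anim_stat": anim_stat(stat["heave"], stat["surge"], stat["sway"],
                               reference),
        "pitch": p, "roll": r,
    })
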