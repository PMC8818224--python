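"""Mounting-orientation calibration from a static rail-reference window.

Before deployment the collar hangs on a rail with the logger at the bottom,
so the true gravity direction during that window is known (+heave by
convention). A non-centred mount shows up as the window's mean acceleration
pointing elsewhere; the correction is the minimal (axis-angle) rotation
taking that mean onto the expected gravity direction. Rotation only — both
logger models report in calibrated g, so no per-axis gain or bias is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .devicesim import AccelTrace

_DEFAULT_GRAVITY = np.array([1.0, 0.0, 0.0])  # +heave


@dataclass(frozen=True)
class CalibrationReference:
    """A static interval with known gravity direction.

    window is (start_s, end_s) within the trace; expected_gravity is the
    unit gravity direction in device axes during that interval (default
    +heave: collar hanging).
    """

    window: tuple[float, float]
    expected_gravity: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.window[1] - self.window[0] < 4.0:
            raise ValueError("reference window must span >= 4 s")
        if not np.isclose(np.linalg.norm(self.expected_gravity), 1.0,
                          atol=1e-6):
            raise ValueError("expected_gravity must be a unit vector")


@dataclass(frozen=True)
class MountingCorrection:
    """A rigid rotation correcting for non-centred collar mounting."""

    rotation: np.ndarray
    residual_angle: float  # degrees, after correction

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        if self.residual_angle < 0:
            raise ValueError("residual_angle must be >= 0")


def minimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Smallest-angle rotation taking unit vector src onto unit vector dst.

    Rodrigues form about axis src x dst; antiparallel inputs rotate 180°
    about an arbitrary perpendicular axis.
    """
    src = np.asarray(src, float) / np.linalg.norm(src)
    dst = np.asarray(dst, float) / np.linalg.norm(dst)
    c = float(np.dot(src, dst))
    axis = np.cross(src, dst)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: any perpendicular axis works
        perp = np.cross(src, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(src, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        k = np.array([[0, -perp[2], perp[1]], [perp[2], 0, -perp[0]],
                      [-perp[1], perp[0], 0]])
        return np.eye(3) + 2.0 * (k @ k)
    axis = axis / s
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two 3-vectors, degrees."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def estimate_correction(trace: AccelTrace,
                        ref: CalibrationReference) -> MountingCorrection:
    """Estimate the mounting correction from the reference window.

    Averages the acceleration vector over the window (noise and any slight
    sway average out over >= 2 s) and returns the minimal rotation mapping
    that mean onto the expected gravity direction.
    """
    start, end = ref.window
    mask = (trace.time >= start) & (trace.time < end)
    if mask.sum() < 2 * trace.rate:
        raise ValueError("reference window contains < 2 s of samples")
    mean_vec = trace.as_matrix()[mask].mean(axis=0)
    if np.linalg.norm(mean_vec) < 0.5:
        raise ValueError(
            "reference window not static: mean magnitude "
            f"{np.linalg.norm(mean_vec):.3f} g < 0.5 g")
    g = np.asarray(ref.expected_gravity, float)
    R = minimal_rotation(mean_vec, g)
    residual = angle_between(R @ mean_vec, g)
    return MountingCorrection(rotation=R, residual_angle=residual)


def apply_correction(trace: AccelTrace,
                     corr: MountingCorrection) -> AccelTrace:
    """Rotate every sample vector by the correction; time grid unchanged."""
    m = trace.as_matrix() @ np.asarray(corr.rotation).T
    return trace.with_matrix(m)


def calibrate(trace: AccelTrace, ref: CalibrationReference
              ) -> tuple[AccelTrace, MountingCorrection]:
    """Estimate and apply the mounting correction in one step."""
    corr = estimate_correction(trace, ref)
    return apply_correction(trace, corr), corr
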