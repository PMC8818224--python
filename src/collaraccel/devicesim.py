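"""Synthetic collar-accelerometer sessions with known ground truth.

Generates tri-axial (heave, surge, sway) acceleration traces for a captive
exercise bout: a leading "rail" reference window (collar hung on a rail for
calibration), followed by behaviour segments drawn from a 17-class ethogram
of a cursorial felid (sedentary postures, stalks, the four gaits, pounce,
head movement, and a rag-bag "other").

The signal model is posture + gait + noise:

* a static component, gravity (1 g) projected onto the behaviour's
  characteristic collar orientation;
* a dynamic component; for gaits, a train of per-limb raised-cosine contact
  impulses locked to the stride cycle (walk 4-beat, trot 2-beat diagonal,
  canter 3-beat, gallop 4-beat with suspensions), dominating heave with
  smaller surge/sway components whose signs alternate with limb side; for
  non-gait movement (head movement, "other"), band-limited random wobble;
* additive i.i.d. Gaussian sensor noise per axis.

Ideal traces are generated on a fine 100 samples/s grid; ``apply_device``
then records them through a logger profile (resampling, range clipping,
amplitude quantisation), so several loggers can observe one ground truth —
mirroring a dual-logger collar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

IDEAL_RATE = 100.0
"""Sampling rate (samples/s) of ideal, pre-device traces."""

UNASSIGNABLE = "unassignable"
"""Sentinel label for samples whose behaviour is unknown (e.g. rail window)."""

_AXES = ("heave", "surge", "sway")


@dataclass(frozen=True)
class DeviceProfile:
    """Operational envelope of an accelerometer data logger.

    Parameters
    ----------
    name : str
        Logger identifier.
    sampling_rate : float
        Recording frequency, samples/s.
    max_accel : float
        Symmetric measurable range, g; samples are clipped to ±max_accel.
        Must exceed 1 g so gravity itself is measurable.
    resolution : float
        Amplitude quantisation step, g per count; 0 means continuous.
    """

    name: str
    sampling_rate: float
    max_accel: float
    resolution: float = 0.0
    axis_order: tuple[str, str, str] = _AXES

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.max_accel <= 1.0:
            raise ValueError("max_accel must exceed 1 g (gravity)")
        if self.resolution < 0:
            raise ValueError("resolution must be >= 0")


def builtin_profiles() -> tuple[DeviceProfile, DeviceProfile]:
    """Return the two study logger presets.

    The lower-capacity logger (``CEFAS``: 30 samples/s, ±2.3 g, effectively
    continuous amplitude) and the higher-capacity one (``GCDC``: 50
    samples/s, ±8.6 g, 0.001 g resolution).
    """
    cefas = DeviceProfile(name="CEFAS", sampling_rate=30.0, max_accel=2.3,
                          resolution=0.0)
    gcdc = DeviceProfile(name="GCDC", sampling_rate=50.0, max_accel=8.6,
                         resolution=0.001)
    return cefas, gcdc


@dataclass(frozen=True)
class Footfall:
    """One limb contact within a stride cycle.

    phase is the contact onset as a fraction of the cycle in [0, 1);
    duration is the contact length as a fraction of the cycle.
    """

    limb: str
    phase: float
    duration: float


@dataclass(frozen=True)
class BehaviourSpec:
    """Signal-model parameters for one ethogram behaviour.

    static_orientation is the unit gravity direction in device axes
    (heave, surge, sway) characteristic of the posture; dynamic_amplitude
    scales the movement component (g); stride_rate is strides/s for gaits
    (0 for non-gait behaviours, in which case footfall_pattern is empty and
    any dynamic amplitude is realised as low-frequency wobble).
    """

    name: str
    static_orientation: tuple[float, float, float]
    dynamic_amplitude: float
    stride_rate: float = 0.0
    footfall_pattern: tuple[Footfall, ...] = ()
    duration_range: tuple[float, float] = (5.0, 30.0)

    def __post_init__(self) -> None:
        if self.dynamic_amplitude < 0:
            raise ValueError("dynamic_amplitude must be >= 0")
        if (self.stride_rate == 0) != (len(self.footfall_pattern) == 0):
            raise ValueError(
                "stride_rate == 0 iff footfall_pattern is empty")
        n = np.linalg.norm(self.static_orientation)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("static_orientation must be a unit vector")


@dataclass(frozen=True)
class SessionPlan:
    """Ordered behaviour schedule for one simulated exercise bout.

    segments are (behaviour name, duration s) pairs; rail_window is the
    leading calibration interval (s) during which the collar hangs on a
    rail; mounting_offset, if given, is a 3x3 rotation applied to the whole
    recorded trace to emulate a non-centred collar mount.
    """

    segments: tuple[tuple[str, float], ...]
    rail_window: float = 10.0
    mounting_offset: np.ndarray | None = None
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.segments):
            raise ValueError("segment durations must be > 0")
        if self.rail_window < 4.0:
            raise ValueError(
                "rail_window must be >= 4 s (two rolling windows)")

    @property
    def duration(self) -> float:
        return self.rail_window + sum(d for _, d in self.segments)


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration in g.

    Attributes
    ----------
    time : ndarray
        Sample times, s; strictly increasing uniform grid.
    heave, surge, sway : ndarray
        Per-axis acceleration, g (vertical, longitudinal, transverse).
    device : DeviceProfile or None
        Profile the trace was recorded through; None for ideal traces.
    """

    time: np.ndarray
    heave: np.ndarray
    surge: np.ndarray
    sway: np.ndarray
    device: DeviceProfile | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for ax in _AXES:
            if len(getattr(self, ax)) != n:
                raise ValueError("axis length mismatch with time grid")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def rate(self) -> float:
        if len(self.time) < 2:
            raise ValueError("rate undefined for traces of < 2 samples")
        return 1.0 / (self.time[1] - self.time[0])

    def as_matrix(self) -> np.ndarray:
        """Samples as an (n, 3) array in (heave, surge, sway) order."""
        return np.column_stack([self.heave, self.surge, self.sway])

    def with_matrix(self, m: np.ndarray) -> "AccelTrace":
        return AccelTrace(time=self.time.copy(), heave=m[:, 0].copy(),
                          surge=m[:, 1].copy(), sway=m[:, 2].copy(),
                          device=self.device)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "heave_g": self.heave,
                             "surge_g": self.surge, "sway_g": self.sway})


@dataclass
class LabelTrack:
    """Per-sample behaviour labels at a stated ethogram resolution."""

    labels: np.ndarray
    level: str = "fine"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)


def _unit(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    return tuple(a / np.linalg.norm(a))


# Footfall patterns over one stride cycle: contact onset phase and contact
# duration as fractions of the cycle. Left/right distinguished so lateral
# (sway) components can alternate sign.
_WALK = (Footfall("LH", 0.00, 0.6), Footfall("LF", 0.25, 0.6),
         Footfall("RH", 0.50, 0.6), Footfall("RF", 0.75, 0.6))
_TROT = (Footfall("LF", 0.00, 0.40), Footfall("RH", 0.00, 0.40),
         Footfall("RF", 0.50, 0.40), Footfall("LH", 0.50, 0.40))
_CANTER = (Footfall("RH", 0.00, 0.35), Footfall("LH", 0.30, 0.35),
           Footfall("RF", 0.30, 0.35), Footfall("LF", 0.60, 0.35))
_GALLOP = (Footfall("RH", 0.00, 0.22), Footfall("LH", 0.12, 0.22),
           Footfall("RF", 0.50, 0.22), Footfall("LF", 0.62, 0.22))
_POUNCE = (Footfall("LH", 0.0, 0.30), Footfall("RH", 0.0, 0.30),
           Footfall("LF", 0.45, 0.25), Footfall("RF", 0.45, 0.25))

_UPRIGHT = (1.0, 0.0, 0.0)          # gravity along +heave
_HEAD_DOWN = _unit((0.87, 0.5, 0))  # stalking: collar pitched nose-down
_DEEP_STALK = _unit((0.75, 0.66, 0))
_SIT = _unit((0.93, -0.37, 0))      # anterior upright, collar tipped back
_LIE = _unit((0.45, 0.1, 0.89))     # lateral surface down: gravity in sway
_CROUCH = _unit((0.92, 0.39, 0))


def default_behaviour_specs() -> dict[str, BehaviourSpec]:
    """Signal specs for the 17 fine ethogram behaviours.

    Dynamic amplitudes are ordered lie < stand < walk < trot < canter <
    gallop, so neighbouring gaits genuinely overlap once sensor noise is
    added; stalking variants share their parent posture/gait with a
    pitched-down collar orientation and reduced amplitude. Stride rates
    and amplitudes are stated modelling assumptions, not measurements.
    """
    s = [
        BehaviourSpec("lie", _LIE, 0.0, duration_range=(10, 60)),
        BehaviourSpec("sit", _SIT, 0.005, duration_range=(5, 40)),
        BehaviourSpec("crouch", _CROUCH, 0.01, duration_range=(4, 20)),
        BehaviourSpec("stand", _UPRIGHT, 0.015, duration_range=(4, 30)),
        BehaviourSpec("head movement", _unit((0.97, 0.26, 0)), 0.12,
                      duration_range=(2, 10)),
        BehaviourSpec("crouching stalk", _DEEP_STALK, 0.02,
                      duration_range=(3, 15)),
        BehaviourSpec("lying stalk", _unit((0.5, 0.35, 0.79)), 0.012,
                      duration_range=(5, 40)),
        BehaviourSpec("sitting stalk", _unit((0.85, 0.15, -0.5)), 0.015,
                      duration_range=(3, 15)),
        BehaviourSpec("standing stalk", _HEAD_DOWN, 0.02,
                      duration_range=(3, 20)),
        BehaviourSpec("walking stalk", _HEAD_DOWN, 0.18, stride_rate=0.9,
                      footfall_pattern=_WALK, duration_range=(3, 15)),
        BehaviourSpec("trotting stalk", _HEAD_DOWN, 0.45, stride_rate=1.6,
                      footfall_pattern=_TROT, duration_range=(3, 10)),
        BehaviourSpec("walk", _UPRIGHT, 0.25, stride_rate=1.0,
                      footfall_pattern=_WALK, duration_range=(4, 30)),
        BehaviourSpec("trot", _UPRIGHT, 0.6, stride_rate=1.8,
                      footfall_pattern=_TROT, duration_range=(3, 15)),
        BehaviourSpec("canter", _UPRIGHT, 1.4, stride_rate=2.2,
                      footfall_pattern=_CANTER, duration_range=(3, 12)),
        BehaviourSpec("gallop", _UPRIGHT, 3.2, stride_rate=2.8,
                      footfall_pattern=_GALLOP, duration_range=(3, 12)),
        BehaviourSpec("pounce", _unit((0.8, 0.6, 0)), 2.2, stride_rate=1.4,
                      footfall_pattern=_POUNCE, duration_range=(0.5, 1.5)),
        BehaviourSpec("other", _unit((0.99, 0.1, 0.1)), 0.3,
                      duration_range=(2, 10)),
    ]
    return {b.name: b for b in s}


def _raised_cosine_train(t: np.ndarray, spec: BehaviourSpec,
                         rng: np.random.Generator) -> np.ndarray:
    """Dynamic (n, 3) gait component: per-limb contact impulses.

    Each limb contact contributes a raised-cosine impulse over its contact
    interval, dominating heave; surge gets a differentiated (push-off)
    component, and sway an impulse whose sign follows limb side.
    """
    cycle = np.mod(t * spec.stride_rate, 1.0)
    dyn = np.zeros((len(t), 3))
    amp = spec.dynamic_amplitude
    for ff in spec.footfall_pattern:
        # phase distance from contact onset, wrapped to [0, 1)
        d = np.mod(cycle - ff.phase, 1.0)
        in_contact = d < ff.duration
        x = np.where(in_contact, d / ff.duration, 0.0)  # 0..1 over contact
        pulse = 0.5 * (1.0 - np.cos(2 * np.pi * x)) * in_contact
        side = -1.0 if ff.limb.startswith("L") else 1.0
        fore = 1.0 if ff.limb.endswith("F") else -1.0
        dyn[:, 0] += amp * pulse
        dyn[:, 1] += 0.45 * amp * fore * np.sin(2 * np.pi * x) * in_contact
        dyn[:, 2] += 0.3 * amp * side * pulse
    # small stride-to-stride irregularity so cycles are not bit-identical
    jitter = rng.normal(0.0, 0.03 * amp, size=dyn.shape) if amp > 0 else 0.0
    return dyn + jitter


def _wobble(t: np.ndarray, amplitude: float,
            rng: np.random.Generator) -> np.ndarray:
    """Band-limited random wobble (n, 3) with per-axis RMS ≈ amplitude.

    Smoothed white noise (≈1.5 Hz corner) models non-periodic movement such
    as head movement or miscellaneous activity.
    """
    if amplitude == 0:
        return np.zeros((len(t), 3))
    raw = rng.normal(0.0, 1.0, size=(len(t) + 60, 3))
    kernel = np.hanning(31)
    kernel /= kernel.sum()
    sm = np.apply_along_axis(lambda c: np.convolve(c, kernel, "same"), 0, raw)
    sm = sm[30:30 + len(t)]
    rms = np.sqrt(np.mean(sm**2, axis=0))
    sm = sm / np.where(rms > 0, rms, 1.0) * amplitude
    # movement wobble is strongest along heave/surge (neck nodding)
    return sm * np.array([1.0, 0.8, 0.5])


def simulate_segment(spec: BehaviourSpec, duration: float,
                     rate: float = IDEAL_RATE, noise_sd: float = 0.05,
                     seed: int | np.random.Generator = 0) -> AccelTrace:
    """Simulate one behaviour segment as an ideal (unclipped) trace.

    Output = gravity projected onto the spec's static orientation, plus the
    behaviour's dynamic component (footfall train for gaits, wobble
    otherwise), plus i.i.d. Gaussian noise of sd ``noise_sd`` per axis.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    static = np.outer(np.ones(n), np.asarray(spec.static_orientation))
    if spec.stride_rate > 0:
        dyn = _raised_cosine_train(t, spec, rng)
    else:
        dyn = _wobble(t, spec.dynamic_amplitude, rng)
    noise = (rng.normal(0.0, noise_sd, size=(n, 3)) if noise_sd > 0
             else np.zeros((n, 3)))
    m = static + dyn + noise
    return AccelTrace(time=t, heave=m[:, 0], surge=m[:, 1], sway=m[:, 2])


def rotation_about(axis: str | np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a named device axis or arbitrary 3-vector."""
    if isinstance(axis, str):
        axis = {"heave": [1, 0, 0], "surge": [0, 1, 0],
                "sway": [0, 0, 1]}[axis]
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    th = np.deg2rad(angle_deg)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def plan_intervals(plan: SessionPlan) -> pd.DataFrame:
    """Half-open behaviour intervals [start, end) implied by a plan.

    The rail window is not included (it is unassignable by construction).
    """
    rows = []
    t0 = plan.rail_window
    for name, dur in plan.segments:
        rows.append({"start_s": t0, "end_s": t0 + dur, "behaviour": name})
        t0 += dur
    return pd.DataFrame(rows, columns=["start_s", "end_s", "behaviour"])


def compose_session(plan: SessionPlan, specs: dict[str, BehaviourSpec],
                    rate: float = IDEAL_RATE) -> tuple[AccelTrace, LabelTrack]:
    """Assemble a full session: rail reference window + behaviour segments.

    The rail window has gravity along +heave (collar hanging) and zero
    dynamics; the plan's mounting offset rotation is then applied to the
    whole trace, so the recorded rail direction reveals the offset. The
    label track marks the rail window as unassignable. Deterministic in
    (plan, specs): the plan's seed drives all randomness.
    """
    if not plan.segments:
        raise ValueError("session plan has no segments")
    missing = [n for n, _ in plan.segments if n not in specs]
    if missing:
        raise KeyError(f"no behaviour spec for label(s): {missing}")
    rng = np.random.default_rng(plan.seed)
    rail_spec = BehaviourSpec("rail", _UPRIGHT, 0.0)
    parts = [simulate_segment(rail_spec, plan.rail_window, rate,
                              plan.noise_sd, rng)]
    labels = [np.full(len(parts[0]), UNASSIGNABLE, dtype=object)]
    for name, dur in plan.segments:
        seg = simulate_segment(specs[name], dur, rate, plan.noise_sd, rng)
        parts.append(seg)
        labels.append(np.full(len(seg), name, dtype=object))
    m = np.vstack([p.as_matrix() for p in parts])
    if plan.mounting_offset is not None:
        R = np.asarray(plan.mounting_offset, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("mounting_offset must be orthonormal")
        m = m @ R.T
    n = len(m)
    trace = AccelTrace(time=np.arange(n) / rate, heave=m[:, 0],
                       surge=m[:, 1], sway=m[:, 2])
    return trace, LabelTrack(np.concatenate(labels), level="fine")


def apply_device(trace: AccelTrace, device: DeviceProfile) -> AccelTrace:
    """Record an ideal trace through a logger profile.

    Resamples to the device rate by linear interpolation on the uniform
    grid, clips each axis to ±max_accel, then (if resolution > 0) rounds to
    the nearest multiple of the resolution. Idempotent for a fixed profile.
    """
    src_rate = trace.rate
    if src_rate < device.sampling_rate - 1e-9:
        raise ValueError(
            f"ideal rate {src_rate:g} < device rate "
            f"{device.sampling_rate:g}; upsampling not supported")
    t0, t1 = trace.time[0], trace.time[-1]
    n_out = int(np.floor((t1 - t0) * device.sampling_rate)) + 1
    t_new = t0 + np.arange(n_out) / device.sampling_rate
    out = {}
    for ax in _AXES:
        y = np.interp(t_new, trace.time, getattr(trace, ax))
        y = np.clip(y, -device.max_accel, device.max_accel)
        if device.resolution > 0:
            y = np.round(y / device.resolution) * device.resolution
        out[ax] = y
    return AccelTrace(time=t_new, device=device, **out)


def saturation_fraction(trace: AccelTrace, max_accel: float | None = None
                        ) -> float:
    """Fraction of samples with any axis at or beyond the clip bound."""
    if max_accel is None:
        if trace.device is None:
            raise ValueError("no device profile on trace; pass max_accel")
        max_accel = trace.device.max_accel
    m = np.abs(trace.as_matrix())
    return float(np.mean(np.any(m >= max_accel - 1e-12, axis=1)))
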