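"""Simulator contracts: device presets, gait spectra, session assembly,
and logger recording (resampling, clipping, quantisation)."""

import numpy as np
import pytest

from collaraccel.devicesim import (IDEAL_RATE, UNASSIGNABLE, AccelTrace,
                                   BehaviourSpec, DeviceProfile, SessionPlan,
                                   apply_device, builtin_profiles,
                                   compose_session, default_behaviour_specs,
                                   plan_intervals, rotation_about,
                                   saturation_fraction, simulate_segment)


def dominant_frequency(signal, rate):
    """Independent FFT oracle: frequency of the largest non-DC peak."""
    x = np.asarray(signal) - np.mean(signal)
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
    return freqs[np.argmax(spec)]


class TestProfiles:
    def test_builtin_presets_match_logger_specs(self):
        cefas, gcdc = builtin_profiles()
        assert cefas.sampling_rate == 30 and cefas.max_accel == 2.3
        assert cefas.resolution == 0
        assert gcdc.sampling_rate == 50 and gcdc.max_accel == 8.6
        assert gcdc.resolution == 0.001

    @pytest.mark.parametrize("kwargs", [
        dict(sampling_rate=0, max_accel=2.0),
        dict(sampling_rate=30, max_accel=0.9),
        dict(sampling_rate=30, max_accel=2.0, resolution=-0.1),
    ])
    def test_invalid_profiles_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DeviceProfile(name="bad", **kwargs)


class TestSimulateSegment:
    def test_zero_dynamics_yields_pure_gravity_projection(self, specs):
        lie = specs["lie"]
        tr = simulate_segment(lie, 5.0, 100.0, noise_sd=0.0, seed=1)
        m = tr.as_matrix()
        assert np.allclose(m, np.asarray(lie.static_orientation), atol=1e-12)
        assert np.allclose(m.var(axis=0), 0.0)

    def test_standing_mean_is_one_g_in_heave(self, specs):
        tr = simulate_segment(specs["stand"], 10.0, 100.0, noise_sd=0.02,
                              seed=2)
        assert tr.heave.mean() == pytest.approx(1.0, abs=0.02)
        assert tr.surge.mean() == pytest.approx(0.0, abs=0.02)
        assert tr.sway.mean() == pytest.approx(0.0, abs=0.02)

    @pytest.mark.parametrize("gait", ["walk", "trot", "canter", "gallop"])
    def test_gait_spectral_peak_at_stride_rate(self, specs, gait):
        spec = specs[gait]
        tr = simulate_segment(spec, 10.0, 100.0, noise_sd=0.0, seed=3)
        f = dominant_frequency(tr.heave, 100.0)
        # peak may sit at the stride rate or a footfall harmonic; the
        # fundamental must be within 5% of a multiple of the stride rate
        ratio = f / spec.stride_rate
        assert abs(ratio - round(ratio)) < 0.05
        assert round(ratio) >= 1

    def test_gaits_have_distinct_dominant_frequencies(self, specs):
        # dominant peaks sit at footfall harmonics of the stride rate, so
        # each gait leaves a distinguishable spectral signature
        freqs = []
        for gait in ("walk", "trot", "canter", "gallop"):
            tr = simulate_segment(specs[gait], 20.0, 100.0, 0.0, seed=4)
            freqs.append(dominant_frequency(tr.heave, 100.0))
        for i in range(len(freqs)):
            for j in range(i + 1, len(freqs)):
                assert abs(freqs[i] - freqs[j]) > 0.2

    def test_spectral_peak_survives_50hz_recording(self, specs):
        # Nyquist: stride structure below 25 strides/s must survive the
        # higher-rate logger's resampling
        spec = specs["gallop"]
        ideal = simulate_segment(spec, 10.0, 100.0, noise_sd=0.0, seed=5)
        _, gcdc = builtin_profiles()
        rec = apply_device(ideal, gcdc)
        f_ideal = dominant_frequency(ideal.heave, 100.0)
        f_rec = dominant_frequency(rec.heave, gcdc.sampling_rate)
        assert f_rec == pytest.approx(f_ideal, rel=0.05)


class TestBehaviourSpecs:
    def test_all_seventeen_fine_behaviours_present(self, specs):
        assert len(specs) == 17
        assert {"lie", "gallop", "pounce", "other",
                "head movement"} <= set(specs)

    def test_amplitudes_ordered_by_intensity(self, specs):
        order = ["lie", "stand", "walk", "trot", "canter", "gallop"]
        amps = [specs[b].dynamic_amplitude for b in order]
        assert amps == sorted(amps)

    def test_gait_iff_footfalls(self, specs):
        for b in specs.values():
            assert (b.stride_rate == 0) == (len(b.footfall_pattern) == 0)
        with pytest.raises(ValueError):
            BehaviourSpec("bad", (1, 0, 0), 0.1, stride_rate=1.0)


class TestComposeSession:
    def test_length_arithmetic(self, specs):
        plan = SessionPlan(segments=(("lie", 60.0),), rail_window=10.0,
                           noise_sd=0.0, seed=0)
        trace, labels = compose_session(plan, specs, rate=30.0)
        assert len(trace) == 2100
        assert int(np.sum(labels.labels == "lie")) == 1800
        assert int(np.sum(labels.labels == UNASSIGNABLE)) == 300

    def test_trace_and_labels_always_aligned(self, small_session):
        _, trace, labels = small_session
        assert len(trace) == len(labels)

    def test_seeded_determinism_bit_identical(self, specs):
        plan = SessionPlan(segments=(("walk", 5.0), ("gallop", 3.0)),
                           rail_window=4.0, seed=7)
        t1, l1 = compose_session(plan, specs)
        t2, l2 = compose_session(plan, specs)
        assert t1.as_matrix().tobytes() == t2.as_matrix().tobytes()
        assert list(l1.labels) == list(l2.labels)

    def test_identity_offset_preserves_canonical_gravity(self, specs):
        plan = SessionPlan(segments=(("stand", 20.0),), rail_window=4.0,
                           mounting_offset=np.eye(3), noise_sd=0.0, seed=1)
        trace, labels = compose_session(plan, specs)
        seg = trace.as_matrix()[np.asarray(labels.labels) == "stand"]
        # stand carries a small wobble; its smoothed mean is only
        # approximately zero over a finite segment
        assert np.allclose(seg.mean(axis=0), [1.0, 0.0, 0.0], atol=0.01)
        # the zero-amplitude posture matches the projection exactly
        plan0 = SessionPlan(segments=(("lie", 10.0),), rail_window=4.0,
                            mounting_offset=np.eye(3), noise_sd=0.0, seed=1)
        tr0, l0 = compose_session(plan0, specs)
        seg0 = tr0.as_matrix()[np.asarray(l0.labels) == "lie"]
        assert np.allclose(
            seg0.mean(axis=0),
            np.asarray(specs["lie"].static_orientation), atol=1e-9)

    def test_mounting_offset_rotates_rail_gravity(self, specs):
        R = rotation_about("sway", 30.0)
        plan = SessionPlan(segments=(("lie", 5.0),), rail_window=4.0,
                           mounting_offset=R, noise_sd=0.0, seed=1)
        trace, labels = compose_session(plan, specs)
        rail = trace.as_matrix()[np.asarray(labels.labels) == UNASSIGNABLE]
        assert np.allclose(rail.mean(axis=0), R @ [1.0, 0.0, 0.0],
                           atol=1e-9)

    def test_empty_plan_rejected(self, specs):
        plan = SessionPlan(segments=(), rail_window=4.0)
        with pytest.raises(ValueError):
            compose_session(plan, specs)

    def test_unknown_behaviour_named_in_error(self, specs):
        plan = SessionPlan(segments=(("moonwalk", 5.0),), rail_window=4.0)
        with pytest.raises(KeyError, match="moonwalk"):
            compose_session(plan, specs)

    def test_plan_intervals_are_half_open_and_contiguous(self, specs):
        plan = SessionPlan(segments=(("lie", 5.0), ("walk", 3.0)),
                           rail_window=4.0)
        iv = plan_intervals(plan)
        assert iv["start_s"].tolist() == [4.0, 9.0]
        assert iv["end_s"].tolist() == [9.0, 12.0]


class TestApplyDevice:
    def _trace(self, values, rate=100.0):
        v = np.asarray(values, float)
        t = np.arange(len(v)) / rate
        return AccelTrace(time=t, heave=v, surge=np.zeros_like(v),
                          sway=np.zeros_like(v))

    def test_clipping_at_low_capacity_bound(self):
        cefas, _ = builtin_profiles()
        tr = self._trace(np.full(200, 5.0))
        rec = apply_device(tr, cefas)
        assert np.allclose(rec.heave, 2.3)

    def test_within_range_identity(self):
        cefas, _ = builtin_profiles()
        tr = self._trace(np.full(200, 0.8))
        rec = apply_device(tr, cefas)
        assert np.allclose(rec.heave, 0.8)

    def test_quantisation_to_nearest_resolution_multiple(self):
        _, gcdc = builtin_profiles()
        tr = self._trace(np.full(200, 0.0014))
        rec = apply_device(tr, gcdc)
        assert np.allclose(rec.heave, 0.001)
        # every recorded value is an integer multiple of the resolution
        k = rec.heave / gcdc.resolution
        assert np.allclose(k, np.round(k), atol=1e-9)

    def test_idempotence(self, specs):
        tr = simulate_segment(specs["gallop"], 6.0, 100.0, 0.05, seed=9)
        for dev in builtin_profiles():
            once = apply_device(tr, dev)
            twice = apply_device(once, dev)
            assert np.allclose(once.as_matrix(), twice.as_matrix(),
                               atol=1e-12)
            assert np.allclose(once.time, twice.time)

    def test_no_upsampling(self):
        _, gcdc = builtin_profiles()
        tr = self._trace(np.zeros(100), rate=30.0)
        with pytest.raises(ValueError, match="upsampling"):
            apply_device(tr, gcdc)

    def test_clipping_fraction_monotone_in_capacity(self, specs):
        cefas, gcdc = builtin_profiles()
        tr = simulate_segment(specs["gallop"], 10.0, 100.0, 0.05, seed=10)
        frac_low = saturation_fraction(apply_device(tr, cefas))
        frac_high = saturation_fraction(apply_device(tr, gcdc))
        assert frac_low >= frac_high
        assert frac_low > 0  # galloping drives the low-capacity logger
        # into saturation

    def test_resampling_matches_interp_oracle(self, specs):
        cefas, _ = builtin_profiles()
        tr = simulate_segment(specs["walk"], 4.0, 100.0, 0.0, seed=11)
        rec = apply_device(tr, cefas)
        t_expect = np.arange(len(rec)) / 30.0
        oracle = np.interp(t_expect, tr.time, tr.heave)
        assert np.allclose(rec.heave, np.clip(oracle, -2.3, 2.3))
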