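"""Helical acquisition simulator: geometry, limits, and experiment bookkeeping."""

import dataclasses

import numpy as np
import pytest

from ctinterplay import (
    SLOW_PROTOCOL,
    STANDARD_PROTOCOL,
    ApparentObject,
    BreathingWaveform,
    ExperimentConfig,
    ScanProtocol,
    TargetSphere,
    acquire,
    alignment_error,
    apparent_center,
    run_phantom_experiment,
    signed_errors_monte_carlo,
)
from ctinterplay.exceptions import ConfigError, TargetNotCapturedError

SPHERE = TargetSphere()  # 30 mm diameter at mid scan length

# near-instantaneous sweep: the whole scan takes 50 ms, so the sphere is
# effectively frozen at one breathing phase (snapshot limit)
FAST_LIMIT = ScanProtocol(
    name="fast_limit", rotation_time_s=0.005, pitch=1.75,
    scan_time_s=0.05, slice_thickness_mm=1.0,
)
# sphere-crossing time of ~80 s >> any breathing period here (averaging limit)
SLOW_LIMIT = ScanProtocol(
    name="slow_limit", rotation_time_s=1.0, pitch=0.562, scan_time_s=500.0
)


def _still(amplitude=0.0, rate=12.0):
    return BreathingWaveform(amplitude_mm=amplitude, rate_bpm=rate)


class TestProtocols:
    def test_builtin_speed_ratio_consistent_with_pitch_and_rotation(self):
        # scan-time ratio slow/standard tracks (pitch/rotation) standard/slow
        time_ratio = SLOW_PROTOCOL.scan_time_s / STANDARD_PROTOCOL.scan_time_s
        speed_ratio = (STANDARD_PROTOCOL.pitch / STANDARD_PROTOCOL.rotation_time_s) / (
            SLOW_PROTOCOL.pitch / SLOW_PROTOCOL.rotation_time_s
        )
        assert time_ratio == pytest.approx(speed_ratio, rel=0.05)

    def test_table_speed(self):
        assert STANDARD_PROTOCOL.table_speed_mm_s == pytest.approx(250 / 9.9)
        assert SLOW_PROTOCOL.table_speed_mm_s == pytest.approx(250 / 59.5)


class TestAcquire:
    @pytest.mark.parametrize("protocol", [STANDARD_PROTOCOL, SLOW_PROTOCOL])
    def test_static_target_spans_sphere_diameter(self, protocol):
        obj = acquire(protocol, _still(), SPHERE)
        n_occupied = int(obj.occupied.sum())
        assert n_occupied in (12, 13)  # 30 mm sphere, 2.5 mm slices
        assert apparent_center(obj) == pytest.approx(SPHERE.center_mm)
        assert apparent_center(obj, mode="midpoint") == pytest.approx(
            SPHERE.center_mm, abs=protocol.slice_thickness_mm / 2
        )

    def test_snapshot_at_exhale_is_displaced_rigidly(self):
        # a standard scan catching the sphere at peak exhale sees a
        # near-rigid object shifted toward the head by up to half the
        # peak-to-peak amplitude
        w = BreathingWaveform(amplitude_mm=10, rate_bpm=8)
        crossing_t = (
            STANDARD_PROTOCOL.scan_length_mm - SPHERE.center_mm
        ) / STANDARD_PROTOCOL.table_speed_mm_s
        w = dataclasses.replace(w, phase_s=-crossing_t % w.period_s)
        rec = alignment_error(
            STANDARD_PROTOCOL, w, SPHERE, readout_quantum_mm=0.0
        )
        assert 0.0 < rec.signed_error_mm <= 5.0

    def test_slow_scan_blurs_target_beyond_diameter(self):
        w = BreathingWaveform(amplitude_mm=15, rate_bpm=28)
        obj = acquire(SLOW_PROTOCOL, w, SPHERE, start_phase_s=0.3)
        assert obj.extent_mm > 30.0

    def test_target_outside_scan_raises(self):
        far = TargetSphere(diameter_mm=30, center_mm=500.0)
        with pytest.raises(TargetNotCapturedError):
            acquire(STANDARD_PROTOCOL, _still(), far)


class TestApparentCenter:
    @staticmethod
    def _object(positions, occupancy):
        return ApparentObject(
            slice_positions_mm=np.asarray(positions, dtype=float),
            occupancy=np.asarray(occupancy, dtype=float),
            acquisition_times_s=np.zeros(len(positions)),
        )

    def test_symmetric_occupancy_centres_at_zero(self):
        obj = self._object([-2.5, 0.0, 2.5], [1.0, 2.0, 1.0])
        assert apparent_center(obj) == 0.0
        assert apparent_center(obj, mode="midpoint") == 0.0

    def test_binary_midpoint(self):
        obj = self._object([0.0, 2.5], [1.0, 1.0])
        assert apparent_center(obj, mode="midpoint") == pytest.approx(1.25)

    def test_area_weighted_mean(self):
        obj = self._object([0.0, 2.5], [3.0, 1.0])
        assert apparent_center(obj, mode="area_weighted") == pytest.approx(0.625)

    def test_empty_object_raises(self):
        obj = self._object([0.0, 2.5], [0.0, 0.0])
        with pytest.raises(TargetNotCapturedError):
            apparent_center(obj)


class TestAlignmentError:
    @pytest.mark.parametrize("protocol", [STANDARD_PROTOCOL, SLOW_PROTOCOL])
    @pytest.mark.parametrize("phase", [0.0, 1.3, 4.0])
    def test_zero_amplitude_zero_error(self, protocol, phase):
        rec = alignment_error(protocol, _still(), SPHERE, start_phase_s=phase)
        assert rec.signed_error_mm == 0.0
        assert rec.abs_error_mm == 0.0

    def test_readout_quantization(self):
        w = BreathingWaveform(amplitude_mm=10, rate_bpm=8)
        rec = alignment_error(STANDARD_PROTOCOL, w, SPHERE, 1.0,
                              readout_quantum_mm=1.0)
        assert rec.signed_error_mm == pytest.approx(round(rec.signed_error_mm))

    def test_fast_scan_matches_snapshot_oracle_per_phase(self):
        # in the snapshot limit, the signed error equals the waveform
        # displacement at the instant the plane crossed the sphere centre
        w = BreathingWaveform(amplitude_mm=10, rate_bpm=12)
        for phase in np.linspace(0, w.period_s, 7):
            rec = alignment_error(
                FAST_LIMIT, w, SPHERE, start_phase_s=phase,
                readout_quantum_mm=0.0, supersample=1,
            )
            crossing_t = (
                FAST_LIMIT.scan_length_mm - SPHERE.center_mm
            ) / FAST_LIMIT.table_speed_mm_s
            snapshot = w.displacement(crossing_t + phase)
            assert rec.signed_error_mm == pytest.approx(
                snapshot, abs=FAST_LIMIT.slice_thickness_mm / 2
            )

    def test_phase_symmetry_of_signed_errors(self):
        # over uniform start phase a sinusoid gives a sign-symmetric error
        # distribution: the mean is within 3 standard errors of zero
        w = BreathingWaveform(amplitude_mm=10, rate_bpm=20)
        errs = signed_errors_monte_carlo(
            STANDARD_PROTOCOL, w, SPHERE, 10_000, np.random.default_rng(11)
        )
        se = errs.std(ddof=1) / np.sqrt(errs.size)
        assert abs(errs.mean()) < 3 * se


class TestPhantomExperiment:
    def test_default_config_yields_180_records(self):
        records = run_phantom_experiment(ExperimentConfig(seed=3))
        assert len(records) == 180
        conditions = {(r.protocol, r.amplitude_mm, r.rate_bpm) for r in records}
        assert len(conditions) == 18

    def test_direction_alternation(self):
        cfg = ExperimentConfig(
            amplitudes_mm=(10.0,), rates_bpm=(20.0,), repeats=4, seed=0
        )
        records = run_phantom_experiment(cfg)
        for protocol in ("standard", "slow"):
            dirs = [r.direction for r in records if r.protocol == protocol]
            assert dirs == ["head_to_feet", "feet_to_head"] * 2

    def test_same_seed_reproduces_records(self):
        a = run_phantom_experiment(ExperimentConfig(seed=42))
        b = run_phantom_experiment(ExperimentConfig(seed=42))
        assert a == b

    def test_different_seed_changes_phases(self):
        a = run_phantom_experiment(ExperimentConfig(seed=1))
        b = run_phantom_experiment(ExperimentConfig(seed=2))
        assert [r.start_phase_s for r in a] != [r.start_phase_s for r in b]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"repeats": -1},
            {"amplitudes_mm": (-5.0,)},
            {"rates_bpm": (0.0,)},
            {"centroid": "eyeball"},
        ],
    )
    def test_invalid_config_raises(self, kwargs):
        with pytest.raises(ConfigError):
            ExperimentConfig(**kwargs)
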