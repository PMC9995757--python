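"""Simulator contracts: script grammar, kinematic postures, IMU physics."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from nearfall import simulate
from nearfall.io_core import GRAVITY, ActivityClass, Placement, ValidationError
from nearfall.simulate import (
    ActivityScript,
    NoiseModel,
    ScriptSegment,
    generate_random_script,
    kinematics_to_imu,
    script_to_kinematics,
    simulate_session,
    tilt_to_imu,
)


class TestScriptGeneration:
    def test_degenerate_mix_yields_only_walk(self):
        script = generate_random_script(60.0, seed=1, class_mix={ActivityClass.WALK: 1.0})
        assert {s.activity for s in script.segments} == {ActivityClass.WALK}

    def test_seed_determinism(self):
        a = generate_random_script(300.0, seed=5)
        b = generate_random_script(300.0, seed=5)
        assert [(s.activity, s.duration) for s in a.segments] == [
            (s.activity, s.duration) for s in b.segments
        ]

    def test_sit_stand_boundaries_have_transfers(self):
        mix = {ActivityClass.SIT: 0.5, ActivityClass.STAND: 0.5}
        script = generate_random_script(300.0, seed=2, class_mix=mix)
        segs = script.segments
        for a, b in zip(segs, segs[1:]):
            pair = {a.activity, b.activity}
            assert pair != {ActivityClass.SIT, ActivityClass.STAND}, (
                "sit/stand must be separated by a transfer segment"
            )

    def test_total_duration_close_to_requested(self):
        for seed in range(5):
            script = generate_random_script(600.0, seed=seed)
            assert abs(script.total_duration - 600.0) <= max(
                simulate.DEFAULT_MEAN_DURATIONS.values()
            )

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValidationError):
            generate_random_script(60.0, seed=0, class_mix={ActivityClass.WALK: 0.5})
        with pytest.raises(ValidationError):
            generate_random_script(
                60.0, seed=0, mean_durations={ActivityClass.WALK: -1.0}
            )

    def test_transfer_duration_invariant(self):
        with pytest.raises(ValidationError):
            ActivityScript([ScriptSegment(ActivityClass.SIT_TO_STAND, 0.2)])


class TestKinematics:
    def test_stand_script_is_vertical(self):
        script = ActivityScript([ScriptSegment(ActivityClass.STAND, 10.0)])
        kin = script_to_kinematics(script)
        for p in Placement:
            assert np.max(np.abs(kin.pitch[p])) < 0.05

    def test_sit_posture(self):
        script = ActivityScript([
            ScriptSegment(ActivityClass.SIT, 20.0),
        ])
        kin = script_to_kinematics(script)
        mid = slice(500, 1500)
        assert np.allclose(kin.pitch[Placement.THIGH_L][mid], np.pi / 2, atol=0.05)
        assert np.allclose(kin.pitch[Placement.SHANK_L][mid], 0.0, atol=0.05)
        assert np.allclose(kin.pitch[Placement.CHEST][mid], 0.0, atol=0.05)

    def test_lie_down_chest_horizontal(self):
        script = ActivityScript([ScriptSegment(ActivityClass.LIE_DOWN, 20.0)])
        kin = script_to_kinematics(script)
        assert np.allclose(kin.pitch[Placement.CHEST][500:1500], np.pi / 2, atol=0.05)

    def test_near_fall_rate_spike_and_recovery(self):
        script = ActivityScript([
            ScriptSegment(ActivityClass.STAND, 5.0),
            ScriptSegment(ActivityClass.NEAR_FALL, 2.5),
            ScriptSegment(ActivityClass.STAND, 5.0),
        ])
        kin = script_to_kinematics(script)
        chest = kin.pitch[Placement.CHEST]
        rate = np.abs(np.gradient(chest, 1.0 / kin.rate))
        assert rate.max() >= 2.0
        pre = chest[490]  # just before the event
        k_peak = int(np.argmax(chest))
        after = chest[k_peak + int(2.0 * kin.rate)]
        assert abs(after - pre) < 0.1

    def test_near_fall_chest_accel_transient(self):
        script = ActivityScript([
            ScriptSegment(ActivityClass.STAND, 5.0),
            ScriptSegment(ActivityClass.NEAR_FALL, 2.5),
            ScriptSegment(ActivityClass.STAND, 5.0),
        ])
        kin = script_to_kinematics(script)
        session, _ = kinematics_to_imu(
            kin, NoiseModel(accel_noise_sd=0.0, gyro_noise_sd=0.0, gyro_bias_limit=0.0)
        )
        mag = session.traces[Placement.CHEST].accel_magnitude()
        assert np.max(mag - GRAVITY) >= 5.0

    def test_fall_ends_lying(self):
        script = ActivityScript([
            ScriptSegment(ActivityClass.STAND, 5.0),
            ScriptSegment(ActivityClass.FALL, 4.0),
        ])
        kin = script_to_kinematics(script)
        assert kin.pitch[Placement.CHEST][-1] == pytest.approx(np.pi / 2, abs=0.1)

    def test_walk_shank_amplitude_exceeds_thigh(self):
        script = ActivityScript([ScriptSegment(ActivityClass.WALK, 30.0, {"cadence": 1.0})])
        kin = script_to_kinematics(script)
        mid = slice(500, 2500)
        assert np.ptp(kin.pitch[Placement.SHANK_L][mid]) > np.ptp(
            kin.pitch[Placement.THIGH_L][mid]
        )

    def test_walk_left_right_antiphase(self):
        script = ActivityScript([ScriptSegment(ActivityClass.WALK, 30.0, {"cadence": 1.0})])
        kin = script_to_kinematics(script)
        mid = slice(500, 2500)
        l = kin.pitch[Placement.THIGH_L][mid]
        r = kin.pitch[Placement.THIGH_R][mid]
        corr = np.corrcoef(l, r)[0, 1]
        assert corr < -0.9

    def test_walk_spectral_peak_at_cadence(self):
        cadence = 1.1
        script = ActivityScript([ScriptSegment(ActivityClass.WALK, 60.0, {"cadence": cadence})])
        kin = script_to_kinematics(script)
        session, _ = kinematics_to_imu(
            kin, NoiseModel(accel_noise_sd=0.0, gyro_noise_sd=0.0, gyro_bias_limit=0.0)
        )
        gy = session.traces[Placement.SHANK_L].gyro[500:5500, 1]
        spec = np.abs(np.fft.rfft(gy - gy.mean()))
        freqs = np.fft.rfftfreq(gy.size, d=1.0 / kin.rate)
        peak = freqs[np.argmax(spec)]
        assert abs(peak - cadence) <= 0.1

    def test_turn_has_yaw_pulse(self):
        script = ActivityScript([ScriptSegment(ActivityClass.TURN, 3.0, {"yaw_peak": 1.8})])
        kin = script_to_kinematics(script)
        assert np.max(np.abs(kin.yaw_rate[Placement.CHEST])) == pytest.approx(1.8, rel=0.05)


class TestImuSynthesis:
    def test_static_stand_reads_pure_gravity(self):
        theta = np.zeros(500)
        tr = tilt_to_imu(theta, 100.0)
        np.testing.assert_allclose(tr.accel[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(tr.accel[:, 2], GRAVITY, atol=1e-12)
        np.testing.assert_allclose(tr.accel_magnitude(), GRAVITY, atol=1e-12)

    def test_gyro_integrates_back_to_tilt(self):
        # analytic oracle: theta(t) = 0.3 sin(2 pi t)
        rate = 100.0
        t = np.arange(0, 10, 1 / rate)
        theta = 0.3 * np.sin(2 * np.pi * t)
        tr = tilt_to_imu(theta, rate)
        rec = cumulative_trapezoid(tr.gyro[:, 1], dx=1 / rate, initial=0.0) + theta[0]
        assert np.max(np.abs(rec - theta)) < 1e-3

    def test_fixed_seed_bitwise_reproducible(self):
        script = generate_random_script(60.0, seed=3)
        kin = script_to_kinematics(script)
        s1, _ = kinematics_to_imu(kin, NoiseModel(seed=9))
        s2, _ = kinematics_to_imu(kin, NoiseModel(seed=9))
        for p in Placement:
            np.testing.assert_array_equal(s1.traces[p].accel, s2.traces[p].accel)
            np.testing.assert_array_equal(s1.traces[p].gyro, s2.traces[p].gyro)

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValidationError):
            NoiseModel(accel_noise_sd=-0.1)


class TestSessionProperties:
    def test_labels_partition_session(self, small_session):
        session, events, script = small_session
        assert events.total_time() == pytest.approx(session.duration, abs=1e-6)
        starts = [e.start for e in events]
        ends = [e.end for e in events]
        assert starts[0] == 0.0
        np.testing.assert_allclose(ends[:-1], starts[1:], atol=1e-9)

    def test_near_fall_count_matches_script(self, small_session):
        _, events, script = small_session
        scripted = sum(1 for s in script.segments if s.activity is ActivityClass.NEAR_FALL)
        observed = len(events.of_class(ActivityClass.NEAR_FALL))
        assert observed == scripted

    def test_simulate_session_deterministic(self):
        a, ea, _ = simulate_session(60.0, seed=11)
        b, eb, _ = simulate_session(60.0, seed=11)
        np.testing.assert_array_equal(
            a.traces[Placement.CHEST].accel, b.traces[Placement.CHEST].accel
        )
        assert ea.to_frame().equals(eb.to_frame())
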