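"""The three WRI metrics: extrema detection, RoA, RoF, TRT, Symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrikit.io_model import ImuSeries, ProtocolSchedule, SessionRecording
from wrikit.metrics import (
    ExtremaSequence,
    WristCycleStats,
    compute_rotation_amplitude,
    compute_rotation_frequency,
    compute_symmetry,
    compute_total_rotation_time,
    detect_angle_extrema,
    extract_features,
)
from wrikit.preprocess import WristBlockSeries
from wrikit.simulate import SimParams, simulate_session

RATE = 50.0


def block_from_gy(gy, rate=RATE):
    t = np.arange(len(gy)) / rate
    z = np.zeros_like(t)
    return WristBlockSeries(t=t, ax=z, ay=z, az=z, gx=z, gy=np.asarray(gy, float),
                            gz=z, rate=rate, provenance=["test"])


def sine_rate_block(theta_amp=45.0, freq=2.0, duration=20.0, rate=RATE):
    """gy = d/dt [theta_amp * sin(2 pi f t)]."""
    t = np.arange(0, duration, 1 / rate)
    gy = theta_amp * 2 * np.pi * freq * np.cos(2 * np.pi * freq * t)
    return block_from_gy(gy, rate)


class TestExtremaDetection:
    def test_two_hz_sine_has_eighty_extrema_at_analytic_times(self):
        block = sine_rate_block()
        ext = detect_angle_extrema(block)
        assert ext.n_extrema == 80
        analytic = 0.125 + 0.25 * np.arange(80)  # extrema of sin(2 pi 2 t)
        np.testing.assert_allclose(ext.times, analytic, atol=0.010)

    def test_flat_signal_has_no_extrema(self):
        ext = detect_angle_extrema(block_from_gy(np.zeros(1000)))
        assert ext.n_extrema == 0

    def test_single_swing_pair_gives_two_extrema(self):
        # one full angle period: one upswing and one downswing
        t = np.arange(0, 0.5, 1 / RATE)
        gy = 45.0 * 2 * np.pi * 2.0 * np.cos(2 * np.pi * 2.0 * t)
        ext = detect_angle_extrema(block_from_gy(gy))
        assert ext.n_extrema == 2

    def test_bias_invariance_after_detrending(self):
        clean = sine_rate_block()
        biased = block_from_gy(clean.gy + 30.0)
        a = compute_rotation_amplitude(detect_angle_extrema(clean))
        b = compute_rotation_amplitude(detect_angle_extrema(biased))
        assert b == pytest.approx(a, rel=0.01)

    def test_sign_flip_invariance(self):
        clean = sine_rate_block()
        flipped = block_from_gy(-clean.gy)
        a = compute_rotation_amplitude(detect_angle_extrema(clean))
        b = compute_rotation_amplitude(detect_angle_extrema(flipped))
        assert b == pytest.approx(a, rel=1e-9)


class TestRotationAmplitude:
    def test_sine_swing_is_twice_theta(self):
        ext = detect_angle_extrema(sine_rate_block(theta_amp=45.0))
        roa = compute_rotation_amplitude(ext)
        assert roa == pytest.approx(90.0, rel=0.02)

    def test_two_extrema_single_interval(self):
        ext = ExtremaSequence(times=np.array([0.0, 0.25]), angles=np.array([10.0, -20.0]))
        assert compute_rotation_amplitude(ext) == pytest.approx(30.0)

    def test_equal_angles_zero_amplitude(self):
        ext = ExtremaSequence(times=np.array([0.0, 0.25]), angles=np.array([5.0, 5.0]))
        assert compute_rotation_amplitude(ext) == 0.0

    def test_insufficient_extrema_reported_as_zero(self):
        ext = ExtremaSequence(times=np.array([0.1]), angles=np.array([15.0]))
        assert compute_rotation_amplitude(ext) == 0.0

    def test_extrema_differences_equal_direct_integral(self):
        """Angle changes between extrema match independently integrating gy."""
        block = sine_rate_block()
        ext = detect_angle_extrema(block)
        roa = compute_rotation_amplitude(ext)
        # independent route: trapezoid-integrate gy between consecutive
        # extrema times, after removing the same linear trend
        from scipy.integrate import cumulative_trapezoid

        theta = cumulative_trapezoid(block.gy, block.t, initial=0.0)
        theta -= np.polyval(np.polyfit(block.t, theta, 1), block.t)
        idx = np.searchsorted(block.t, ext.times)
        swings = [
            abs(theta[j] - theta[i]) for i, j in zip(idx[:-1], idx[1:])
        ]
        assert roa == pytest.approx(np.mean(swings), rel=1e-6)


class TestRotationFrequency:
    def test_two_hz_sine(self):
        ext = detect_angle_extrema(sine_rate_block(freq=2.0))
        rof = compute_rotation_frequency(ext, duration=20.0)
        assert rof == pytest.approx(2.0, rel=0.02)

    @pytest.mark.parametrize("n", [0, 1])
    def test_too_few_extrema_is_zero(self, n):
        ext = ExtremaSequence(times=np.arange(n, dtype=float), angles=np.zeros(n))
        assert compute_rotation_frequency(ext, duration=20.0) == 0.0

    def test_three_extrema_over_half_second(self):
        ext = ExtremaSequence(times=np.array([0.0, 0.25, 0.5]), angles=np.array([1.0, -1.0, 1.0]))
        assert compute_rotation_frequency(ext, duration=20.0) == pytest.approx(2.0)


class TestTotalRotationTime:
    def test_full_block_rotation(self):
        trt = compute_total_rotation_time(sine_rate_block(duration=20.0))
        assert trt == pytest.approx(20.0, abs=0.2)

    def test_half_block_rotation(self):
        t = np.arange(0, 20, 1 / RATE)
        gy = np.where(t < 10.0, 45.0 * 2 * np.pi * 2 * np.cos(2 * np.pi * 2 * t), 0.0)
        trt = compute_total_rotation_time(block_from_gy(gy))
        assert trt == pytest.approx(10.0, abs=0.3)

    def test_flat_block_zero(self):
        assert compute_total_rotation_time(block_from_gy(np.zeros(1000))) == 0.0

    def test_short_gaps_bridged(self):
        t = np.arange(0, 20, 1 / RATE)
        gy = 45.0 * 2 * np.pi * 2 * np.cos(2 * np.pi * 2 * t)
        gy[(t >= 5.0) & (t < 5.3)] = 0.0  # 0.3 s hesitation < 0.5 s tolerance
        trt = compute_total_rotation_time(block_from_gy(gy))
        assert trt == pytest.approx(20.0, abs=0.3)


class TestSymmetry:
    def stats(self, roa, rof):
        return WristCycleStats(roa=roa, rof=rof, trt=0.0)

    def test_identical_wrists_is_one(self):
        assert compute_symmetry(self.stats(90, 2), self.stats(90, 2)) == 1.0

    def test_one_sided_motion_is_zero(self):
        assert compute_symmetry(self.stats(100, 2), self.stats(0, 0)) == pytest.approx(0.0)

    def test_worked_amplitude_difference(self):
        # 20% amplitude gap, equal frequency: (1 - 0.7*0.2)^2
        val = compute_symmetry(self.stats(80, 2), self.stats(100, 2))
        assert val == pytest.approx(0.7396, abs=1e-12)

    def test_both_wrists_motionless_counts_as_symmetric(self):
        assert compute_symmetry(self.stats(0, 0), self.stats(0, 0)) == 1.0

    @given(
        roa_l=st.floats(0, 500), roa_r=st.floats(0, 500),
        rof_l=st.floats(0, 10), rof_r=st.floats(0, 10),
    )
    @settings(derandomize=True, max_examples=200)
    def test_swap_invariance_and_range(self, roa_l, roa_r, rof_l, rof_r):
        a = compute_symmetry(
            WristCycleStats(roa_l, rof_l, 0), WristCycleStats(roa_r, rof_r, 0)
        )
        b = compute_symmetry(
            WristCycleStats(roa_r, rof_r, 0), WristCycleStats(roa_l, rof_l, 0)
        )
        assert a == b
        assert 0.0 <= a <= 1.0

    @given(gap=st.floats(0, 100), bigger_gap=st.floats(0, 100))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_amplitude_gap(self, gap, bigger_gap):
        lo, hi = sorted([gap, bigger_gap])
        near = compute_symmetry(
            WristCycleStats(100.0, 2.0, 0), WristCycleStats(100.0 - lo, 2.0, 0)
        )
        far = compute_symmetry(
            WristCycleStats(100.0, 2.0, 0), WristCycleStats(100.0 - hi, 2.0, 0)
        )
        assert far <= near + 1e-12


class TestExtractFeatures:
    def test_generator_recovery_noiseless(self, noiseless_session):
        f = extract_features(noiseless_session)
        assert f.trt == pytest.approx(20.0, abs=0.2)
        assert f.roa == pytest.approx(90.0, rel=0.02)
        assert f.symmetry == pytest.approx(1.0, abs=1e-6)
        assert not f.low_motion

    def test_asymmetric_wrists_recover_preset_ratio(self):
        p = SimParams(theta_amp=45, lr_amp_ratio=0.8, lr_freq_ratio=1.0,
                      gyro_noise_sd=0, accel_noise_sd=0, gyro_bias=0)
        f = extract_features(simulate_session(p))
        expected = (1 - 0.7 * 0.2) ** 2  # amplitude ratio 0.8, equal frequency
        assert f.symmetry == pytest.approx(expected, abs=0.02)

    def test_max_over_blocks_rule(self):
        """Session whose three blocks rotate at different amplitudes."""
        sched = ProtocolSchedule()
        t = np.arange(0, sched.total_duration + 1 / RATE, 1 / RATE)
        gy = np.zeros_like(t)
        for k, amp in enumerate([30.0, 45.0, 37.5]):  # RoA 60 / 90 / 75 deg
            start, end = sched.block_window(k)
            m = (t >= start) & (t < end)
            gy[m] = amp * 2 * np.pi * 2 * np.cos(2 * np.pi * 2 * (t[m] - start))
        z = np.zeros_like(t)
        wrist = ImuSeries(t=t, ax=z, ay=z, az=np.ones_like(t), gx=z, gy=gy, gz=z)
        session = SessionRecording("p", "TD", 60.0, left=wrist, right=wrist, schedule=sched)
        f = extract_features(session)
        assert f.roa == pytest.approx(90.0, rel=0.03)
        assert f.symmetry == pytest.approx(1.0, abs=1e-9)

    def test_motionless_session_flagged(self):
        p = SimParams(theta_amp=1.0, gyro_noise_sd=0, accel_noise_sd=0, gyro_bias=0)
        f = extract_features(simulate_session(p))
        assert f.low_motion
        assert (f.trt, f.roa, f.symmetry) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("noise_sd", [5.0, 20.0])
    def test_parameter_recovery_under_noise(self, noise_sd):
        """RoA within 5% and RoF within 2% up to 20 deg/s gyro noise."""
        p = SimParams(theta_amp=45.0, freq=2.0, sustain_s=20.0,
                      gyro_noise_sd=noise_sd, accel_noise_sd=0.02,
                      gyro_bias=1.0, seed=11)
        session = simulate_session(p)
        from wrikit.io_model import segment_blocks
        from wrikit.metrics import block_cycle_stats
        from wrikit.preprocess import preprocess_block

        block = preprocess_block(segment_blocks(session.right, session.schedule)[0])
        stats = block_cycle_stats(block)
        assert stats.roa == pytest.approx(90.0, rel=0.05)
        assert stats.rof == pytest.approx(2.0, rel=0.02)
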