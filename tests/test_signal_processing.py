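"""EMG/IMU conditioning: filters, rectification, envelope, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import signal as sps

from myogait.signal_processing import (
    NormalizationParams,
    RawSignal,
    bandpass_filter,
    compute_power_spectrum,
    denormalize,
    lowpass_envelope,
    median_filter,
    minmax_normalize,
    process_emg,
    rectify,
)


def _tone(freq, fs, dur=2.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _dft_power(x):
    """O(N^2) DFT-definition oracle for the one-sided power spectrum."""
    n = len(x)
    k = np.arange(n // 2 + 1)
    e = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    return np.abs(e @ x) ** 2


class TestPowerSpectrum:
    def test_single_tone_peak_at_its_frequency(self):
        sig = RawSignal(_tone(50, 1000), fs=1000)
        ps = compute_power_spectrum(sig)
        assert ps.frequencies[np.argmax(ps.power)] == pytest.approx(50.0)

    def test_constant_signal_concentrates_at_dc(self):
        ps = compute_power_spectrum(RawSignal(np.full(256, 3.0), fs=100))
        assert np.argmax(ps.power) == 0
        assert ps.power[1:].max() < 1e-18 * ps.power[0]

    def test_two_tone_spectrum_matches_dft_oracle(self):
        fs, n = 1024, 512  # 2 Hz bins: both tones fall exactly on the grid
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 30 * t) + 0.5 * np.sin(2 * np.pi * 200 * t)
        ps = compute_power_spectrum(RawSignal(x, fs))
        expected = _dft_power(x)
        np.testing.assert_allclose(ps.power, expected, rtol=1e-8, atol=1e-8)
        top2 = set(ps.frequencies[np.argsort(ps.power)[-2:]])
        assert top2 == {30.0, 200.0}

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            compute_power_spectrum(RawSignal([1.0, 2.0, 3.0], fs=10))


def _butter_mag_db(freq, low, high, order, fs):
    """Analytic magnitude response of the digital Butterworth bandpass,
    doubled for the forward-backward (zero-phase) application."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    return 2 * 20 * np.log10(np.abs(h[0]))


class TestBandpass:
    def test_passband_tone_preserved(self):
        sig = RawSignal(_tone(100, 2000), fs=2000)
        out = bandpass_filter(sig, 20, 400, order=4)
        mid = out.samples[500:-500]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation_matches_butterworth_response(self):
        sig = RawSignal(_tone(2, 2000, dur=8.0), fs=2000)
        out = bandpass_filter(sig, 20, 400, order=4)
        mid = slice(2000, -2000)
        atten_db = 20 * np.log10(
            np.std(out.samples[mid]) / np.std(sig.samples[mid])
        )
        expected_db = _butter_mag_db(2.0, 20, 400, 4, 2000)
        assert atten_db < -20.0
        assert atten_db == pytest.approx(expected_db, abs=1.5)

    def test_dc_offset_removed(self):
        sig = RawSignal(np.full(4000, 3.0), fs=2000)
        out = bandpass_filter(sig, 20, 400, order=4)
        assert abs(np.mean(out.samples)) < 1e-6 * 3.0

    def test_band_above_nyquist_rejected_with_required_fs(self):
        sig = RawSignal(np.zeros(100) + _tone(10, 500, dur=0.2), fs=500)
        with pytest.raises(ValueError, match="800"):
            bandpass_filter(sig, 20, 400, order=4)


class TestRectifyAndEnvelope:
    def test_rectify_is_absolute_value(self):
        out = rectify(RawSignal([-1.0, 2.0, -3.0], fs=10))
        np.testing.assert_array_equal(out.samples, [1.0, 2.0, 3.0])

    def test_rectify_identity_on_nonnegative(self, rng):
        x = rng.uniform(0, 5, 100)
        np.testing.assert_array_equal(rectify(RawSignal(x, fs=10)).samples, x)

    def test_envelope_of_rectified_sine_is_mean_of_abs(self):
        # mean of |A sin| is 2A/pi; the 8 Hz low-pass keeps only that DC term
        fs, amp = 2000, 1.5
        sig = rectify(RawSignal(_tone(100, fs, dur=4.0, amp=amp), fs=fs))
        env = lowpass_envelope(sig, cutoff_hz=8, order=4).samples[2000:-2000]
        target = 2 * amp / np.pi
        assert np.mean(env) == pytest.approx(target, rel=0.02)
        assert np.max(np.abs(env - target)) < 0.10 * target

    def test_envelope_passes_dc_and_zero(self):
        const = lowpass_envelope(RawSignal(np.full(1000, 0.5), fs=100), 8)
        np.testing.assert_allclose(const.samples, 0.5, atol=1e-9)
        zero = lowpass_envelope(RawSignal(np.zeros(1000), fs=100), 8)
        np.testing.assert_array_equal(zero.samples, 0.0)

    def test_envelope_nonnegative_after_clipping(self, rng):
        sig = rectify(RawSignal(rng.normal(size=5000), fs=1000))
        env = lowpass_envelope(sig, 8)
        assert np.all(env.samples >= 0.0)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_envelope(RawSignal(np.zeros(100) + 1.0, fs=10), cutoff_hz=8)


def _median_oracle(x, k):
    half = k // 2
    padded = np.pad(x, half, mode="symmetric")  # edge-inclusive reflection
    return np.array(
        [np.sort(padded[i: i + k])[half] for i in range(len(x))]
    )


class TestMedianFilter:
    def test_removes_single_impulse(self):
        np.testing.assert_array_equal(
            median_filter(np.array([0, 0, 9, 0, 0.0]), 3), np.zeros(5)
        )

    def test_monotone_ramp_unchanged_in_interior(self):
        x = np.arange(20.0)
        out = median_filter(x, 3)
        np.testing.assert_array_equal(out[1:-1], x[1:-1])

    def test_matches_naive_oracle_on_random_inputs(self, rng):
        for _ in range(50):
            x = rng.normal(size=rng.integers(10, 60))
            for k in (1, 3, 5):
                np.testing.assert_array_equal(
                    median_filter(x, k), _median_oracle(x, k)
                )

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            median_filter(np.zeros(10), 4)


class TestMinMax:
    def test_worked_example(self):
        out, params = minmax_normalize(np.array([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])
        assert (params.y_min, params.y_max) == (2.0, 6.0)

    def test_already_unit_interval_identity(self):
        x = np.array([0.0, 0.25, 1.0])
        out, params = minmax_normalize(x)
        np.testing.assert_allclose(out, x)
        assert (params.y_min, params.y_max) == (0.0, 1.0)

    def test_constant_input_degenerate(self):
        out, params = minmax_normalize(np.full(5, 5.0))
        np.testing.assert_array_equal(out, np.zeros(5))
        assert params.degenerate
        np.testing.assert_array_equal(
            denormalize(np.array([0.3, 0.7]), params), [5.0, 5.0]
        )

    def test_denormalize_worked_example_and_identity_params(self, rng):
        np.testing.assert_allclose(
            denormalize(np.array([0.0, 0.5, 1.0]), NormalizationParams(2, 6)),
            [2.0, 4.0, 6.0],
        )
        x = rng.normal(size=20)
        np.testing.assert_array_equal(x, denormalize(x, NormalizationParams(0, 1)))

    @settings(max_examples=200, deadline=None)
    @given(
        arrays(
            np.float64,
            st.integers(2, 50),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_output_in_unit_interval_and_roundtrip(self, x):
        out, params = minmax_normalize(x)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)
        if not params.degenerate:
            assert out.min() == 0.0 and out.max() == 1.0
            back = denormalize(out, params)
            np.testing.assert_allclose(back, x, rtol=1e-12, atol=1e-12 * params.span)


class TestEmgChain:
    def test_recovers_burst_centers(self, rng):
        # Gaussian bumps modulating a 150 Hz carrier: envelope peaks must sit
        # at the bump centers to within 10 ms
        fs, dur = 1000.0, 6.0
        t = np.arange(int(dur * fs)) / fs
        centers = [1.0, 3.0, 5.0]
        env = sum(np.exp(-0.5 * ((t - c) / 0.08) ** 2) for c in centers)
        raw = env * np.sin(2 * np.pi * 150 * t) + 0.01 * rng.normal(size=t.size)
        out = process_emg(RawSignal(raw, fs))
        for c in centers:
            win = (t > c - 0.5) & (t < c + 0.5)
            t_peak = t[win][np.argmax(out.samples[win])]
            assert abs(t_peak - c) < 0.010

    def test_zero_input_zero_envelope(self):
        out = process_emg(RawSignal(np.zeros(4000), fs=1000))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_scale_invariance_after_normalization(self, rng):
        fs = 1000.0
        t = np.arange(4000) / fs
        raw = np.exp(-0.5 * ((t - 2) / 0.2) ** 2) * rng.normal(size=t.size)
        e1 = process_emg(RawSignal(raw, fs)).samples
        e2 = process_emg(RawSignal(2.0 * raw, fs)).samples
        np.testing.assert_allclose(e2, 2.0 * e1, rtol=1e-9, atol=1e-12)
        n1, _ = minmax_normalize(e1)
        n2, _ = minmax_normalize(e2)
        np.testing.assert_allclose(n1, n2, atol=1e-9)
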