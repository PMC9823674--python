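"""Conditioning of raw surface-EMG and IMU channels.

The EMG chain turns a raw recording into a smooth activation envelope:

    bandpass (20-400 Hz Butterworth) -> full-wave rectification
    -> low-pass envelope (8 Hz Butterworth)

Stride segmentation, time normalization, median filtering and min-max
normalization happen downstream (:mod:`myogait.segmentation`), on a
per-stride basis.  All filters are applied forward-backward (zero phase)
so that peak-timing comparisons are not biased by filter group delay.

IMU channels skip the EMG-specific steps; they share only the per-stride
median filter and min-max normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sps


@dataclass
class RawSignal:
    """A single real-valued channel sampled uniformly at ``fs`` Hz."""

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"signal {self.label!r} contains non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def replace(self, samples: np.ndarray) -> "RawSignal":
        return RawSignal(samples, self.fs, self.label)


@dataclass
class NormalizationParams:
    """Min/max pair of a signal; inverts min-max normalization exactly.

    ``degenerate`` marks a constant input (y_max == y_min), for which the
    normalized signal is defined as all zeros and the inverse returns the
    constant ``y_min``.
    """

    y_min: float
    y_max: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.y_max < self.y_min:
            raise ValueError("y_max must be >= y_min")

    @property
    def span(self) -> float:
        return self.y_max - self.y_min


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray
    power: np.ndarray


@dataclass
class SignalConfig:
    """Filter parameters of the conditioning chain (the ``signal:`` block)."""

    band_low_hz: float = 20.0
    band_high_hz: float = 400.0
    band_order: int = 4
    envelope_cutoff_hz: float = 8.0
    envelope_order: int = 4
    median_kernel: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be an odd integer >= 1")


def compute_power_spectrum(sig: RawSignal) -> PowerSpectrum:
    """One-sided magnitude-squared spectrum (diagnostic band inspection)."""
    n = len(sig)
    if n < 8:
        raise ValueError(f"signal too short for a spectrum: {n} < 8 samples")
    spec = np.fft.rfft(sig.samples)
    freqs = np.fft.rfftfreq(n, d=1.0 / sig.fs)
    return PowerSpectrum(frequencies=freqs, power=np.abs(spec) ** 2)


def _check_cutoff(hz: float, fs: float, what: str) -> None:
    nyq = fs / 2.0
    if hz >= nyq:
        raise ValueError(
            f"{what} cutoff {hz:g} Hz is at or above Nyquist ({nyq:g} Hz); "
            f"a sampling rate above {2 * hz:g} Hz is required"
        )


def bandpass_filter(
    sig: RawSignal, low_hz: float = 20.0, high_hz: float = 400.0, order: int = 4
) -> RawSignal:
    """Zero-phase Butterworth bandpass; removes DC and out-of-band noise."""
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    _check_cutoff(high_hz, sig.fs, "bandpass upper")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=sig.fs, output="sos")
    return sig.replace(sps.sosfiltfilt(sos, sig.samples))


def rectify(sig: RawSignal) -> RawSignal:
    """Full-wave rectification."""
    return sig.replace(np.abs(sig.samples))


def lowpass_envelope(sig: RawSignal, cutoff_hz: float = 8.0, order: int = 4) -> RawSignal:
    """Zero-phase low-pass of a rectified signal; the linear envelope.

    Small negative ringing from the filter is clipped to zero — an
    activation envelope is physically non-negative.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    _check_cutoff(cutoff_hz, sig.fs, "low-pass")
    sos = sps.butter(order, cutoff_hz, btype="lowpass", fs=sig.fs, output="sos")
    out = sps.sosfiltfilt(sos, sig.samples)
    return sig.replace(np.clip(out, 0.0, None))


def median_filter(x: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Sliding-window median with reflected edges; removes impulsive noise."""
    x = np.asarray(x, dtype=float)
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError(f"median kernel must be odd and >= 1, got {kernel}")
    if kernel > x.size:
        raise ValueError(f"median kernel {kernel} exceeds signal length {x.size}")
    if kernel == 1:
        return x.copy()
    return ndimage.median_filter(x, size=kernel, mode="reflect")


def minmax_normalize(x: np.ndarray) -> tuple[np.ndarray, NormalizationParams]:
    """Rescale to [0, 1]: (y - y_min) / (y_max - y_min).

    A constant input has no range; it maps to all zeros and the returned
    params are flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    y_min, y_max = float(np.min(x)), float(np.max(x))
    if y_max == y_min:
        return np.zeros_like(x), NormalizationParams(y_min, y_max, degenerate=True)
    return (x - y_min) / (y_max - y_min), NormalizationParams(y_min, y_max)


def denormalize(x_norm: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Invert :func:`minmax_normalize`: y = y_norm * (y_max - y_min) + y_min."""
    x_norm = np.asarray(x_norm, dtype=float)
    if params.degenerate:
        return np.full_like(x_norm, params.y_min)
    return x_norm * params.span + params.y_min


def process_emg(raw: RawSignal, cfg: SignalConfig | None = None) -> RawSignal:
    """Per-trial EMG conditioning: bandpass -> rectify -> low-pass envelope.

    Returns the continuous activation envelope at the native sampling rate;
    per-stride median filtering and min-max normalization are applied after
    segmentation.
    """
    cfg = cfg or SignalConfig()
    x = bandpass_filter(raw, cfg.band_low_hz, cfg.band_high_hz, cfg.band_order)
    x = rectify(x)
    return lowpass_envelope(x, cfg.envelope_cutoff_hz, cfg.envelope_order)


def process_imu(raw: RawSignal) -> RawSignal:
    """IMU conditioning before segmentation.

    IMU channels bypass the EMG-specific steps; this validates the channel
    (finite, uniformly sampled) and passes it through.  Median filtering and
    min-max normalization are applied per stride downstream, exactly as for
    the EMG envelopes.
    """
    return raw.replace(raw.samples.copy())
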