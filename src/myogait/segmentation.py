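"""Stride segmentation, 101-point time normalization and reconstruction.

A stride (one gait cycle) runs from one heel strike to the next of the same
foot.  Each stride is resampled onto a fixed phase grid of 101 points
(0, 1, ..., 100 % of the gait cycle) by linear interpolation, median
filtered, and min-max normalized to [0, 1].  The stored min/max parameters
make the normalization exactly invertible, so predicted cycles can be
denormalized and stitched back onto the original time axis.

Convention: strides are half-open intervals [strike_k, strike_{k+1}), so the
0 % point of cycle k+1 is not duplicated with the 100 % point of cycle k.
During reconstruction the 100 % point of every cycle except the last is
dropped accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_processing import (
    NormalizationParams,
    RawSignal,
    denormalize,
    median_filter,
    minmax_normalize,
)

N_PHASE_POINTS = 101

#: strides with a duration outside this window (seconds) are physiologically
#: implausible for walking and are excluded from model training
PLAUSIBLE_STRIDE_S = (0.4, 2.5)


@dataclass
class StrideSegment:
    """One stride's samples at the native sampling rate."""

    samples: np.ndarray
    fs: float
    start_s: float
    end_s: float
    source_channel: str = ""

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("stride must have end_s > start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def plausible(self) -> bool:
        lo, hi = PLAUSIBLE_STRIDE_S
        return lo <= self.duration_s <= hi


@dataclass
class NormalizedCycle:
    """A stride on the 101-point phase grid, min-max normalized."""

    values: np.ndarray
    norm_params: NormalizationParams
    start_s: float
    end_s: float
    source_channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PHASE_POINTS,):
            raise ValueError(
                f"a normalized cycle has exactly {N_PHASE_POINTS} values, "
                f"got shape {self.values.shape}"
            )

    @property
    def percent_grid(self) -> np.ndarray:
        return np.arange(N_PHASE_POINTS, dtype=float)


def segment_strides(sig: RawSignal, heel_strikes: np.ndarray) -> list[StrideSegment]:
    """Split a recording into strides at consecutive heel-strike times.

    Data before the first and after the last strike are discarded.  Strike
    pairs that fall outside the recording span are dropped with a warning.
    """
    hs = np.asarray(heel_strikes, dtype=float)
    if hs.size >= 2 and np.any(np.diff(hs) <= 0):
        raise ValueError("heel-strike times must be strictly increasing")
    if hs.size < 2:
        warnings.warn("fewer than 2 heel strikes: no strides segmented", stacklevel=2)
        return []

    n = len(sig)
    span_s = n / sig.fs
    segments: list[StrideSegment] = []
    for start, end in zip(hs[:-1], hs[1:]):
        # sample i sits at time i / fs; take start <= i/fs < end
        i0 = int(np.ceil(start * sig.fs - 1e-9))
        i1 = int(np.ceil(end * sig.fs - 1e-9))
        if start < 0 or end > span_s + 1e-9 or i1 > n:
            warnings.warn(
                f"stride [{start:g}, {end:g}) s outside recording span "
                f"[0, {span_s:g}) s; dropped",
                stacklevel=2,
            )
            continue
        if i1 - i0 < 2:
            warnings.warn(
                f"stride [{start:g}, {end:g}) s holds fewer than 2 samples; dropped",
                stacklevel=2,
            )
            continue
        segments.append(
            StrideSegment(sig.samples[i0:i1].copy(), sig.fs, start, end, sig.label)
        )
    return segments


def time_normalize(samples: np.ndarray, n: int = N_PHASE_POINTS) -> np.ndarray:
    """Resample a stride onto ``n`` equally spaced phase points.

    Linear interpolation; the first/last output equal the first/last input
    sample exactly.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("segment must hold at least 2 samples")
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, x)


def to_normalized_cycle(
    segment: StrideSegment, median_kernel: int = 5, n: int = N_PHASE_POINTS
) -> NormalizedCycle:
    """Time-normalize, median-filter, then min-max normalize one stride.

    The median filter precedes min-max normalization so the output still
    attains exactly 0 and 1.
    """
    values = time_normalize(segment.samples, n)
    values = median_filter(values, median_kernel)
    values, params = minmax_normalize(values)
    return NormalizedCycle(values, params, segment.start_s, segment.end_s,
                           segment.source_channel)


def reconstruct_time_domain(
    cycles: list[NormalizedCycle], heel_strikes: np.ndarray, fs_out: float
) -> RawSignal:
    """Denormalize cycles and stitch them back onto a continuous time axis.

    Each cycle is mapped through the inverse min-max transform and linearly
    resampled from its 101 phase points onto that stride's time grid at
    ``fs_out``.  The output covers [first strike, last strike).
    """
    hs = np.asarray(heel_strikes, dtype=float)
    if hs.size != len(cycles) + 1:
        raise ValueError(
            f"{len(cycles)} cycles need {len(cycles) + 1} heel strikes, got {hs.size}"
        )
    if np.any(np.diff(hs) <= 0):
        raise ValueError("heel-strike times must be strictly increasing")

    t0 = hs[0]
    n_out = int(round((hs[-1] - t0) * fs_out))
    t = t0 + np.arange(n_out) / fs_out
    out = np.empty(n_out)
    phase_grid = np.linspace(0.0, 1.0, N_PHASE_POINTS)
    for cyc, start, end in zip(cycles, hs[:-1], hs[1:]):
        mask = (t >= start - 1e-12) & (t < end - 1e-12)
        phase = (t[mask] - start) / (end - start)
        y = denormalize(cyc.values, cyc.norm_params)
        out[mask] = np.interp(phase, phase_grid, y)
    label = cycles[0].source_channel if cycles else ""
    return RawSignal(out, fs_out, label)
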