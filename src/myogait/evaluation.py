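"""Waveform agreement between actual and predicted activation envelopes.

Per gait cycle (101-point envelopes):

* ``nRMSE`` — root-mean-square error divided by the *actual* envelope's
  range, in percent.  Undefined for a constant actual cycle.
* ``r`` — Pearson product-moment correlation, in percent.  Undefined when
  either signal has zero variance.
* ``dTp`` — signed difference between actual and predicted peak-contraction
  times, in % of gait cycle (actual minus predicted, no circular wrapping).
* ``dEp`` — absolute relative difference of the peak amplitudes,
  |Xp - Yp| / Xp, in percent.  Undefined when the actual peak is zero.

Undefined metrics become NaN; aggregation excludes them and reports the
exclusion count.  The timing error is aggregated on absolute values (mean
± SD), with the signed mean also reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_POINTS = 101


@dataclass
class PeakContraction:
    """Timing (% gait cycle) and amplitude of the largest contraction."""

    time_pct: int
    amplitude: float
    degenerate: bool = False


@dataclass
class CycleMetrics:
    nrmse_pct: float
    r_pct: float
    delta_tp_pct: float
    delta_ep_pct: float


def _check(env: np.ndarray, name: str) -> np.ndarray:
    env = np.asarray(env, dtype=float)
    if env.shape != (N_POINTS,):
        raise ValueError(f"{name} must have exactly {N_POINTS} points, "
                         f"got shape {env.shape}")
    return env


def find_peak(envelope: np.ndarray) -> PeakContraction:
    """Global maximum of a cycle; ties broken by the earliest index."""
    env = _check(envelope, "envelope")
    idx = int(np.argmax(env))  # argmax returns the first maximal index
    degenerate = bool(np.min(env) == np.max(env))
    return PeakContraction(idx, float(env[idx]), degenerate)


def nrmse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """RMSE over the cycle divided by the actual range, x100."""
    x = _check(actual, "actual")
    y = _check(predicted, "predicted")
    span = float(np.max(x) - np.min(x))
    if span == 0.0:
        return float("nan")
    return 100.0 * float(np.sqrt(np.mean((x - y) ** 2))) / span


def pearson_r(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation x100; NaN when either signal is constant."""
    x = _check(actual, "actual")
    y = _check(predicted, "predicted")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
    if denom == 0.0:
        return float("nan")
    return 100.0 * float(np.sum(xc * yc) / denom)


def delta_tp(actual_peak: PeakContraction, predicted_peak: PeakContraction) -> float:
    """Signed peak-time difference (actual - predicted), % of gait cycle."""
    return float(actual_peak.time_pct - predicted_peak.time_pct)


def delta_ep(actual_peak: PeakContraction, predicted_peak: PeakContraction) -> float:
    """|Xp - Yp| / Xp x100; NaN when the actual peak amplitude is zero."""
    if actual_peak.amplitude == 0.0:
        return float("nan")
    return 100.0 * abs(actual_peak.amplitude - predicted_peak.amplitude) / \
        actual_peak.amplitude


def cycle_metrics(actual: np.ndarray, predicted: np.ndarray) -> CycleMetrics:
    pa, pp = find_peak(actual), find_peak(predicted)
    return CycleMetrics(
        nrmse_pct=nrmse(actual, predicted),
        r_pct=pearson_r(actual, predicted),
        delta_tp_pct=delta_tp(pa, pp),
        delta_ep_pct=delta_ep(pa, pp),
    )


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    ok = values[np.isfinite(values)]
    if ok.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0
    return float(np.mean(ok)), sd


def evaluate_group(
    actual: np.ndarray, predicted: np.ndarray, muscle: str, group: str = "test"
) -> dict:
    """One report row: per-cycle metrics aggregated as mean ± sample SD.

    ``actual``/``predicted`` are (n_cycles, 101).  Cycles with undefined
    metrics are excluded per metric; exclusion counts are reported so that
    included + excluded always equals the total cycle count.
    """
    actual = np.atleast_2d(np.asarray(actual, dtype=float))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have matching shapes")
    n = actual.shape[0]
    per = [cycle_metrics(a, p) for a, p in zip(actual, predicted)]
    nr = np.array([m.nrmse_pct for m in per])
    rr = np.array([m.r_pct for m in per])
    dt = np.array([m.delta_tp_pct for m in per])
    de = np.array([m.delta_ep_pct for m in per])

    row = {"muscle": muscle, "group": group, "n_cycles": n}
    for key, vals in (("nrmse", nr), ("r", rr), ("delta_ep", de)):
        mean, sd = _mean_sd(vals)
        row[f"{key}_mean"] = mean
        row[f"{key}_sd"] = sd
        row[f"{key}_excluded"] = int(np.sum(~np.isfinite(vals)))
    # timing error: tables aggregate the absolute value; signed mean kept too
    mean_abs, sd_abs = _mean_sd(np.abs(dt))
    row["delta_tp_mean"] = mean_abs
    row["delta_tp_sd"] = sd_abs
    row["delta_tp_signed_mean"] = _mean_sd(dt)[0]
    row["delta_tp_excluded"] = int(np.sum(~np.isfinite(dt)))
    return row


def report_frame(rows: list[dict]) -> pd.DataFrame:
    """Stack report rows into a table (one row per muscle x architecture)."""
    return pd.DataFrame(rows)


def write_report(rows: list[dict], csv_path, json_path=None) -> pd.DataFrame:
    df = report_frame(rows)
    df.to_csv(csv_path, index=False, float_format="%.4f")
    if json_path is not None:
        df.to_json(json_path, orient="records", indent=1)
    return df
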