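"""On-disk formats.

Trials live as delimited time-series files: a ``time_s`` column plus named
channels (``emg_<muscle>``, ``<segment>_<accel|gyro>_<x|y|z>``).  Heel-strike
events are a one-column file (``heel_strike_s``).  Sampling rate is inferred
from the time column; irregular sampling beyond 1 % jitter is rejected.

Segmented, normalized cycles are persisted in one hierarchical HDF5
container: groups ``/<subject>/<trial>`` with per-stride arrays (IMU
101x24, EMG 101xM, min/max parameters, stride boundaries).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .signal_processing import RawSignal
from .synthetic import IMU_CHANNELS, SyntheticStudy, SyntheticTrial


def infer_fs(time_s: np.ndarray, max_jitter: float = 0.01) -> float:
    """Sampling rate from a time column; rejects irregular sampling."""
    t = np.asarray(time_s, dtype=float)
    if t.size < 2:
        raise ValueError("time column must hold at least 2 samples")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise ValueError("time column must be strictly increasing")
    if np.max(np.abs(dt - med)) > max_jitter * med:
        raise ValueError(
            f"irregular sampling: time steps deviate more than {max_jitter:.0%} "
            "from the median interval"
        )
    return 1.0 / med


def read_timeseries(path: Path) -> tuple[pd.DataFrame, float]:
    """Read a delimited trial file; returns (frame, sampling rate in Hz)."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing 'time_s' column")
    if df.isna().any().any():
        bad = [c for c in df.columns if df[c].isna().any()]
        raise ValueError(f"{path}: missing values in columns {bad}")
    return df, infer_fs(df["time_s"].to_numpy())


def channel_signal(df: pd.DataFrame, fs: float, name: str) -> RawSignal:
    if name not in df.columns:
        raise KeyError(f"channel {name!r} not present in trial file")
    return RawSignal(df[name].to_numpy(), fs, name)


def read_events(path: Path) -> np.ndarray:
    ev = pd.read_csv(path)
    if "heel_strike_s" not in ev.columns:
        raise ValueError(f"{path}: missing 'heel_strike_s' column")
    return ev["heel_strike_s"].to_numpy(dtype=float)


def write_study(study: SyntheticStudy, out_dir: Path) -> Path:
    """Write each trial's IMU/EMG/event files plus a study manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": study.seed, "muscles": study.muscles, "trials": []}
    for tr in study.trials:
        stem = f"{tr.subject_id}_{tr.trial_id}"
        tr.imu.to_csv(out_dir / f"{stem}_imu.csv", index=False, float_format="%.6g")
        tr.emg.to_csv(out_dir / f"{stem}_emg.csv", index=False, float_format="%.6g")
        pd.DataFrame({"heel_strike_s": tr.heel_strikes}).to_csv(
            out_dir / f"{stem}_events.csv", index=False, float_format="%.9g"
        )
        manifest["trials"].append(
            {"subject_id": tr.subject_id, "trial_id": tr.trial_id, "speed": tr.speed,
             "stem": stem}
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out_dir


@dataclass
class TrialFiles:
    """One trial loaded back from disk."""

    subject_id: str
    trial_id: str
    speed: str
    imu: pd.DataFrame
    imu_fs: float
    emg: pd.DataFrame
    emg_fs: float
    heel_strikes: np.ndarray


def read_study(data_dir: Path) -> tuple[list[TrialFiles], list[str]]:
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    trials = []
    for entry in manifest["trials"]:
        stem = entry["stem"]
        imu, imu_fs = read_timeseries(data_dir / f"{stem}_imu.csv")
        emg, emg_fs = read_timeseries(data_dir / f"{stem}_emg.csv")
        hs = read_events(data_dir / f"{stem}_events.csv")
        trials.append(
            TrialFiles(entry["subject_id"], entry["trial_id"], entry["speed"],
                       imu, imu_fs, emg, emg_fs, hs)
        )
    return trials, manifest["muscles"]


def save_cycles(path: Path, samples: list, muscles: list[str]) -> None:
    """Persist GaitCycleSamples to the hierarchical container."""
    by_trial: dict = {}
    for s in samples:
        by_trial.setdefault((s.subject_id, s.trial_id), []).append(s)
    with h5py.File(path, "w") as f:
        f.attrs["muscles"] = muscles
        f.attrs["imu_channels"] = list(IMU_CHANNELS)
        for (sid, tid), group in by_trial.items():
            group.sort(key=lambda s: s.stride_index)
            g = f.require_group(f"{sid}/{tid}")
            g.attrs["speed"] = group[0].speed_label or ""
            g.create_dataset("imu", data=np.stack([s.features for s in group]))
            g.create_dataset(
                "emg", data=np.stack(
                    [np.stack([s.targets[m] for m in muscles], axis=1) for s in group]
                )
            )
            g.create_dataset(
                "emg_min", data=np.array(
                    [[s.target_params[m].y_min for m in muscles] for s in group]
                )
            )
            g.create_dataset(
                "emg_max", data=np.array(
                    [[s.target_params[m].y_max for m in muscles] for s in group]
                )
            )
            g.create_dataset("stride_index",
                             data=np.array([s.stride_index for s in group]))
            g.create_dataset("start_s", data=np.array([s.start_s for s in group]))
            g.create_dataset("end_s", data=np.array([s.end_s for s in group]))


def load_cycles(path: Path) -> tuple[list, list[str]]:
    """Load GaitCycleSamples back from the hierarchical container."""
    from .datasets import GaitCycleSample  # local import: avoid a cycle
    from .signal_processing import NormalizationParams

    samples: list = []
    with h5py.File(path, "r") as f:
        muscles = [m for m in f.attrs["muscles"]]
        for sid in f:
            for tid in f[sid]:
                g = f[sid][tid]
                imu = g["imu"][...]
                emg = g["emg"][...]
                emg_min = g["emg_min"][...]
                emg_max = g["emg_max"][...]
                for k in range(imu.shape[0]):
                    targets = {m: emg[k, :, j] for j, m in enumerate(muscles)}
                    params = {
                        m: NormalizationParams(
                            float(emg_min[k, j]), float(emg_max[k, j]),
                            degenerate=emg_min[k, j] == emg_max[k, j],
                        )
                        for j, m in enumerate(muscles)
                    }
                    samples.append(
                        GaitCycleSample(
                            features=imu[k], targets=targets, target_params=params,
                            subject_id=sid, trial_id=tid,
                            stride_index=int(g["stride_index"][k]),
                            speed_label=g.attrs.get("speed", ""),
                            start_s=float(g["start_s"][k]),
                            end_s=float(g["end_s"][k]),
                        )
                    )
    samples.sort(key=lambda s: (s.subject_id, s.trial_id, s.stride_index))
    return samples, muscles


def write_split_manifest(path: Path, split) -> None:
    """Human-auditable table: one row per sample with its assigned group."""
    rows = []
    for name in ("train", "validation", "test", "unseen_subject"):
        for s in getattr(split, name):
            rows.append(
                {"subject_id": s.subject_id, "trial_id": s.trial_id,
                 "stride_index": s.stride_index, "group": name}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
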