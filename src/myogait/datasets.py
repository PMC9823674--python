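"""Per-stride feature/target samples and the train/validation/test split.

A sample is one gait cycle: a 101x24 block of min-max-normalized IMU
channels (phase x [trunk, thigh, shank, foot] x [accel xyz, gyro xyz]) and,
per muscle, a 101-point normalized EMG envelope with its stored min/max
parameters.  Samples are randomized and divided 80:15:5 into train,
validation and test groups, with one whole subject optionally held out as
unseen-subject data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import segmentation as seg
from .io import infer_fs
from .signal_processing import (
    NormalizationParams,
    RawSignal,
    SignalConfig,
    median_filter,
    minmax_normalize,
    process_emg,
)
from .synthetic import IMU_CHANNELS

N_FEATURES = len(IMU_CHANNELS)  # 24


@dataclass
class GaitCycleSample:
    features: np.ndarray                 # (101, 24), values in [0, 1]
    targets: dict                        # muscle -> (101,) normalized envelope
    target_params: dict                  # muscle -> NormalizationParams
    subject_id: str
    trial_id: str
    stride_index: int
    speed_label: str = ""
    start_s: float = 0.0
    end_s: float = 0.0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (seg.N_PHASE_POINTS, N_FEATURES):
            raise ValueError(
                f"feature block must be {seg.N_PHASE_POINTS}x{N_FEATURES}, "
                f"got {self.features.shape}"
            )
        for m, t in self.targets.items():
            t = np.asarray(t, dtype=float)
            if t.shape != (seg.N_PHASE_POINTS,):
                raise ValueError(f"target {m!r} must have {seg.N_PHASE_POINTS} points")
            self.targets[m] = t


@dataclass
class DatasetSplit:
    train: list
    validation: list
    test: list
    unseen_subject: list = field(default_factory=list)
    seed: int = 0


def _segment_normalized(
    sig: RawSignal, heel_strikes: np.ndarray, kernel: int
) -> list[seg.NormalizedCycle | None]:
    """One NormalizedCycle per stride; implausible strides become None."""
    out: list = []
    for segment in seg.segment_strides(sig, heel_strikes):
        if not segment.plausible:
            out.append(None)
            continue
        out.append(seg.to_normalized_cycle(segment, median_kernel=kernel))
    return out


def build_samples(trials, muscles: list[str], cfg: SignalConfig | None = None) -> list:
    """Run the full conditioning chain on trials and pair IMU/EMG strides.

    ``trials`` are objects exposing ``imu``/``emg`` dataframes (``time_s`` +
    named channels), ``heel_strikes``, ``subject_id``, ``trial_id`` and
    ``speed``.  Channels are looked up by name, so column order in the files
    is irrelevant.  Strides with implausible duration are excluded.
    """
    cfg = cfg or SignalConfig()
    samples: list = []
    for tr in trials:
        imu_fs = infer_fs(tr.imu["time_s"].to_numpy())
        emg_fs = infer_fs(tr.emg["time_s"].to_numpy())
        missing = [c for c in IMU_CHANNELS if c not in tr.imu.columns]
        missing += [f"emg_{m}" for m in muscles if f"emg_{m}" not in tr.emg.columns]
        if missing:
            raise ValueError(
                f"trial {tr.subject_id}/{tr.trial_id}: missing channels {missing}"
            )
        hs = np.asarray(tr.heel_strikes, dtype=float)

        imu_cycles = {
            ch: _segment_normalized(
                RawSignal(tr.imu[ch].to_numpy(), imu_fs, ch), hs, cfg.median_kernel
            )
            for ch in IMU_CHANNELS
        }
        emg_cycles = {}
        for m in muscles:
            raw = RawSignal(tr.emg[f"emg_{m}"].to_numpy(), emg_fs, f"emg_{m}")
            env = process_emg(raw, cfg)
            emg_cycles[m] = _segment_normalized(env, hs, cfg.median_kernel)

        n_strides = len(next(iter(imu_cycles.values())))
        for k in range(n_strides):
            cycle_set = [imu_cycles[ch][k] for ch in IMU_CHANNELS]
            target_set = [emg_cycles[m][k] for m in muscles]
            if any(c is None for c in cycle_set + target_set):
                continue  # implausible stride: excluded from training data
            features = np.stack([c.values for c in cycle_set], axis=1)
            samples.append(
                GaitCycleSample(
                    features=features,
                    targets={m: c.values for m, c in zip(muscles, target_set)},
                    target_params={m: c.norm_params
                                   for m, c in zip(muscles, target_set)},
                    subject_id=tr.subject_id,
                    trial_id=tr.trial_id,
                    stride_index=k,
                    speed_label=getattr(tr, "speed", ""),
                    start_s=cycle_set[0].start_s,
                    end_s=cycle_set[0].end_s,
                )
            )
    return samples


def _split_indices(n: int, ratios, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Floor val/test sizes; the remainder goes to train."""
    n_val = math.floor(n * ratios[1])
    n_test = math.floor(n * ratios[2])
    perm = rng.permutation(n)
    return (
        perm[: n - n_val - n_test],
        perm[n - n_val - n_test: n - n_test],
        perm[n - n_test:],
    )


def split_dataset(
    samples: list,
    ratios: tuple = (0.80, 0.15, 0.05),
    seed: int = 0,
    by: str = "stride",
) -> DatasetSplit:
    """Randomized 80:15:5 division into train/validation/test.

    ``by='stride'`` randomizes individual gait cycles (cycles of one subject
    may appear in several groups); ``by='trial'`` keeps whole trials
    together.  Deterministic given ``seed``.
    """
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    if len(samples) < 20:
        raise ValueError("need at least 20 samples to split")
    rng = np.random.default_rng(seed)

    if by == "stride":
        tr, va, te = _split_indices(len(samples), ratios, rng)
        pick = lambda idx: [samples[i] for i in sorted(idx)]
        return DatasetSplit(pick(tr), pick(va), pick(te), seed=seed)
    if by == "trial":
        keys = sorted({(s.subject_id, s.trial_id) for s in samples})
        tr, va, te = _split_indices(len(keys), ratios, rng)
        groups = {k: [] for k in keys}
        for s in samples:
            groups[(s.subject_id, s.trial_id)].append(s)
        pick = lambda idx: [s for i in sorted(idx) for s in groups[keys[i]]]
        return DatasetSplit(pick(tr), pick(va), pick(te), seed=seed)
    raise ValueError(f"unknown split unit {by!r}; use 'stride' or 'trial'")


def holdout_subject(samples: list, subject_id: str) -> tuple[list, list]:
    """Set one subject aside entirely as unseen-subject test data."""
    unseen = [s for s in samples if s.subject_id == subject_id]
    if not unseen:
        raise ValueError(f"subject {subject_id!r} not present in the sample set")
    remaining = [s for s in samples if s.subject_id != subject_id]
    return remaining, unseen


def stack_features(samples: list, flatten: bool = False) -> np.ndarray:
    """(N, 101, 24) feature tensor, or (N, 2424) when flattened for the FNN."""
    x = np.stack([s.features for s in samples])
    return x.reshape(len(samples), -1) if flatten else x


def stack_targets(samples: list, muscle: str) -> np.ndarray:
    return np.stack([s.targets[muscle] for s in samples])
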