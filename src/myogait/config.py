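"""Run configuration: one YAML file validated against a strict schema.

Unknown keys are rejected before any computation, so typos in a config file
fail fast instead of silently falling back to defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .signal_processing import SignalConfig
from .synthetic import GeneratorConfig, muscle_names


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SignalBlock(_Strict):
    band_low_hz: float = 20.0
    band_high_hz: float = 400.0
    band_order: int = 4
    envelope_cutoff_hz: float = 8.0
    envelope_order: int = 4
    median_kernel: int = 5

    def to_config(self) -> SignalConfig:
        return SignalConfig(**self.model_dump())


class SplitBlock(_Strict):
    ratios: tuple[float, float, float] = (0.80, 0.15, 0.05)
    by: str = "stride"
    #: subject id to hold out entirely; "random" draws one from the seed
    unseen_subject: str = "random"

    @field_validator("by")
    @classmethod
    def _by(cls, v: str) -> str:
        if v not in ("stride", "trial"):
            raise ValueError("split unit must be 'stride' or 'trial'")
        return v


class ModelBlock(_Strict):
    architectures: list[str] = ["fnn", "lstm"]
    hidden_layers: int = 2
    hidden_units: int = 64
    dropout_rate: float = 0.2
    learning_rate: float = 3e-3
    batch_size: int = 128
    max_epochs: int = 120
    early_stop_patience: int = 15

    @field_validator("architectures")
    @classmethod
    def _arch(cls, v: list[str]) -> list[str]:
        bad = [a for a in v if a not in ("fnn", "lstm")]
        if bad:
            raise ValueError(f"unknown architectures {bad}")
        return v


class SyntheticBlock(_Strict):
    n_subjects: int = 4
    trials_per_subject: int = 3
    strides_per_trial: int = 60
    emg_fs: float = 1000.0
    imu_fs: float = 200.0
    imu_noise_sd: float = 0.03
    emg_noise_sd: float = 0.01
    drift_amp_rel: float = 0.25
    impulse_rate_hz: float = 0.2
    burst_amp_jitter_sd: float = 0.15
    burst_center_jitter_pct: float = 1.0
    subject_amp_sd: float = 0.35
    subject_burst_sd: float = 0.25
    coupling_gain: float = 1.0
    n_harmonics: int = 3

    def to_config(self) -> GeneratorConfig:
        return GeneratorConfig(**self.model_dump())


class RunConfig(_Strict):
    seed: int = 0
    muscles: list[str] | None = None     # None -> the default nine-muscle set
    signal: SignalBlock = SignalBlock()
    split: SplitBlock = SplitBlock()
    model: ModelBlock = ModelBlock()
    synthetic: SyntheticBlock = SyntheticBlock()

    def muscle_list(self) -> list[str]:
        return list(self.muscles) if self.muscles else muscle_names()


def load_config(path: Path | str | None = None, **overrides) -> RunConfig:
    """Load and validate a YAML run config; keyword overrides win."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path: Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)
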