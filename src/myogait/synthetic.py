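"""Synthetic gait studies: stride-locked IMU channels coupled to muscle bursts.

The generator emulates the structure of a level-ground walking dataset:

* nine lower-extremity muscles, each with one or two activation bursts at
  gait phases taken from the standard gait-EMG literature (e.g. tibialis
  anterior bursting in pre-/mid-swing around 60-80 % and again at terminal
  swing wrapping into the next cycle; hamstrings peaking near 90 % with an
  additional stance-phase component around 30 % that grows in slow walking;
  rectus femoris around 50 % with strong speed dependence plus an early
  stance peak modelling crosstalk from vastus lateralis);
* four instrumented segments (trunk, thigh, shank, foot), each providing
  3-axis acceleration and 3-axis angular velocity.  Every IMU channel is a
  subject-specific low-order Fourier series over gait phase **plus a linear
  mixture of the realized muscle activations and their phase derivatives**,
  plus sensor noise — so the IMU -> EMG map is deterministic up to noise and
  the estimation problem is solvable by construction;
* raw surface EMG synthesized as the activation envelope amplitude-modulating
  a zero-mean broadband (20-400 Hz) carrier, with additive low-frequency
  drift and sparse impulsive artifacts, so the full conditioning chain is
  exercised from the raw end;
* per-subject variability: stride period, per-muscle and per-burst amplitude
  scalings, IMU gains/offsets, and per-stride jitter of burst timing and
  amplitude.

Negative-control mode (``coupling_gain=0``): the activation mixture is
removed from the IMU channels *and* burst timing is decoupled from the gait
cycle (burst centers drawn uniformly per stride).  Zero coupling means the
muscles fire independently of limb motion, so no model should be able to
predict the per-stride envelopes from the IMU data; any residual skill
indicates information leakage through preprocessing.  See docs/methods.md.

All randomness flows from one integer seed; per-subject substreams are
derived by stable hashing of the subject id, so output is reproducible
across runs and platforms.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_processing import RawSignal

SPEEDS = ("slow", "normal", "fast")
STRIDE_PERIOD_S = {"slow": 1.25, "normal": 1.10, "fast": 0.95}

IMU_SEGMENTS = ("trunk", "thigh", "shank", "foot")
IMU_KINDS = ("accel", "gyro")
IMU_AXES = ("x", "y", "z")
#: fixed, documented channel order: [trunk, thigh, shank, foot] x [accel xyz, gyro xyz]
IMU_CHANNELS = tuple(
    f"{seg}_{kind}_{ax}" for seg in IMU_SEGMENTS for kind in IMU_KINDS for ax in IMU_AXES
)

N_PHASE = 101


@dataclass
class Burst:
    """One Gaussian activation burst on the circular gait-phase axis."""

    center_pct: float
    width_pct: float
    amplitude: float = 1.0
    #: per-speed amplitude multiplier
    speed_coupling: dict = field(
        default_factory=lambda: {"slow": 1.0, "normal": 1.0, "fast": 1.0}
    )

    def __post_init__(self) -> None:
        if not 0 <= self.center_pct <= 100:
            raise ValueError("burst center must lie in [0, 100] % gait cycle")
        if self.width_pct <= 0 or self.amplitude < 0:
            raise ValueError("burst width must be > 0 and amplitude >= 0")


@dataclass
class SyntheticMuscleSpec:
    name: str
    bursts: list
    #: (source muscle name, fraction) — surface-electrode crosstalk
    crosstalk: tuple | None = None


def default_muscle_specs() -> list[SyntheticMuscleSpec]:
    """The nine-muscle set with burst phases from standard gait-EMG timing."""
    sc = lambda s, n, f: {"slow": s, "normal": n, "fast": f}
    return [
        SyntheticMuscleSpec("gastrocnemius", [
            Burst(42, 8, 1.0), Burst(12, 6, 0.25),
        ]),
        SyntheticMuscleSpec("tibialis_anterior", [
            Burst(70, 7, 0.8),            # pre- to mid-swing
            Burst(97, 6, 1.0),            # terminal swing, wraps into 0-10 %
        ]),
        SyntheticMuscleSpec("soleus", [Burst(44, 9, 1.0)]),
        SyntheticMuscleSpec("vastus_medialis", [
            Burst(6, 7, 1.0), Burst(96, 5, 0.4),
        ]),
        SyntheticMuscleSpec("vastus_lateralis", [
            Burst(5, 7, 1.0), Burst(95, 5, 0.4),
        ]),
        SyntheticMuscleSpec("rectus_femoris", [
            # pre-/initial-swing burst, nearly absent at slow speed
            Burst(50, 6, 0.9, sc(0.15, 0.6, 1.0)),
        ], crosstalk=("vastus_lateralis", 0.5)),
        SyntheticMuscleSpec("biceps_femoris", [
            Burst(92, 7, 1.0),
            Burst(30, 8, 0.6, sc(1.4, 0.8, 0.45)),   # stance bump, slow-enhanced
        ]),
        SyntheticMuscleSpec("semitendinosus", [
            Burst(90, 7, 1.0),
            Burst(32, 8, 0.55, sc(1.4, 0.8, 0.45)),
        ]),
        SyntheticMuscleSpec("gluteus_medius", [
            Burst(8, 8, 1.0), Burst(55, 10, 0.35),
        ]),
    ]


def muscle_names(specs=None) -> list[str]:
    return [m.name for m in (specs or default_muscle_specs())]


@dataclass
class SyntheticSubjectConfig:
    """Per-subject draw of gait and sensor idiosyncrasies."""

    subject_id: str
    stride_period_factor: float = 1.0   # multiplies the speed-class mean
    stride_period_sd_s: float = 0.03    # stride-to-stride SD
    muscle_amp_scale: dict = field(default_factory=dict)      # muscle -> factor
    burst_amp_mods: dict = field(default_factory=dict)        # muscle -> per-burst factors
    imu_gain: np.ndarray | None = None                        # (24,)
    imu_offset: np.ndarray | None = None                      # (24,)
    fourier_cos: np.ndarray | None = None                     # (24, K)
    fourier_sin: np.ndarray | None = None


@dataclass
class GeneratorConfig:
    """Study-level defaults (the ``synthetic:`` config block)."""

    n_subjects: int = 4
    trials_per_subject: int = 3
    strides_per_trial: int = 60
    emg_fs: float = 1000.0
    imu_fs: float = 200.0
    imu_noise_sd: float = 0.03
    emg_noise_sd: float = 0.01          # relative broadband floor on raw EMG
    drift_amp_rel: float = 0.25         # low-frequency drift, relative to peak
    impulse_rate_hz: float = 0.2        # sparse artifact rate on raw EMG
    burst_amp_jitter_sd: float = 0.15   # per-stride lognormal sigma
    burst_center_jitter_pct: float = 1.0
    subject_amp_sd: float = 0.35        # per-subject lognormal sigma (per muscle)
    subject_burst_sd: float = 0.25      # per-subject lognormal sigma (per burst)
    coupling_gain: float = 1.0          # activation -> IMU mixture strength
    n_harmonics: int = 3


def _circ_dist(phase_pct: np.ndarray, center_pct: float) -> np.ndarray:
    return (np.asarray(phase_pct, dtype=float) - center_pct + 50.0) % 100.0 - 50.0


def activation_profile(
    spec: SyntheticMuscleSpec,
    phase_pct: np.ndarray,
    speed: str = "normal",
    burst_scales: np.ndarray | None = None,
    burst_centers: np.ndarray | None = None,
) -> np.ndarray:
    """Sum of circular Gaussian bursts of one muscle, >= 0.

    Bursts centered near 100 % wrap into the next cycle's 0 %.  Crosstalk is
    added at the study level (it needs the source muscle's profile); this
    function evaluates the muscle's own bursts only.
    """
    phase_pct = np.asarray(phase_pct, dtype=float)
    env = np.zeros_like(phase_pct)
    for j, b in enumerate(spec.bursts):
        amp = b.amplitude * b.speed_coupling.get(speed, 1.0)
        if burst_scales is not None:
            amp *= burst_scales[j]
        center = b.center_pct if burst_centers is None else burst_centers[j]
        d = _circ_dist(phase_pct, center)
        env += amp * np.exp(-0.5 * (d / b.width_pct) ** 2)
    return np.clip(env, 0.0, None)


def synthesize_raw_emg(
    envelope: np.ndarray,
    fs: float,
    rng: np.random.Generator,
    noise_sd: float = 0.01,
    drift_amp_rel: float = 0.25,
    impulse_rate_hz: float = 0.2,
    band: tuple = (20.0, 400.0),
) -> RawSignal:
    """Raw surface EMG from a known activation envelope.

    Amplitude-modulated zero-mean broadband carrier plus low-frequency drift,
    a broadband noise floor, and sparse single-sample impulsive artifacts.
    All disturbance amplitudes scale with the envelope's peak, so a zero
    envelope yields an exactly zero recording.
    """
    envelope = np.asarray(envelope, dtype=float)
    n = envelope.size
    scale = float(np.max(envelope)) if n else 0.0
    if scale == 0.0:
        return RawSignal(np.zeros(max(n, 2)), fs, "emg")

    high = min(band[1], 0.45 * fs)
    sos = sps.butter(4, [band[0], high], btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
    carrier /= np.std(carrier)

    t = np.arange(n) / fs
    drift = drift_amp_rel * scale * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    raw = envelope * carrier + drift + noise_sd * scale * rng.standard_normal(n)

    n_imp = rng.poisson(impulse_rate_hz * n / fs)
    if n_imp:
        idx = rng.integers(0, n, size=n_imp)
        raw[idx] += rng.choice([-1.0, 1.0], size=n_imp) * 3.0 * scale
    return RawSignal(raw, fs, "emg")


def imu_from_activations(
    subject: SyntheticSubjectConfig,
    phase_pct: np.ndarray,
    activations: np.ndarray,
    mix_act: np.ndarray,
    mix_deriv: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float = 0.03,
    coupling_gain: float = 1.0,
) -> np.ndarray:
    """24 IMU channels over one trial's sample grid.

    ``activations`` is (n_samples, n_muscles); ``mix_act``/``mix_deriv`` are
    (24, n_muscles) study-level mixture weights.  Each channel is a fixed
    smooth Fourier basis over phase (subject-specific coefficients) plus a
    linear mixture of the activations and their sample derivatives, plus
    Gaussian sensor noise.
    """
    phase = np.asarray(phase_pct, dtype=float) / 100.0
    k = np.arange(1, subject.fourier_cos.shape[1] + 1)
    ang = 2 * np.pi * phase[:, None] * k[None, :]          # (n, K)
    basis = np.cos(ang) @ subject.fourier_cos.T + np.sin(ang) @ subject.fourier_sin.T

    act = np.asarray(activations, dtype=float)
    deriv = np.gradient(act, axis=0) * 8.0                 # per-sample slope, rescaled
    mixed = act @ mix_act.T + deriv @ mix_deriv.T          # (n, 24)

    out = basis + coupling_gain * mixed
    out = out * subject.imu_gain[None, :] + subject.imu_offset[None, :]
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return out


@dataclass
class SyntheticTrial:
    subject_id: str
    trial_id: str
    speed: str
    emg: pd.DataFrame          # time_s + emg_<muscle> columns
    imu: pd.DataFrame          # time_s + 24 named channels
    heel_strikes: np.ndarray
    #: ground truth for oracles: muscle -> (n_strides, 101) realized envelopes
    truth_cycles: dict = field(default_factory=dict)
    #: muscle -> continuous true envelope on the EMG time grid
    truth_envelopes: dict = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    trials: list
    muscles: list
    config: GeneratorConfig
    seed: int

    def subjects(self) -> list:
        seen: dict = {}
        for tr in self.trials:
            seen.setdefault(tr.subject_id, None)
        return list(seen)


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(subject_id.encode())])


def _draw_subject(
    seed: int, subject_id: str, specs, cfg: GeneratorConfig
) -> SyntheticSubjectConfig:
    rng = _subject_rng(seed, subject_id)
    n_ch = len(IMU_CHANNELS)
    k = np.arange(1, cfg.n_harmonics + 1, dtype=float)
    return SyntheticSubjectConfig(
        subject_id=subject_id,
        stride_period_factor=float(rng.normal(1.0, 0.04)),
        stride_period_sd_s=0.03,
        muscle_amp_scale={
            m.name: float(rng.lognormal(0.0, cfg.subject_amp_sd)) for m in specs
        },
        burst_amp_mods={
            m.name: rng.lognormal(0.0, cfg.subject_burst_sd, size=len(m.bursts))
            for m in specs
        },
        imu_gain=rng.normal(1.0, 0.05, size=n_ch),
        imu_offset=rng.normal(0.0, 0.1, size=n_ch),
        fourier_cos=rng.normal(0.0, 1.0, size=(n_ch, cfg.n_harmonics)) / k[None, :],
        fourier_sin=rng.normal(0.0, 1.0, size=(n_ch, cfg.n_harmonics)) / k[None, :],
    )


def _phase_curve(t: np.ndarray, heel_strikes: np.ndarray) -> np.ndarray:
    """Continuous gait phase in % over the recording (stride index x 100)."""
    cum = np.interp(t, heel_strikes, np.arange(heel_strikes.size, dtype=float))
    return (cum % 1.0) * 100.0


def generate_study(
    n_subjects: int | None = None,
    trials_per_subject: int | None = None,
    strides_per_trial: int | None = None,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    specs: list | None = None,
    phase_locked: bool | None = None,
) -> SyntheticStudy:
    """Generate a full walking study; fully deterministic given ``seed``.

    Each subject walks ``trials_per_subject`` trials, cycling through the
    slow/normal/fast speed classes.  ``phase_locked`` defaults to True unless
    the config's ``coupling_gain`` is zero (negative-control mode), in which
    case burst timing is decoupled from the stride — see the module docstring.
    """
    cfg = config or GeneratorConfig()
    if n_subjects is not None:
        cfg.n_subjects = n_subjects
    if trials_per_subject is not None:
        cfg.trials_per_subject = trials_per_subject
    if strides_per_trial is not None:
        cfg.strides_per_trial = strides_per_trial
    if cfg.strides_per_trial < 1:
        raise ValueError("strides_per_trial must be >= 1")
    specs = specs or default_muscle_specs()
    if phase_locked is None:
        phase_locked = cfg.coupling_gain != 0.0

    study_rng = np.random.default_rng([seed, 0xC0FFEE])
    n_m = len(specs)
    mix_act = study_rng.normal(0.0, 0.35, size=(len(IMU_CHANNELS), n_m))
    mix_deriv = study_rng.normal(0.0, 0.35, size=(len(IMU_CHANNELS), n_m))
    spec_by_name = {m.name: m for m in specs}

    trials: list = []
    for si in range(cfg.n_subjects):
        sid = f"S{si + 1:02d}"
        subject = _draw_subject(seed, sid, specs, cfg)
        for ti in range(cfg.trials_per_subject):
            speed = SPEEDS[ti % len(SPEEDS)]
            rng = np.random.default_rng([seed, zlib.crc32(sid.encode()), ti])
            trials.append(
                _generate_trial(
                    subject, f"T{ti + 1:02d}", speed, specs, spec_by_name,
                    mix_act, mix_deriv, rng, cfg, phase_locked,
                )
            )
    return SyntheticStudy(trials, [m.name for m in specs], cfg, seed)


def _generate_trial(
    subject, trial_id, speed, specs, spec_by_name, mix_act, mix_deriv, rng, cfg,
    phase_locked,
) -> SyntheticTrial:
    n_strides = cfg.strides_per_trial
    period = STRIDE_PERIOD_S[speed] * subject.stride_period_factor
    durations = np.clip(
        rng.normal(period, subject.stride_period_sd_s, size=n_strides), 0.5, 2.2
    )
    heel_strikes = 0.5 + np.concatenate([[0.0], np.cumsum(durations)])
    total_s = heel_strikes[-1] + 0.3

    t_emg = np.arange(0.0, total_s, 1.0 / cfg.emg_fs)
    t_imu = np.arange(0.0, total_s, 1.0 / cfg.imu_fs)
    phase_emg = _phase_curve(t_emg, heel_strikes)
    phase_imu = _phase_curve(t_imu, heel_strikes)
    grid101 = np.linspace(0.0, 100.0, N_PHASE)

    # per-stride realized burst parameters, per muscle
    realized: dict = {}
    for m in specs:
        nb = len(m.bursts)
        base_centers = np.array([b.center_pct for b in m.bursts])
        scales = (
            subject.muscle_amp_scale[m.name]
            * subject.burst_amp_mods[m.name][None, :]
            * rng.lognormal(0.0, cfg.burst_amp_jitter_sd, size=(n_strides, nb))
        )
        if phase_locked:
            centers = (
                base_centers[None, :]
                + rng.normal(0.0, cfg.burst_center_jitter_pct, size=(n_strides, nb))
            ) % 100.0
        else:
            centers = rng.uniform(0.0, 100.0, size=(n_strides, nb))
        realized[m.name] = (scales, centers)

    def eval_act(name: str, t: np.ndarray, phase: np.ndarray) -> np.ndarray:
        spec = spec_by_name[name]
        scales, centers = realized[name]
        env = np.zeros_like(t)
        edges = np.searchsorted(t, heel_strikes)
        for k in range(n_strides):
            sl = slice(edges[k], edges[k + 1])
            env[sl] = activation_profile(
                spec, phase[sl], speed, scales[k], centers[k]
            )
        # outside [first, last) strike: keep the neighbouring stride's profile
        env[: edges[0]] = activation_profile(
            spec, phase[: edges[0]], speed, scales[0], centers[0]
        )
        env[edges[-1]:] = activation_profile(
            spec, phase[edges[-1]:], speed, scales[-1], centers[-1]
        )
        return env

    names = [m.name for m in specs]
    own_emg = {m.name: eval_act(m.name, t_emg, phase_emg) for m in specs}
    own_imu = {m.name: eval_act(m.name, t_imu, phase_imu) for m in specs}
    own_101 = {
        m.name: np.stack([
            activation_profile(m, grid101, speed, realized[m.name][0][k],
                               realized[m.name][1][k])
            for k in range(n_strides)
        ])
        for m in specs
    }

    def add_crosstalk(own: dict) -> dict:
        out = {}
        for m in specs:
            env = own[m.name].copy()
            if m.crosstalk is not None:
                src, frac = m.crosstalk
                env += frac * own[src]
            out[m.name] = env
        return out

    env_emg = add_crosstalk(own_emg)
    env_imu = add_crosstalk(own_imu)
    truth_cycles = add_crosstalk(own_101)

    emg_cols = {"time_s": t_emg}
    for name in names:
        emg_cols[f"emg_{name}"] = synthesize_raw_emg(
            env_emg[name], cfg.emg_fs, rng, cfg.emg_noise_sd,
            cfg.drift_amp_rel, cfg.impulse_rate_hz,
        ).samples[: t_emg.size]

    act_matrix = np.stack([env_imu[n] for n in names], axis=1)
    imu_block = imu_from_activations(
        subject, phase_imu, act_matrix, mix_act, mix_deriv, rng,
        noise_sd=cfg.imu_noise_sd, coupling_gain=cfg.coupling_gain,
    )
    imu_cols = {"time_s": t_imu}
    for ci, ch in enumerate(IMU_CHANNELS):
        imu_cols[ch] = imu_block[:, ci]

    return SyntheticTrial(
        subject_id=subject.subject_id,
        trial_id=trial_id,
        speed=speed,
        emg=pd.DataFrame(emg_cols),
        imu=pd.DataFrame(imu_cols),
        heel_strikes=heel_strikes,
        truth_cycles=truth_cycles,
        truth_envelopes=env_emg,
    )
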