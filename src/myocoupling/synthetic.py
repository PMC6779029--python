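"""Synthetic endurance-test cohorts with known ground truth.

Real recordings of this protocol (cyclic isokinetic wrist extension at
60 deg/s / flexion at 180 deg/s over a 70 deg range, ~2 s cycles, to
exhaustion) are not publicly available, so every stage of the pipeline is
exercised against generated subjects instead. The generator emulates the
statistical structure the analysis is built to measure:

* kinematics: trapezoidal velocity, integrated angle, a torque hump per
  half-cycle whose amplitude decays linearly with fatigue;
* muscle drives: a per-muscle activation shape over the cycle phase,
  multiplied by lognormal modulation that mixes a *shared* phase-locked
  fine-structure pattern (the common motor program, lagged per muscle)
  with *private* temporal noise; the shared-variance fraction starts at
  ``coupling0`` and decays exponentially per cycle — this is the
  load-sharing construct the cross-prediction index tracks, and because
  the shared pattern is time-lagged between muscles it is visible to the
  delay-embedded predictor but largely invisible to an instantaneous
  overlap measure;
* array EMG: Poisson motor-unit action-potential trains, rate-modulated by
  the drive, propagated across the 7 single-differential channels at a
  programmed conduction velocity, plus additive noise and optional
  movement artifacts.

All randomness flows from a single integer seed; identical configs give
bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .records import MUSCLES, CycleTable, Envelope, KinematicRecording, RawArrayRecording

__all__ = [
    "SubjectConfig",
    "CohortConfig",
    "SubjectData",
    "gen_cycle_durations",
    "gen_kinematics",
    "gen_coupled_drives",
    "gen_muscle_array",
    "gen_envelopes",
    "gen_subject",
    "cohort_configs",
    "gen_envelope_cohort",
]

# protocol geometry: 70 deg range at 60 deg/s up, 180 deg/s down
_ROM_DEG = 70.0
_V_EXT = 60.0
_V_FLEX = 180.0
_T_EXT = _ROM_DEG / _V_EXT     # 1.167 s
_T_FLEX = _ROM_DEG / _V_FLEX   # 0.389 s

#: Activation-shape centre (cycle phase in [0, 1)) and width per muscle.
#: Extensors peak during extension, FCR during flexion, so extensor pairs
#: overlap strongly while ECR-FCR overlaps weakly — the co-activation
#: ordering seen in real forearm recordings.
_SHAPE = {
    "ECR": (0.32, 0.18),
    "EDC": (0.38, 0.20),
    "ECU": (0.44, 0.20),
    "FCR": (0.88, 0.10),
}


@dataclass
class SubjectConfig:
    """Ground-truth parameters of one synthetic subject."""

    n_cycles: int = 60
    cycle_s: float = 2.0
    cycle_jitter: float = 0.02          # fractional SD of cycle duration
    cv_true: dict = field(default_factory=lambda: {
        "ECR": 4.0, "EDC": 4.5, "ECU": 5.0, "FCR": 4.2})
    firing_rate: float = 600.0          # composite MUAP rate at full drive, pps
    coupling0: dict = field(default_factory=lambda: {m: 0.97 for m in MUSCLES})
    #: per-cycle exponential decay of coupling; a float applies to every
    #: muscle, a dict sets per-muscle rates
    decay_rate: float | dict = 0.0165
    torque0: float = 12.0               # N*m, initial torque amplitude
    torque_final_frac: float = 0.3      # final/initial torque amplitude
    noise_snr: float = 15.0             # dB, EMG channel noise
    artifact_channels: dict = field(default_factory=dict)  # muscle -> [SD idx]
    lags: dict = field(default_factory=lambda: {
        "ECR": 0.00, "EDC": 0.05, "ECU": 0.10, "FCR": 0.15})  # s, shared-drive lag
    shape_amp: float = 0.1              # deterministic cyclic modulation depth
    shape_base: float = 0.35            # baseline activation level (never silent)
    fluct_sigma: float = 0.8            # stochastic (lognormal) modulation SD
    fluct_tau: float = 0.7              # correlation time of modulation, s
    env_noise: float = 0.01             # additive noise on direct envelopes
    pattern_harmonics: int = 6          # harmonics of the shared phase pattern
    pattern_subject_frac: float = 0.1   # subject-specific share of the pattern
    seed: int = 0
    fs_emg: float = 2048.0
    fs_kin: float = 100.0
    fs_env: float = 20.0
    ied: float = 0.005


@dataclass
class CohortConfig:
    """Two-group study design: control-like vs patient-like subjects.

    Groups differ only in the stated parameters: patients decay twice as
    fast and start with a lower shared-drive weight for the ECR, mirroring
    the deficit concentrated on ECR pairs.
    """

    n_per_group: int = 10
    control: dict = field(default_factory=lambda: {
        "decay_rate": 0.0165,
        "coupling0": {m: 0.97 for m in MUSCLES},
    })
    patient: dict = field(default_factory=lambda: {
        "decay_rate": 0.033,
        "coupling0": {"ECR": 0.93, "EDC": 0.97, "ECU": 0.97, "FCR": 0.97},
    })
    n_cycles_range: tuple = (60, 75)
    decay_subject_sd: float = 0.0       # lognormal between-subject spread of decay
    master_seed: int = 0


@dataclass
class SubjectData:
    """One fully generated subject (raw level)."""

    kin: KinematicRecording
    emg: dict
    drives: dict
    durations: np.ndarray
    truth: dict


def gen_cycle_durations(cfg: SubjectConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-cycle durations: mean cycle_s with multiplicative jitter."""
    jit = 1.0 + cfg.cycle_jitter * np.clip(rng.standard_normal(cfg.n_cycles), -3, 3)
    d = cfg.cycle_s * jit
    floor = (_T_EXT + _T_FLEX) * cfg.cycle_s / 2.0 + 0.1
    return np.maximum(d, floor)


def _timeline(durations: np.ndarray, fs: float):
    """Sample times, cycle index and within-cycle time for a cycle sequence."""
    edges = np.concatenate(([0.0], np.cumsum(durations)))
    n = int(np.floor(edges[-1] * fs))
    t = np.arange(n) / fs
    cyc = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(durations) - 1)
    tau = t - edges[cyc]
    return t, cyc, tau, edges


def gen_kinematics(
    cfg: SubjectConfig,
    durations: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> KinematicRecording:
    """Torque, angle and velocity traces at 100 Hz for one subject.

    Each cycle is [extension at +60 deg/s][pause][flexion at -180 deg/s]
    [pause]; jitter lives in the pauses so the isokinetic plateaus stay at
    the device velocities. Torque is a positive hump over the extension
    half and a smaller negative hump over the flexion half (zero crossings
    at the half boundaries), with amplitude decaying linearly to
    ``torque_final_frac`` of its initial value.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if durations is None:
        durations = gen_cycle_durations(cfg, rng)
    scale = cfg.cycle_s / 2.0
    t, cyc, tau, edges = _timeline(durations, cfg.fs_kin)
    d_c = durations[cyc]
    te = _T_EXT * scale
    tf = _T_FLEX * scale
    pause = (d_c - te - tf) / 2.0
    t_half = te + pause           # extension half-cycle end (per sample)

    velocity = np.zeros_like(t)
    velocity[tau < te] = _V_EXT
    in_flex = (tau >= t_half) & (tau < t_half + tf)
    velocity[in_flex] = -_V_FLEX
    # brief ramps for realism (30 ms moving average)
    w = max(1, int(round(0.03 * cfg.fs_kin)))
    velocity = np.convolve(velocity, np.ones(w) / w, mode="same")

    angle = -40.0 + np.cumsum(velocity) / cfg.fs_kin
    angle = np.clip(angle, -40.0, 30.0)

    n = len(durations)
    amp = cfg.torque0 * (1.0 + (cfg.torque_final_frac - 1.0) * cyc / max(n - 1, 1))
    torque = np.where(
        tau < t_half,
        amp * np.sin(np.pi * np.clip(tau / t_half, 0, 1)),
        -0.5 * amp * np.sin(np.pi * np.clip((tau - t_half) / (d_c - t_half), 0, 1)),
    )
    torque = torque + rng.normal(0.0, 0.02 * cfg.torque0, size=len(t))
    velocity = velocity + rng.normal(0.0, 0.5, size=len(t))
    angle = angle + rng.normal(0.0, 0.2, size=len(t))
    return KinematicRecording(torque=torque, angle=angle, velocity=velocity, fs=cfg.fs_kin)


def _ar1(n: int, fs: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance first-order autoregressive noise with time constant tau."""
    a = np.exp(-1.0 / (fs * tau))
    eps = rng.standard_normal(n)
    x = sps.lfilter([np.sqrt(1.0 - a * a)], [1.0, -a], eps)
    return x


def _periodic_pattern(rng: np.random.Generator, n_harmonics: int = 8):
    """Fixed smooth zero-mean, unit-variance random function of cycle phase."""
    a = rng.standard_normal(n_harmonics) / np.sqrt(np.arange(1, n_harmonics + 1))
    b = rng.standard_normal(n_harmonics) / np.sqrt(np.arange(1, n_harmonics + 1))
    norm = np.sqrt(0.5 * (a**2 + b**2).sum())

    def pattern(phase: np.ndarray) -> np.ndarray:
        out = np.zeros_like(phase)
        for j in range(n_harmonics):
            out += a[j] * np.cos(2 * np.pi * (j + 1) * phase)
            out += b[j] * np.sin(2 * np.pi * (j + 1) * phase)
        return out / norm

    return pattern


def gen_coupled_drives(
    cfg: SubjectConfig,
    durations: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    fs: float | None = None,
) -> dict:
    """Non-negative activation drives for the four muscles.

    drive_m(t) = shape_m(phase) * max(1 + sigma * mix_m(t), 0.05) with
    mix_m = sqrt(alpha_m) * U(phase - lag_m) + sqrt(1 - alpha_m) * v_m(t).

    U is a fixed smooth random function of cycle phase shared by all
    muscles — the within-cycle fine structure of the common motor program,
    reproduced (lagged per muscle) every cycle while coordination holds.
    v_m is private temporal noise. alpha_m(c) = coupling0_m *
    exp(-decay_rate * c) is the shared-variance fraction at cycle c: as it
    decays, the muscle's activation detail drifts from the shared program
    into idiosyncratic fluctuation. This is the construct the
    cross-prediction index measures — a phase-locked dynamical dependence
    between muscles, not the mere amplitude overlap a co-activation index
    captures.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if durations is None:
        durations = gen_cycle_durations(cfg, rng)
    fs = fs if fs is not None else cfg.fs_kin
    t, cyc, tau, edges = _timeline(durations, fs)
    d_c = durations[cyc]
    pf = tau / d_c
    n = len(t)

    # the task is identical for every subject, so the shared program is a
    # canonical pattern plus a subject-specific component
    canon = _periodic_pattern(np.random.default_rng(2**20 + cfg.pattern_harmonics),
                              cfg.pattern_harmonics)
    subj = _periodic_pattern(rng, cfg.pattern_harmonics)
    eta = cfg.pattern_subject_frac

    def shared(phase):
        return np.sqrt(1.0 - eta) * canon(phase) + np.sqrt(eta) * subj(phase)
    drives = {}
    for m in MUSCLES:
        c0, w0 = _SHAPE[m]
        dist = np.abs(pf - c0)
        dist = np.minimum(dist, 1.0 - dist)  # periodic phase distance
        shape = cfg.shape_base + cfg.shape_amp * np.exp(-0.5 * (dist / w0) ** 2)
        rate = cfg.decay_rate[m] if isinstance(cfg.decay_rate, dict) else cfg.decay_rate
        alpha = np.clip(cfg.coupling0.get(m, 0.85) * np.exp(-rate * cyc), 0.0, 1.0)
        phase_lag = (pf - cfg.lags.get(m, 0.0) / d_c) % 1.0
        u_m = shared(phase_lag)
        v_m = _ar1(n, fs, cfg.fluct_tau, rng)
        mix = np.sqrt(alpha) * u_m + np.sqrt(1.0 - alpha) * v_m
        # lognormal modulation: positive and smooth, so no clipping
        # nonlinearity eats into the predictable variance
        drives[m] = shape * np.exp(cfg.fluct_sigma * mix - 0.5 * cfg.fluct_sigma**2)
    return drives


def _biphasic_wavelet(fs: float, sigma_s: float = 0.0015) -> np.ndarray:
    """Biphasic MUAP-like wavelet (~10 ms support): Gaussian first derivative."""
    half = int(round(4 * sigma_s * fs))
    tw = np.arange(-half, half + 1) / fs
    w = -(tw / sigma_s) * np.exp(-0.5 * (tw / sigma_s) ** 2)
    return w


def _fractional_delay(x: np.ndarray, d_samples: float) -> np.ndarray:
    """Band-limited delay of x by a (fractional) number of samples."""
    n = len(x)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n)  # cycles/sample
    return np.fft.irfft(X * np.exp(-2j * np.pi * f * d_samples), n=n)


def gen_muscle_array(
    cfg: SubjectConfig,
    drive: np.ndarray,
    muscle: str,
    rng: np.random.Generator,
    drive_fs: float | None = None,
) -> RawArrayRecording:
    """7-channel single-differential array EMG for one muscle.

    A composite MUAP train fires as an inhomogeneous Poisson process with
    rate proportional to the drive; each successive channel is the same
    train delayed by ied / cv_true (band-limited fractional delay), plus
    white noise at ``noise_snr``. Channels listed in
    ``artifact_channels[muscle]`` receive low-frequency wander and spike
    bursts emulating movement artifacts.
    """
    cv = cfg.cv_true.get(muscle, 4.0)
    if cv <= 0:
        raise ValueError("cv_true must be positive")
    drive_fs = drive_fs if drive_fs is not None else cfg.fs_kin
    fs = cfg.fs_emg
    t_src = np.arange(len(drive)) / drive_fs
    n = int(np.floor(t_src[-1] * fs)) + 1
    t = np.arange(n) / fs
    dr = np.interp(t, t_src, drive)
    dmax = dr.max()
    if dmax <= 0:
        raise ValueError("drive must be non-negative with some activity")
    rate = cfg.firing_rate * dr / dmax
    fires = rng.random(n) < rate / fs
    train = np.zeros(n)
    train[fires] = rng.uniform(0.6, 1.4, size=int(fires.sum()))
    base = sps.fftconvolve(train, _biphasic_wavelet(fs), mode="same")
    rms = np.sqrt(np.mean(base**2))
    sigma_n = rms * 10 ** (-cfg.noise_snr / 20.0)
    delta = cfg.ied / cv * fs  # propagation delay between channels, samples
    channels = np.empty((7, n))
    for j in range(7):
        ch = _fractional_delay(base, j * delta) if j else base.copy()
        ch += rng.normal(0.0, sigma_n, n)
        channels[j] = ch
    for j in cfg.artifact_channels.get(muscle, []):
        f0 = rng.uniform(3.0, 8.0)
        phase = rng.uniform(0, 2 * np.pi)
        channels[j] += 20.0 * rms * np.sin(2 * np.pi * f0 * t + phase)
        n_spk = max(5, n // 20000)
        pos = rng.integers(0, n - 20, size=n_spk)
        for p in pos:
            width = int(rng.integers(3, 12))
            channels[j, p: p + width] += rng.choice([-1.0, 1.0]) * rng.uniform(15, 25) * rms
    return RawArrayRecording(muscle=muscle, channels=channels, fs=fs, ied=cfg.ied)


def _cycle_table(cfg: SubjectConfig, durations: np.ndarray) -> CycleTable:
    edges = np.concatenate(([0.0], np.cumsum(durations)))
    return CycleTable(
        onsets_kin=np.round(edges * cfg.fs_kin).astype(int),
        onsets_env=np.round(edges * cfg.fs_env).astype(int),
        durations=np.diff(edges),
        fs_kin=cfg.fs_kin,
        fs_env=cfg.fs_env,
    )


def gen_envelopes(cfg: SubjectConfig) -> tuple[dict, CycleTable, dict]:
    """Direct 20 Hz envelopes (post-preprocessing stage) for one subject.

    Skips the raw-EMG layer: the drives themselves, plus measurement noise,
    stand for the demodulated envelopes. Used for analysis-scale studies
    where the raw electrode physics is irrelevant.
    """
    rng = np.random.default_rng(cfg.seed)
    durations = gen_cycle_durations(cfg, rng)
    drives = gen_coupled_drives(cfg, durations, rng, fs=cfg.fs_env)
    envs = {}
    for m in MUSCLES:
        raw = np.clip(drives[m] + rng.normal(0.0, cfg.env_noise, len(drives[m])), 0.0, None)
        mean, std = float(raw.mean()), float(raw.std())
        envs[m] = Envelope(muscle=m, values=(raw - mean) / std, fs_env=cfg.fs_env,
                           mean=mean, std=std, raw=raw)
    cycles = _cycle_table(cfg, durations)
    truth = {
        "decay_rate": cfg.decay_rate,
        "coupling0": dict(cfg.coupling0),
        "cycle_s": float(np.mean(durations)),
        "n_cycles": cfg.n_cycles,
    }
    return envs, cycles, truth


def gen_subject(cfg: SubjectConfig) -> SubjectData:
    """Full raw-level subject: kinematics plus 4 x 7-channel array EMG."""
    rng = np.random.default_rng(cfg.seed)
    durations = gen_cycle_durations(cfg, rng)
    kin = gen_kinematics(cfg, durations, rng)
    drives = gen_coupled_drives(cfg, durations, rng, fs=cfg.fs_kin)
    emg = {m: gen_muscle_array(cfg, drives[m], m, rng) for m in MUSCLES}
    truth = {
        "decay_rate": cfg.decay_rate,
        "coupling0": dict(cfg.coupling0),
        "cv_true": dict(cfg.cv_true),
        "torque_final_frac": cfg.torque_final_frac,
        "cycle_s": float(np.mean(durations)),
        "n_cycles": cfg.n_cycles,
        "onset_times": np.concatenate(([0.0], np.cumsum(durations))),
    }
    return SubjectData(kin=kin, emg=emg, drives=drives, durations=durations, truth=truth)


def decay_probe_config(lam: float, seed: int, n_cycles: int = 50) -> SubjectConfig:
    """Conditions under which the programmed decay rate is identifiable.

    The sliding-course log-slope equals the coupling decay rate only when
    the course is proportional to the target's shared-variance fraction:
    the predictor muscle must supply a clean state (full, non-decaying
    coupling), the target starts fully coupled so the normalised course
    leaves from the estimator's noise-free point, the deterministic shape
    is removed so the decaying shared pattern carries the predictable
    variance, jitter is off so phase matching is index-exact, and the
    modulation is kept in the linear (unclipped) range. Decay is
    programmed on the target muscles only.
    """
    return SubjectConfig(
        seed=seed,
        n_cycles=n_cycles,
        cycle_jitter=0.0,
        shape_amp=0.0,
        fluct_sigma=0.5,
        env_noise=0.002,
        pattern_harmonics=4,
        coupling0={m: 1.0 for m in MUSCLES},
        decay_rate={"ECR": 0.0, "EDC": lam, "ECU": lam, "FCR": lam},
    )


def fit_decay_rate(norm_area: np.ndarray, floor: float = 0.7) -> float:
    """Log-linear slope of a sliding course, per cycle (positive = decay).

    Windows below ``floor`` are excluded: the R^2 response is proportional
    to the shared-variance fraction only near full coupling, and the slope
    bias grows as the clamp at zero is approached.
    """
    w = np.arange(len(norm_area), dtype=float)
    mask = np.isfinite(norm_area) & (norm_area >= floor)
    if mask.sum() < 5:
        raise ValueError("too few usable windows to fit a decay rate")
    return float(-np.polyfit(w[mask], np.log(norm_area[mask]), 1)[0])


def cohort_configs(ccfg: CohortConfig) -> list[tuple[str, str, SubjectConfig]]:
    """(subject_id, group, SubjectConfig) for every subject in the design.

    Subject seeds, cycle counts and the between-subject spread of the decay
    rate all derive deterministically from ``master_seed``.
    """
    rng = np.random.default_rng(ccfg.master_seed)
    out = []
    for group, overrides in (("control", ccfg.control), ("patient", ccfg.patient)):
        for i in range(ccfg.n_per_group):
            seed = int(rng.integers(0, 2**31 - 1))
            n_cycles = int(rng.integers(ccfg.n_cycles_range[0], ccfg.n_cycles_range[1] + 1))
            subj_decay = float(overrides.get("decay_rate", 0.01)
                               * np.exp(ccfg.decay_subject_sd * rng.standard_normal()))
            cfg = SubjectConfig(seed=seed, n_cycles=n_cycles, decay_rate=subj_decay)
            if "coupling0" in overrides:
                cfg = replace(cfg, coupling0=dict(overrides["coupling0"]))
            for key, val in overrides.items():
                if key not in ("decay_rate", "coupling0"):
                    cfg = replace(cfg, **{key: val})
            out.append((f"{group[:4]}{i + 1:02d}", group, cfg))
    return out


def gen_envelope_cohort(ccfg: CohortConfig):
    """Yield (subject_id, group, envelopes, cycles, truth) per subject."""
    for sid, group, cfg in cohort_configs(ccfg):
        envs, cycles, truth = gen_envelopes(cfg)
        yield sid, group, envs, cycles, truth
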