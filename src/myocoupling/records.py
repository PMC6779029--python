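"""Core data containers shared across the pipeline.

The containers mirror the stages of the analysis: raw linear-array EMG
(`RawArrayRecording`), dynamometer kinematics (`KinematicRecording`),
per-channel quality indices used for channel selection (`ChannelQuality`),
the demodulated 20 Hz activation envelope (`Envelope`) and the cycle
segmentation derived from torque zero-crossings (`CycleTable`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The four forearm muscles analysed in the wrist extension/flexion protocol.
MUSCLES = ("ECR", "EDC", "ECU", "FCR")

#: The six unordered muscle pairs, in canonical order.
MUSCLE_PAIRS = (
    ("ECR", "EDC"), ("ECR", "ECU"), ("ECR", "FCR"),
    ("EDC", "ECU"), ("EDC", "FCR"), ("ECU", "FCR"),
)

#: Pairs involving ECR (the muscle most affected in lateral epicondylitis).
ECR_PAIRS = (("ECR", "EDC"), ("ECR", "ECU"), ("ECR", "FCR"))


@dataclass
class RawArrayRecording:
    """One muscle's linear-array surface EMG.

    `channels` holds single-differential (or, after spatial filtering,
    double-differential) traces as a (n_channels, n_samples) array in volts.
    `ied` is the inter-electrode distance in metres along the fibre direction.
    """

    muscle: str
    channels: np.ndarray
    fs: float = 2048.0
    ied: float = 0.005

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.ied <= 0:
            raise ValueError("ied must be positive")
        if self.channels.ndim != 2 or self.channels.shape[0] < 2:
            raise ValueError("need a 2-D array with at least 2 channels")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class KinematicRecording:
    """Torque (N·m), joint angle (deg) and angular velocity (deg/s).

    `trigger_offset` is the time of the first kinematic sample relative to
    the start of the EMG recording (the synchronisation trigger), seconds.
    """

    torque: np.ndarray
    angle: np.ndarray
    velocity: np.ndarray
    fs: float = 100.0
    trigger_offset: float = 0.0

    def __post_init__(self) -> None:
        self.torque = np.asarray(self.torque, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not (len(self.torque) == len(self.angle) == len(self.velocity)):
            raise ValueError("torque, angle and velocity must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.torque)

    @property
    def times(self) -> np.ndarray:
        return self.trigger_offset + np.arange(self.n_samples) / self.fs


@dataclass
class ChannelQuality:
    """Quality indices of one double-differential channel.

    `cc` is the peak of the normalised cross-correlation with the adjacent
    DD channel; `cv` the conduction velocity (m/s) implied by the
    sub-sample delay at that peak. A zero delay makes `cv` undefined
    (`cv_valid` False). `artifact_flag` marks channels contaminated by
    movement artifacts.
    """

    dd_index: int
    cc: float
    cv: float
    cv_valid: bool = True
    artifact_flag: bool = False
    delay_s: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.cc <= 1.0 + 1e-12:
            raise ValueError("|cc| must be <= 1")


@dataclass
class Envelope:
    """Demodulated 20 Hz EMG envelope of one selected channel.

    `values` is the z-normalised envelope (zero mean, unit variance over the
    retained span); `raw` the non-negative envelope before normalisation,
    which co-activation analysis consumes. The removed (mean, std) are kept
    so the normalisation is invertible.
    """

    muscle: str
    values: np.ndarray
    fs_env: float = 20.0
    mean: float = 0.0
    std: float = 1.0
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.raw is not None:
            self.raw = np.asarray(self.raw, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CycleTable:
    """Extension/flexion cycles delimited by rising torque zero-crossings.

    `onsets_kin` are sample indices into the kinematic traces (fs_kin);
    `onsets_env` their equivalents on the 20 Hz envelope time base.
    `ext_ends_kin` holds the intermediate falling crossings (extension ->
    flexion boundary) between consecutive onsets. The total number of
    cycles (TNC) is ``len(onsets) - 1``.
    """

    onsets_kin: np.ndarray
    onsets_env: np.ndarray
    durations: np.ndarray
    fs_kin: float = 100.0
    fs_env: float = 20.0
    ext_ends_kin: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.onsets_kin = np.asarray(self.onsets_kin, dtype=int)
        self.onsets_env = np.asarray(self.onsets_env, dtype=int)
        self.durations = np.asarray(self.durations, dtype=float)
        if np.any(np.diff(self.onsets_kin) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.durations <= 0):
            raise ValueError("cycle durations must be positive")
        if len(self.durations) != len(self.onsets_kin) - 1:
            raise ValueError("durations must have len(onsets) - 1 entries")

    @property
    def n_cycles(self) -> int:
        """TNC: total number of cycles."""
        return len(self.onsets_kin) - 1

    @property
    def mean_duration(self) -> float:
        return float(np.mean(self.durations))
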