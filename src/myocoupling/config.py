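"""Run configuration: every protocol constant in one place.

Defaults are hard-wired to the recording and analysis protocol (20-350 Hz
band, CC > 0.7, 3-7 m/s CV gate, 400 ms demodulation window, 20 Hz
envelope rate, ED = 4, k = 3*ED = 12 neighbours, 10 s / 0.5 s horizons,
15-cycle windows, alpha = 0.05). A YAML file may override any field;
unknown keys are rejected. The loaded config is echoed into every output
for provenance.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # band-pass filtering
    band_low_hz: float = 20.0
    band_high_hz: float = 350.0
    filter_order: int = 4
    # channel selection gates
    cc_min: float = 0.7
    cv_low: float = 3.0
    cv_high: float = 7.0
    artifact_z_clip: float = 14.0
    artifact_low_power_frac: float = 0.2
    # envelope
    ma_ms: float = 400.0
    fs_env: float = 20.0
    # cycle segmentation
    torque_smooth_ms: float = 100.0
    min_half_cycle_s: float = 0.3
    # embedding / prediction
    ed: int = 4
    k_neighbors: int = 12
    theiler_window: int = 0
    target_mode: str = "scalar"  # or "vector"
    ph_long_s: float = 10.0
    ph_short_s: float = 0.5
    window_cycles: int = 15
    checkpoint_step_pct: float = 10.0
    # statistics
    alpha: float = 0.05
    holm: bool = False
    # focus pairs for staged/sliding analyses ("ecr" or "all")
    focus: str = "ecr"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """Load a RunConfig from YAML, applying keyword overrides on top."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    valid = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
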