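"""Delay embedding of activation envelopes.

A scalar envelope is lifted to a state-space trajectory by stacking
time-lagged samples: row t of the embedded matrix is
``[s_t, s_{t+DT}, ..., s_{t+(ED-1)DT}]``, giving P = NS - (ED-1)*DT rows
for a source of NS samples. With the embedding dimension fixed at 4 and
the delay set to a quarter of the movement cycle, each row summarises one
full extension/flexion cycle of activity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import CycleTable, Envelope

__all__ = ["EmbeddedSeries", "embed", "choose_dt"]


@dataclass
class EmbeddedSeries:
    """Trajectory matrix S (P x ED) with its embedding metadata."""

    S: np.ndarray
    ed: int
    dt: int
    ns: int

    @property
    def P(self) -> int:
        return self.S.shape[0]


def embed(env: Envelope | np.ndarray, ed: int = 4, dt: int = 10) -> EmbeddedSeries:
    """Build the delay-embedded trajectory matrix of an envelope (segment).

    ``S[i, j] = x[i + j*dt]`` with P = NS - (ed-1)*dt rows. Raises when the
    segment is too short for even a single row.
    """
    x = env.values if isinstance(env, Envelope) else np.asarray(env, float)
    if x.ndim != 1:
        raise ValueError("embed expects a 1-D series")
    if ed < 2 or dt < 1:
        raise ValueError("need ed >= 2 and dt >= 1")
    ns = len(x)
    p = ns - (ed - 1) * dt
    if p < 1:
        raise ValueError(
            f"segment too short to embed: NS={ns}, need NS >= {(ed - 1) * dt + 1} "
            f"for ED={ed}, DT={dt}"
        )
    S = np.lib.stride_tricks.sliding_window_view(x, (ed - 1) * dt + 1)[:, ::dt]
    return EmbeddedSeries(S=np.ascontiguousarray(S, dtype=float), ed=ed, dt=dt, ns=ns)


def choose_dt(cycles: CycleTable, fs_env: float = 20.0) -> int:
    """Delay = a quarter of the subject's mean cycle duration, in samples.

    For ~2 s cycles sampled at 20 Hz this gives DT ~ 10 samples; the floor
    of 1 guards degenerate (very fast) cycles. DT is a per-subject constant
    across the whole session.
    """
    return max(1, int(round(cycles.mean_duration / 4.0 * fs_env)))
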