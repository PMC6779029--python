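"""Reference co-activation index (CI) of a muscle pair.

CI_ab = 2 * integral of min(nEMG_a, nEMG_b) over a cycle divided by
(iEMG_a + iEMG_b), times 100, where nEMG is the *non-negative* envelope
normalised by its own standard deviation within each cycle and iEMG its
integral over the cycle. CI is symmetric, lives in [0, 100], and measures
the instantaneous overlap of activity — the classical load-sharing
measure the cross-prediction index is contrasted with. The z-normalised
envelope used for prediction is signed and would break the min()
semantics, so CI consumes the pre-normalisation envelope.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analyses import STAGES, stage_spans
from .records import CycleTable, Envelope

__all__ = ["CoactivationResult", "CISlidingCourse", "normalize_per_cycle",
           "coactivation_index", "ci_schemes"]


@dataclass
class CoactivationResult:
    """Per-cycle and aggregate CI (%) for an unordered muscle pair."""

    pair: tuple[str, str]
    ci_per_cycle: np.ndarray
    ci_aggregate: float
    scheme: str = "whole"
    cycle_span: tuple[int, int] | None = None


@dataclass
class CISlidingCourse:
    """15-cycle moving-window CI normalised to its initial value."""

    pair: tuple[str, str]
    tnc_grid: np.ndarray
    ci_windows: np.ndarray
    norm_ci: np.ndarray
    cum_pct: np.ndarray
    cum_ci: np.ndarray
    window_cycles: int = 15


def _raw_values(env) -> np.ndarray:
    if isinstance(env, Envelope):
        if env.raw is None:
            raise ValueError("Envelope has no pre-normalisation (non-negative) values")
        return env.raw
    x = np.asarray(env, float)
    if np.any(x < 0):
        raise ValueError("co-activation requires a non-negative envelope")
    return x


def normalize_per_cycle(env, cycles: CycleTable) -> np.ndarray:
    """Divide each cycle's samples by that cycle's standard deviation (nEMG)."""
    x = _raw_values(env).copy()
    for c in range(cycles.n_cycles):
        i0 = cycles.onsets_env[c]
        i1 = min(cycles.onsets_env[c + 1], len(x))
        sd = x[i0:i1].std()
        if sd == 0:
            raise ValueError(f"zero-variance cycle {c + 1}: cannot normalise")
        x[i0:i1] /= sd
    return x


def coactivation_index(
    nA: np.ndarray,
    nB: np.ndarray,
    cycles: CycleTable,
    pair: tuple[str, str] = ("a", "b"),
    scheme: str = "whole",
    span: tuple[int, int] | None = None,
) -> CoactivationResult:
    """Per-cycle CI by rectangular-sum integration; aggregate = mean over cycles.

    ``span`` restricts the aggregate to cycles first..last (1-based).
    """
    nA = np.asarray(nA, float)
    nB = np.asarray(nB, float)
    if nA.shape != nB.shape:
        raise ValueError("nEMG traces must have equal length")
    first, last = span if span is not None else (1, cycles.n_cycles)
    cis = np.empty(last - first + 1)
    for j, c in enumerate(range(first - 1, last)):
        i0 = cycles.onsets_env[c]
        i1 = min(cycles.onsets_env[c + 1], len(nA))
        a, b = nA[i0:i1], nB[i0:i1]
        denom = a.sum() + b.sum()
        if denom == 0:
            raise ValueError(f"zero total activity in cycle {c + 1}")
        cis[j] = 200.0 * np.minimum(a, b).sum() / denom
    return CoactivationResult(pair=pair, ci_per_cycle=cis,
                              ci_aggregate=float(cis.mean()), scheme=scheme,
                              cycle_span=(first, last))


def ci_schemes(
    envA,
    envB,
    cycles: CycleTable,
    pair: tuple[str, str] = ("a", "b"),
    window: int = 15,
    checkpoint_step: float = 10.0,
) -> dict:
    """CI under the same three schemes as the cross-prediction analyses.

    Returns ``{"whole": CoactivationResult, "stages": {stage: ...},
    "sliding": CISlidingCourse}``. The sliding course is the 15-cycle
    moving-window mean CI normalised to its initial value, with cumulative
    values every 10 %TNC.
    """
    nA = normalize_per_cycle(envA, cycles)
    nB = normalize_per_cycle(envB, cycles)
    whole = coactivation_index(nA, nB, cycles, pair=pair, scheme="whole")
    per_cycle = whole.ci_per_cycle
    stages = {}
    spans = stage_spans(cycles.n_cycles, window)
    for stage in STAGES:
        first, last = spans[stage]
        stages[stage] = CoactivationResult(
            pair=pair, ci_per_cycle=per_cycle[first - 1: last],
            ci_aggregate=float(per_cycle[first - 1: last].mean()),
            scheme="staged", cycle_span=(first, last))
    tnc = cycles.n_cycles
    n_off = tnc - window
    offsets = np.arange(n_off + 1)
    win_ci = np.array([per_cycle[w: w + window].mean() for w in offsets])
    norm = win_ci / win_ci[0]
    tnc_grid = offsets / max(n_off, 1) * 100.0
    cum_pct = np.arange(checkpoint_step, 100.0 + 1e-9, checkpoint_step)
    cum_ci = np.array([
        np.trapezoid(norm[tnc_grid <= q + 1e-9], tnc_grid[tnc_grid <= q + 1e-9])
        for q in cum_pct
    ])
    slide = CISlidingCourse(pair=pair, tnc_grid=tnc_grid, ci_windows=win_ci,
                            norm_ci=norm, cum_pct=cum_pct, cum_ci=cum_ci,
                            window_cycles=window)
    return {"whole": whole, "stages": stages, "sliding": slide}
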