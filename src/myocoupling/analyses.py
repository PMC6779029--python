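"""The three session-level cross-prediction schemes.

1. whole test: one R^2(PH) curve over the full session, area to PH = 10 s;
2. staged: the same index on three 15-cycle segments (initial, middle,
   final), which overlap when the subject completed fewer than 45 cycles;
3. sliding: the first 15 cycles of the predictor muscle, embedded once,
   predict a 15-cycle window of the target muscle advancing one cycle at
   a time; short-term area (PH <= 0.5 s) per window, normalised by its
   initial value, with cumulative values reported every 10% of the total
   number of cycles (%TNC).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .crosspred import AreaIndex, PredictionCurve, TemplatePredictor, area_under_r2, r2_curve
from .records import CycleTable, Envelope

__all__ = ["StageResult", "SlidingCourse", "stage_spans", "whole_test", "staged", "sliding"]

STAGES = ("initial", "middle", "final")


@dataclass
class StageResult:
    """Area index of one 15-cycle stage."""

    stage: str
    cycle_span: tuple[int, int]  # 1-based inclusive
    area: AreaIndex
    curve: PredictionCurve


@dataclass
class SlidingCourse:
    """Short-term predictability as a function of window position (%TNC)."""

    pair: tuple[str, str]
    tnc_grid: np.ndarray       # window start as %TNC
    areas: np.ndarray          # raw short-term areas
    norm_area: np.ndarray      # areas / areas[0]
    cum_pct: np.ndarray        # checkpoints (10, 20, ..., 100 %TNC)
    cum_area: np.ndarray       # cumulative normalised area at each checkpoint
    window_cycles: int = 15


def stage_spans(tnc: int, window: int = 15) -> dict[str, tuple[int, int]]:
    """1-based cycle spans of the initial, middle and final stages.

    The middle stage is the centered window, start = floor((TNC-15)/2)+1;
    spans overlap exactly when TNC < 3*window (45 cycles).
    """
    if tnc < window:
        raise ValueError(f"need at least {window} cycles, got {tnc}")
    mid = (tnc - window) // 2 + 1
    return {
        "initial": (1, window),
        "middle": (mid, mid + window - 1),
        "final": (tnc - window + 1, tnc),
    }


def _values(env) -> np.ndarray:
    return env.values if isinstance(env, Envelope) else np.asarray(env, float)


def _segment(env, cycles: CycleTable, first: int, last: int) -> np.ndarray:
    """Envelope samples of cycles first..last (1-based, inclusive)."""
    x = _values(env)
    i0 = cycles.onsets_env[first - 1]
    i1 = min(cycles.onsets_env[last], len(x))
    return x[i0:i1]


def whole_test(
    envA,
    envB,
    dt: int,
    ph_max_s: float = 10.0,
    ed: int = 4,
    k: int = 12,
    fs_env: float = 20.0,
    theiler: int = 0,
    target_mode: str = "scalar",
    pair: tuple[str, str] | None = None,
) -> tuple[PredictionCurve, AreaIndex]:
    """Full-session R^2(PH) curve and long-term area index."""
    a = _values(envA)
    need = 2 * ((ed - 1) * dt + int(round(ph_max_s * fs_env)))
    if len(a) < need:
        raise ValueError(
            f"session too short for whole-test analysis: {len(a)} samples, need >= {need}"
        )
    curve = r2_curve(envA, envB, ph_max_s=ph_max_s, ed=ed, dt=dt, k=k,
                     fs_env=fs_env, theiler=theiler, target_mode=target_mode, pair=pair)
    return curve, area_under_r2(curve, ph_max_s)


def staged(
    envA,
    envB,
    cycles: CycleTable,
    dt: int,
    window: int = 15,
    ph_max_s: float = 10.0,
    ed: int = 4,
    k: int = 12,
    fs_env: float = 20.0,
    theiler: int = 0,
    target_mode: str = "scalar",
    pair: tuple[str, str] | None = None,
) -> list[StageResult]:
    """Long-term area on the initial / middle / final 15-cycle stages."""
    spans = stage_spans(cycles.n_cycles, window)
    out = []
    for stage in STAGES:
        first, last = spans[stage]
        segA = _segment(envA, cycles, first, last)
        segB = _segment(envB, cycles, first, last)
        curve = r2_curve(segA, segB, ph_max_s=ph_max_s, ed=ed, dt=dt, k=k,
                         fs_env=fs_env, theiler=theiler, target_mode=target_mode, pair=pair)
        out.append(StageResult(stage=stage, cycle_span=(first, last), curve=curve,
                               area=area_under_r2(curve, ph_max_s)))
    return out


def sliding(
    envA,
    envB,
    cycles: CycleTable,
    dt: int,
    window: int = 15,
    ph_short_s: float = 0.5,
    ed: int = 4,
    k: int = 12,
    fs_env: float = 20.0,
    theiler: int = 0,
    checkpoint_step: float = 10.0,
    pair: tuple[str, str] | None = None,
) -> SlidingCourse:
    """Cycle-by-cycle course of short-term predictability.

    The template (A's first 15 cycles) is embedded once; window w of B
    covers cycles (1+w)..(15+w), sampled from the cycle onset so template
    rows map to phase-matched positions. Prediction horizons stay within
    the window (PH <= 0.5 s). The course is normalised by its value at
    0 %TNC, so it is exactly 1 there by construction.
    """
    tnc = cycles.n_cycles
    if tnc < window:
        raise ValueError(f"need at least {window} cycles, got {tnc}")
    if tnc == window:
        warnings.warn("TNC == window: sliding course has a single point", stacklevel=2)
    b = _values(envB)
    template = _segment(envA, cycles, 1, window)
    ph_grid = np.arange(1, int(round(ph_short_s * fs_env)) + 1)
    tp = TemplatePredictor(template, ph_grid, ed=ed, dt=dt, k=k, theiler=theiler)
    ns_t = len(template)
    n_off = tnc - window
    offsets = np.arange(n_off + 1)
    areas = np.empty(len(offsets))
    onsets = cycles.onsets_env
    # template sample -> (cycle, within-cycle phase fraction): windows are
    # sampled at the same phase fraction of the w-shifted cycle, so cycle
    # jitter does not misalign the template against the window
    j_abs = onsets[0] + np.arange(ns_t)
    cyc_of = np.clip(np.searchsorted(onsets, j_abs, side="right") - 1, 0, window - 1)
    len_t = (onsets[cyc_of + 1] - onsets[cyc_of]).astype(float)
    frac = (j_abs - onsets[cyc_of]) / len_t
    for w in offsets:
        len_w = (onsets[cyc_of + w + 1] - onsets[cyc_of + w]).astype(float)
        tgt = onsets[cyc_of + w] + np.round(frac * len_w).astype(int)
        tgt = np.minimum(tgt, onsets[cyc_of + w + 1] - 1)
        tgt = np.minimum(tgt, len(b) - 1)
        seg = b[tgt]
        areas[w] = float(tp.r2(seg).sum())
    if areas[0] <= 0:
        raise ValueError("initial window has zero short-term area: cannot normalise")
    norm = areas / areas[0]
    tnc_grid = offsets / max(n_off, 1) * 100.0
    cum_pct = np.arange(checkpoint_step, 100.0 + 1e-9, checkpoint_step)
    # cumulative area under the normalised course on the %TNC axis, so the
    # checkpoint values are comparable across subjects with different TNC
    cum_area = np.array([
        np.trapezoid(norm[tnc_grid <= q + 1e-9], tnc_grid[tnc_grid <= q + 1e-9])
        for q in cum_pct
    ])
    if pair is None:
        na = envA.muscle if isinstance(envA, Envelope) else "A"
        nb = envB.muscle if isinstance(envB, Envelope) else "B"
        pair = (na, nb)
    return SlidingCourse(pair=pair, tnc_grid=tnc_grid, areas=areas, norm_area=norm,
                         cum_pct=cum_pct, cum_area=cum_area, window_cycles=window)
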