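"""End-to-end orchestration: raw subject -> envelopes -> indices -> report.

Each step is a thin composition of the module functions, returning tidy
DataFrames keyed (subject, group, pair, ...) so the statistics layer and
the CSV outputs share one representation.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analyses, coactivation, preprocess, stats
from .config import RunConfig
from .embedding import choose_dt
from .records import ECR_PAIRS, MUSCLE_PAIRS, CycleTable, Envelope, KinematicRecording

__all__ = ["SubjectEnvelopes", "preprocess_subject", "analyze_subject",
           "run_cohort", "cohort_statistics", "write_report"]


@dataclass
class SubjectEnvelopes:
    """Quality-selected envelopes and cycle structure of one subject."""

    envelopes: dict[str, Envelope]
    qualities: dict
    cycles: CycleTable
    dt: int
    kin_summary: dict


def preprocess_subject(
    emg: dict, kin: KinematicRecording, cfg: RunConfig | None = None
) -> SubjectEnvelopes:
    """Filter, spatially filter, gate channels, demodulate and segment."""
    cfg = cfg or RunConfig()
    cycles = preprocess.segment_cycles(
        kin, fs_env=cfg.fs_env, smooth_ms=cfg.torque_smooth_ms,
        min_half_cycle_s=cfg.min_half_cycle_s)
    envelopes, qualities = {}, {}
    for muscle, rec in emg.items():
        filt = preprocess.bandpass_filter(rec, cfg.band_low_hz, cfg.band_high_hz,
                                          cfg.filter_order)
        dd = preprocess.compute_double_differential(filt)
        dd_raw = preprocess.compute_double_differential(rec)
        quals = preprocess.channel_quality(
            dd, unfiltered_dd=dd_raw, z_clip=cfg.artifact_z_clip,
            low_power_frac=cfg.artifact_low_power_frac)
        trace, best, all_q = preprocess.select_channel(
            dd, quals, cc_min=cfg.cc_min, cv_range=(cfg.cv_low, cfg.cv_high))
        envelopes[muscle] = preprocess.compute_envelope(
            trace, fs_in=rec.fs, ma_ms=cfg.ma_ms, fs_env=cfg.fs_env, muscle=muscle)
        qualities[muscle] = {"selected": best, "all": all_q}
    dt = choose_dt(cycles, cfg.fs_env)
    ks = preprocess.kinematic_summary(kin, cycles)
    return SubjectEnvelopes(envelopes=envelopes, qualities=qualities, cycles=cycles,
                            dt=dt, kin_summary=ks)


def _focus_pairs(cfg: RunConfig):
    return ECR_PAIRS if cfg.focus == "ecr" else MUSCLE_PAIRS


def analyze_subject(
    envelopes: dict[str, Envelope],
    cycles: CycleTable,
    dt: int,
    cfg: RunConfig | None = None,
    subject: str = "s01",
    group: str = "unknown",
) -> dict[str, pd.DataFrame]:
    """All three cross-prediction schemes plus the co-activation analogue.

    Whole-test areas cover all six ordered pairs; staged and sliding
    analyses cover the focus pairs (by default the three ECR pairs).
    Returns tidy frames: whole, staged, sliding, sliding_cum, ci_whole,
    ci_staged, ci_cum.
    """
    cfg = cfg or RunConfig()
    kw = dict(ed=cfg.ed, k=cfg.k_neighbors, fs_env=cfg.fs_env, theiler=cfg.theiler_window)
    meta = {"subject": subject, "group": group}
    whole_rows, staged_rows, slide_rows, cum_rows = [], [], [], []
    ci_whole_rows, ci_staged_rows, ci_cum_rows = [], [], []

    for a, b in MUSCLE_PAIRS:
        label = f"{a}-{b}"
        _, area = analyses.whole_test(
            envelopes[a], envelopes[b], dt, ph_max_s=cfg.ph_long_s,
            target_mode=cfg.target_mode, pair=(a, b), **kw)
        whole_rows.append({**meta, "pair": label, "area": area.area})

    for a, b in _focus_pairs(cfg):
        label = f"{a}-{b}"
        for sr in analyses.staged(envelopes[a], envelopes[b], cycles, dt,
                                  window=cfg.window_cycles, ph_max_s=cfg.ph_long_s,
                                  target_mode=cfg.target_mode, pair=(a, b), **kw):
            staged_rows.append({**meta, "pair": label, "stage": sr.stage,
                                "first_cycle": sr.cycle_span[0],
                                "last_cycle": sr.cycle_span[1], "area": sr.area.area})
        try:
            course = analyses.sliding(envelopes[a], envelopes[b], cycles, dt,
                                      window=cfg.window_cycles, ph_short_s=cfg.ph_short_s,
                                      checkpoint_step=cfg.checkpoint_step_pct,
                                      pair=(a, b), **kw)
        except ValueError as exc:
            # e.g. zero initial short-term area: course undefined for this
            # pair; downstream tables treat the missing cell as NA
            warnings.warn(f"{subject} {label}: sliding course unavailable ({exc})",
                          stacklevel=2)
        else:
            for pct, na in zip(course.tnc_grid, course.norm_area):
                slide_rows.append({**meta, "pair": label, "pct_tnc": pct, "norm_area": na})
            for pct, ca in zip(course.cum_pct, course.cum_area):
                cum_rows.append({**meta, "pair": label, "pct_tnc": pct, "cum_area": ca})

        ci = coactivation.ci_schemes(envelopes[a], envelopes[b], cycles, pair=(a, b),
                                     window=cfg.window_cycles,
                                     checkpoint_step=cfg.checkpoint_step_pct)
        ci_whole_rows.append({**meta, "pair": label, "ci": ci["whole"].ci_aggregate})
        for stage, res in ci["stages"].items():
            ci_staged_rows.append({**meta, "pair": label, "stage": stage,
                                   "ci": res.ci_aggregate})
        for pct, cc in zip(ci["sliding"].cum_pct, ci["sliding"].cum_ci):
            ci_cum_rows.append({**meta, "pair": label, "pct_tnc": pct, "cum_ci": cc})

    return {
        "whole": pd.DataFrame(whole_rows),
        "staged": pd.DataFrame(staged_rows),
        "sliding": pd.DataFrame(slide_rows),
        "sliding_cum": pd.DataFrame(cum_rows),
        "ci_whole": pd.DataFrame(ci_whole_rows),
        "ci_staged": pd.DataFrame(ci_staged_rows),
        "ci_cum": pd.DataFrame(ci_cum_rows),
    }


def run_cohort(subject_iter, cfg: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """Analyse every subject and concatenate the tidy frames.

    ``subject_iter`` yields either (sid, group, emg dict, kin) raw tuples
    or (sid, group, envelopes, cycles, truth) envelope-level tuples.
    """
    cfg = cfg or RunConfig()
    frames: dict[str, list] = {}
    kin_rows = []
    for item in subject_iter:
        sid, group = item[0], item[1]
        if isinstance(item[2], dict) and isinstance(
                next(iter(item[2].values())), Envelope):
            envelopes, cycles = item[2], item[3]
            dt = choose_dt(cycles, cfg.fs_env)
        else:
            emg, kin = item[2], item[3]
            try:
                se = preprocess_subject(emg, kin, cfg)
            except preprocess.ChannelSelectionError as exc:
                warnings.warn(f"subject {sid} excluded: {exc}", stacklevel=2)
                continue
            envelopes, cycles, dt = se.envelopes, se.cycles, se.dt
            kin_rows.append({"subject": sid, "group": group, **se.kin_summary["summary"]})
        res = analyze_subject(envelopes, cycles, dt, cfg, subject=sid, group=group)
        for key, df in res.items():
            frames.setdefault(key, []).append(df)
    out = {key: pd.concat(dfs, ignore_index=True) for key, dfs in frames.items()}
    if kin_rows:
        out["kinematics"] = pd.DataFrame(kin_rows)
    return out


def cohort_statistics(results: dict[str, pd.DataFrame],
                      cfg: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """The comparison tables: between-group and within-group contrasts."""
    cfg = cfg or RunConfig()
    alpha, holm = cfg.alpha, cfg.holm
    tables = {}
    tables["whole_between"] = stats.between_group_table(
        results["whole"], "area", keys=["pair"], alpha=alpha, holm=holm)
    tables["staged_between"] = stats.between_group_table(
        results["staged"], "area", keys=["pair", "stage"], alpha=alpha, holm=holm)
    tables["staged_contrasts"] = stats.stage_contrast_table(
        results["staged"], "area", alpha=alpha)
    tables["sliding_between"] = stats.between_group_table(
        results["sliding_cum"], "cum_area", keys=["pair", "pct_tnc"],
        alpha=alpha, holm=holm)
    tables["ci_whole_between"] = stats.between_group_table(
        results["ci_whole"], "ci", keys=["pair"], alpha=alpha, holm=holm)
    tables["ci_staged_between"] = stats.between_group_table(
        results["ci_staged"], "ci", keys=["pair", "stage"], alpha=alpha, holm=holm)
    tables["ci_staged_contrasts"] = stats.stage_contrast_table(
        results["ci_staged"], "ci", alpha=alpha)
    tables["ci_sliding_between"] = stats.between_group_table(
        results["ci_cum"], "cum_ci", keys=["pair", "pct_tnc"], alpha=alpha, holm=holm)
    if "kinematics" in results:
        kin_long = results["kinematics"].melt(
            id_vars=["subject", "group"], var_name="variable", value_name="value")
        tables["kinematics_between"] = stats.between_group_table(
            kin_long, "value", keys=["variable"], alpha=alpha)
    return tables


def _plot_group_courses(results, outdir):  # pragma: no cover - thin plotting glue
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results["sliding"]
    fig, axes = plt.subplots(1, df["pair"].nunique(), figsize=(12, 3.5),
                             sharey=True, squeeze=False)
    for ax, (pair, sub) in zip(axes[0], df.groupby("pair", sort=False)):
        for group, g in sub.groupby("group"):
            m = g.groupby(g["pct_tnc"].round(0))["norm_area"].mean()
            ax.plot(m.index, m.values, label=group)
        ax.set_title(pair)
        ax.set_xlabel("%TNC")
    axes[0][0].set_ylabel("normalised short-term area")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(os.path.join(outdir, "sliding_courses.png"), dpi=120)
    plt.close(fig)


def write_report(results: dict[str, pd.DataFrame], outdir: str,
                 cfg: RunConfig | None = None, plots: bool = True) -> dict:
    """Write tidy CSVs, statistics tables (CSV + markdown) and plots."""
    cfg = cfg or RunConfig()
    os.makedirs(outdir, exist_ok=True)
    for key, df in results.items():
        df.to_csv(os.path.join(outdir, f"{key}.csv"), index=False)
    tables = cohort_statistics(results, cfg)
    md_lines = ["# Group comparison report", ""]
    for key, df in tables.items():
        df.to_csv(os.path.join(outdir, f"stats_{key}.csv"), index=False)
        md_lines += [f"## {key}", "", df.to_markdown(index=False), ""]
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write("\n".join(md_lines))
    from .config import save_config
    save_config(cfg, os.path.join(outdir, "config_used.yaml"))
    if plots and "sliding" in results and len(results["sliding"]):
        _plot_group_courses(results, outdir)
    return tables
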