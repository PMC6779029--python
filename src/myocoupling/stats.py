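"""Non-parametric statistics for the two-group endurance design.

Small samples (10 per group) and mostly non-normal indices call for
rank-based tests: Lilliefors-corrected Kolmogorov-Smirnov for normality
screening, Wilcoxon signed-rank for paired within-group contrasts
(stage vs stage) and Mann-Whitney U for between-group comparisons, all
two-sided at alpha = 0.05. Exact p-values are used whenever sample sizes
permit and no ties are present; otherwise the normal approximation with
tie and continuity corrections. No multiple-testing correction is applied
by default (per-comparison alpha), with Holm available as an option.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupStats",
    "ks_normality",
    "mann_whitney",
    "wilcoxon_paired",
    "holm_correction",
    "between_group_table",
    "stage_contrast_table",
]

STAGE_CONTRASTS = (("initial", "middle"), ("middle", "final"), ("initial", "final"))


@dataclass
class GroupStats:
    """Result of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def ks_normality(sample, alpha: float = 0.05) -> GroupStats:
    """Kolmogorov-Smirnov normality test with estimated moments.

    Uses the Lilliefors correction: the naive KS test against a normal
    with sample-estimated mean and SD is anti-conservative.
    """
    x = np.asarray(sample, float)
    if len(x) < 3:
        raise ValueError("normality test requires n >= 3")
    if x.std() == 0:
        raise ValueError("constant sample: normality test undefined (std = 0)")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return GroupStats(test="ks_normality", statistic=float(stat), p_value=float(p),
                      n1=len(x), alpha=alpha)


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(x, y, alpha: float = 0.05) -> GroupStats:
    """Two-sided Mann-Whitney U between two independent samples.

    Exact distribution when both n <= 25 and there are no ties; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    exact = max(len(x), len(y)) <= 25 and not _has_ties(np.concatenate([x, y]))
    res = sst.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return GroupStats(test="mann_whitney_u", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n1=len(x), n2=len(y), alpha=alpha)


def wilcoxon_paired(x, y, alpha: float = 0.05) -> GroupStats:
    """Two-sided Wilcoxon signed-rank test on paired samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired test requires equal lengths")
    d = x - y
    if np.all(d == 0):
        raise ValueError("all paired differences are zero: test undefined")
    nz = d[d != 0]
    exact = len(nz) <= 25 and not _has_ties(np.abs(nz))
    res = sst.wilcoxon(x, y, alternative="two-sided", zero_method="wilcox",
                       method="exact" if exact else "approx", correction=not exact)
    return GroupStats(test="wilcoxon_signed_rank", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n1=len(x), n2=len(y), alpha=alpha)


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def between_group_table(
    df: pd.DataFrame,
    value: str,
    keys: list[str],
    group_col: str = "group",
    groups: tuple[str, str] = ("control", "patient"),
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Mann-Whitney between the two groups for every combination of keys.

    One row per key combination with group means, U, p and significance;
    missing cells produce an explicit NA row with the reason.
    """
    rows = []
    for key_vals, sub in df.groupby(keys, sort=False):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        x = sub.loc[sub[group_col] == groups[0], value].dropna().to_numpy()
        y = sub.loc[sub[group_col] == groups[1], value].dropna().to_numpy()
        row = dict(zip(keys, key_vals))
        row.update({
            f"{groups[0]}_mean": x.mean() if len(x) else np.nan,
            f"{groups[0]}_sd": x.std(ddof=1) if len(x) > 1 else np.nan,
            f"{groups[1]}_mean": y.mean() if len(y) else np.nan,
            f"{groups[1]}_sd": y.std(ddof=1) if len(y) > 1 else np.nan,
            "n1": len(x), "n2": len(y),
        })
        if len(x) == 0 or len(y) == 0:
            row.update({"U": np.nan, "p": np.nan, "significant": pd.NA,
                        "note": "missing group"})
        else:
            r = mann_whitney(x, y, alpha=alpha)
            row.update({"U": r.statistic, "p": r.p_value,
                        "significant": r.significant, "note": ""})
        rows.append(row)
    out = pd.DataFrame(rows)
    if holm and len(out):
        ok = out["p"].notna()
        out.loc[ok, "p_holm"] = holm_correction(out.loc[ok, "p"].to_numpy())
        out.loc[ok, "significant"] = out.loc[ok, "p_holm"] <= alpha
    return out


def stage_contrast_table(
    df: pd.DataFrame,
    value: str,
    pair_col: str = "pair",
    stage_col: str = "stage",
    subject_col: str = "subject",
    group_col: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Within-group paired Wilcoxon contrasts between stages.

    For each group and muscle pair: Initial-Middle, Middle-Final and
    Initial-Final contrasts over matched subjects. Cells that cannot be
    computed (missing stage, all-zero differences) are reported as NA with
    the reason.
    """
    rows = []
    for (group, pair), sub in df.groupby([group_col, pair_col], sort=False):
        wide = sub.pivot_table(index=subject_col, columns=stage_col, values=value)
        for s1, s2 in STAGE_CONTRASTS:
            row = {group_col: group, pair_col: pair, "contrast": f"{s1}-{s2}"}
            if s1 not in wide.columns or s2 not in wide.columns:
                row.update({"W": np.nan, "p": np.nan, "significant": pd.NA,
                            "note": "missing stage"})
            else:
                paired = wide[[s1, s2]].dropna()
                try:
                    r = wilcoxon_paired(paired[s1].to_numpy(), paired[s2].to_numpy(),
                                        alpha=alpha)
                    row.update({"W": r.statistic, "p": r.p_value,
                                "significant": r.significant, "n": len(paired),
                                "note": ""})
                except ValueError as e:
                    row.update({"W": np.nan, "p": np.nan, "significant": pd.NA,
                                "n": len(paired), "note": str(e)})
            rows.append(row)
    return pd.DataFrame(rows)
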