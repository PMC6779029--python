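"""Non-parametric tests against brute-force enumeration oracles."""
from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from myocoupling.stats import (
    between_group_table,
    holm_correction,
    ks_normality,
    mann_whitney,
    stage_contrast_table,
    wilcoxon_paired,
)


def exact_mannwhitney_p(x, y):
    """Two-sided p by enumerating all group assignments of the pooled sample."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    obs = min(obs, n1 * len(y) - obs)  # smaller-tail U
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        u = min(u, n1 * len(y) - u)
        count += u <= obs + 1e-12
        total += 1
    return count / total


def exact_wilcoxon_p(x, y):
    """Two-sided p by enumerating all sign patterns of the differences."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    w_obs = min(w_obs, ranks.sum() - w_obs)
    count = total = 0
    for signs in product([0, 1], repeat=len(d)):
        w = ranks[np.asarray(signs, bool)].sum()
        w = min(w, ranks.sum() - w)
        count += w <= w_obs + 1e-12
        total += 1
    return count / total


class TestMannWhitney:
    def test_two_vs_two_exact(self):
        r = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert r.statistic == 0
        assert r.p_value == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(rng.integers(3, 8))
        y = rng.standard_normal(rng.integers(3, 8))
        r = mann_whitney(x, y)
        assert r.p_value == pytest.approx(exact_mannwhitney_p(x, y), abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        x, y = rng.standard_normal(9), rng.standard_normal(7)
        assert mann_whitney(x, y).p_value == pytest.approx(
            mann_whitney(y, x).p_value, abs=1e-12)

    def test_type_one_error_near_alpha(self):
        rng = np.random.default_rng(42)
        rej = sum(mann_whitney(rng.standard_normal(10), rng.standard_normal(10)).p_value <= 0.05
                  for _ in range(400))
        assert 0.02 <= rej / 400 <= 0.08


class TestWilcoxon:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.standard_normal(7)
        y = x + rng.standard_normal(7)
        r = wilcoxon_paired(x, y)
        assert r.p_value == pytest.approx(exact_wilcoxon_p(x, y), abs=1e-12)

    def test_identical_pairs_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1.0, 2.0], [1.0])


class TestKsNormality:
    def test_normal_sample_usually_passes(self):
        rng = np.random.default_rng(7)
        ps = [ks_normality(rng.standard_normal(1000)).p_value for _ in range(30)]
        assert np.mean(np.asarray(ps) > 0.05) >= 0.8

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(8)
        ps = [ks_normality(rng.exponential(size=1000)).p_value for _ in range(10)]
        assert all(p < 0.05 for p in ps)

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(50))

    def test_tiny_sample_errors(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])


class TestHolm:
    def test_adjusted_values_bounded_and_ordered(self):
        p = np.array([0.001, 0.04, 0.03, 0.9])
        adj = holm_correction(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)


class TestTables:
    def _df(self):
        rng = np.random.default_rng(0)
        rows = []
        for g, shift in (("control", 0.0), ("patient", 2.0)):
            for s in range(8):
                for stage in ("initial", "middle", "final"):
                    bump = {"initial": 0.0, "middle": 0.5, "final": 1.5}[stage]
                    rows.append({"subject": f"{g}{s}", "group": g, "pair": "ECR-FCR",
                                 "stage": stage,
                                 "area": rng.standard_normal() + shift + bump})
        return pd.DataFrame(rows)

    def test_between_group_table_detects_shift(self):
        tab = between_group_table(self._df(), "area", keys=["pair", "stage"])
        assert len(tab) == 3
        assert (tab["n1"] == 8).all()
        assert tab["p"].min() < 0.05

    def test_missing_group_reported_as_na(self):
        df = self._df()
        df = df[df["group"] == "control"]
        tab = between_group_table(df, "area", keys=["pair", "stage"])
        assert tab["p"].isna().all()
        assert (tab["note"] == "missing group").all()

    def test_stage_contrasts_structure(self):
        tab = stage_contrast_table(self._df(), "area")
        assert set(tab["contrast"]) == {"initial-middle", "middle-final", "initial-final"}
        assert len(tab) == 6  # 2 groups x 3 contrasts
        # the programmed initial-vs-final bump is detected
        sig = tab[tab["contrast"] == "initial-final"]["p"] < 0.05
        assert sig.all()
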