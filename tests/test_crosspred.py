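"""Locally linear cross-prediction: oracle equivalence and behaviour.

The reference implementation below is a deliberately naive re-statement of
the algorithm (per-point loops, explicit sorting, explicit truncated-SVD
least squares) kept independent of the vectorised engine.
"""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myocoupling.crosspred import (
    PredictionCurve,
    TemplatePredictor,
    area_under_r2,
    find_neighbors,
    local_linear_predict,
    r2_curve,
)
from myocoupling.embedding import embed

from conftest import periodic_envelope

# truncation constants of the published fit: numerical rank cutoff plus a
# noise floor at a tenth of the signal's global scale
RCOND = 1e-8
SPREAD_FRAC = 0.1


def brute_force_r2(a, b, ph_grid, ed, dt, k):
    """Independent per-point reference implementation."""
    E = embed(a, ed, dt)
    P = E.P
    scale = E.S.std()
    maxidx = min(P - 1, len(b) - 1)
    out = []
    for ph in ph_grid:
        cutoff = maxidx - ph
        preds, truth = [], []
        for t in range(cutoff + 1):
            d = np.sum((E.S - E.S[t]) ** 2, axis=1)
            cand = sorted((i for i in range(P) if i != t and i + ph <= maxidx),
                          key=lambda i: (d[i], i))[:k]
            Xn = E.S[cand]
            y = b[np.asarray(cand) + ph]
            xm, ym = Xn.mean(axis=0), y.mean()
            U, s, Vt = np.linalg.svd(Xn - xm, full_matrices=False)
            keep = s > max(RCOND * s[0], SPREAD_FRAC * scale * np.sqrt(k))
            w = Vt[keep].T @ ((U[:, keep].T @ (y - ym)) / s[keep])
            preds.append(ym + (E.S[t] - xm) @ w)
            truth.append(b[t + ph])
        preds, truth = np.asarray(preds), np.asarray(truth)
        sst = np.sum((truth - truth.mean()) ** 2)
        out.append(float(np.clip(1 - np.sum((truth - preds) ** 2) / sst, 0, 1)))
    return np.asarray(out)


class TestOracleEquivalence:
    @pytest.mark.parametrize("case", range(20))
    def test_random_series_match_reference(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(30, 51))
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        ph_grid = np.arange(1, 6)
        fast = r2_curve(a, b, ph_max_s=5 / 20, ed=4, dt=3, k=5, fs_env=20.0).r2
        ref = brute_force_r2(a, b, ph_grid, ed=4, dt=3, k=5)
        assert np.allclose(fast, ref, atol=1e-8)

    def test_template_predictor_matches_generic_engine(self, rng):
        a, b = rng.standard_normal(600), rng.standard_normal(600)
        tp = TemplatePredictor(a, np.arange(1, 11), ed=4, dt=10, k=12)
        assert np.allclose(tp.r2(b), r2_curve(a, b, ph_max_s=0.5, dt=10, k=12).r2,
                           atol=1e-10)


class TestFindNeighbors:
    def test_exact_duplicate_ranked_first(self, rng):
        x = rng.standard_normal(60)
        x[40:44] = x[10:14]  # plant a duplicate state
        E = embed(x, ed=4, dt=1)
        nbrs = find_neighbors(E, 10, k=3, ph=1)
        assert nbrs[0] == 40

    def test_matches_exhaustive_sort(self, rng):
        x = rng.standard_normal(26)
        E = embed(x, ed=4, dt=2)  # 20 rows
        for q in (0, 7, 19):
            d = np.sum((E.S - E.S[q]) ** 2, axis=1)
            ref = sorted((i for i in range(E.P) if i != q and i + 2 <= E.P - 1),
                         key=lambda i: (d[i], i))[:3]
            assert list(find_neighbors(E, q, k=3, ph=2)) == ref

    def test_insufficient_neighbors_raise(self, rng):
        E = embed(rng.standard_normal(35), ed=4, dt=1)
        with pytest.raises(ValueError, match="eligible"):
            find_neighbors(E, 0, k=12, ph=30)


class TestLocalLinearPredict:
    def test_exact_on_affine_truth(self, rng):
        x = rng.standard_normal(80)
        E = embed(x, ed=4, dt=2)
        w_true = np.array([0.5, -1.2, 2.0, 0.3])
        ph = 3
        target = np.zeros(E.P + ph)
        for i in range(E.P):
            target[i + ph] = E.S[i] @ w_true + 0.7
        for t in (0, 10, 30):
            pred = local_linear_predict(E, target, t, ph=ph, k=8)
            assert pred == pytest.approx(E.S[t] @ w_true + 0.7, abs=1e-8)

    def test_degenerate_neighbourhood_returns_target_mean(self):
        x = np.zeros(40)
        E = embed(x, ed=4, dt=1)
        target = np.arange(40.0)
        pred = local_linear_predict(E, target, 5, ph=1, k=4)
        nbrs = find_neighbors(E, 5, k=4, ph=1)
        assert pred == pytest.approx(target[nbrs + 1].mean())


class TestR2Curve:
    def test_self_prediction_periodic(self):
        x = periodic_envelope()
        c = r2_curve(x, x, ph_max_s=10, dt=10, k=12)
        assert c.r2.min() >= 0.99

    def test_independent_noise_pairs_unpredictable(self):
        means = []
        for i in range(5):
            r = np.random.default_rng(100 + i)
            c = r2_curve(r.standard_normal(600), r.standard_normal(600),
                         ph_max_s=10, dt=10, k=12)
            means.append(c.r2.mean())
        assert max(means) < 0.15

    def test_delayed_pair_beats_null(self):
        x = periodic_envelope(600, noise=0.02)
        y = np.roll(x, 3)
        c = r2_curve(x, y, ph_max_s=2, dt=10, k=12)
        null = []
        for i in range(20):
            r = np.random.default_rng(300 + i)
            null.append(r2_curve(r.standard_normal(600), r.standard_normal(600),
                                 ph_max_s=2, dt=10, k=12).r2)
        q99 = np.quantile(np.asarray(null), 0.99, axis=0)
        assert np.all(c.r2 >= q99)

    def test_deterministic_bit_identical(self, rng):
        a, b = rng.standard_normal(400), rng.standard_normal(400)
        c1 = r2_curve(a, b, ph_max_s=1, dt=10, k=12)
        c2 = r2_curve(a.copy(), b.copy(), ph_max_s=1, dt=10, k=12)
        assert np.array_equal(c1.r2, c2.r2)

    def test_constant_target_errors(self):
        with pytest.raises(ValueError, match="SST"):
            r2_curve(np.random.default_rng(0).standard_normal(200),
                     np.ones(200), ph_max_s=0.5, dt=5, k=5)

    def test_vector_target_mode_bounded(self, rng):
        a, b = rng.standard_normal(300), rng.standard_normal(300)
        c = r2_curve(a, b, ph_max_s=1, dt=5, k=8, target_mode="vector")
        assert np.all((c.r2 >= 0) & (c.r2 <= 1))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_r2_always_clamped(self, seed):
        r = np.random.default_rng(seed)
        c = r2_curve(r.standard_normal(120), r.standard_normal(120),
                     ph_max_s=0.25, dt=3, k=5)
        assert np.all((c.r2 >= 0.0) & (c.r2 <= 1.0))


class TestAreaIndex:
    def _curve(self, value, n=200):
        return PredictionCurve(("A", "B"), np.arange(1, n + 1), np.full(n, value), 100)

    def test_full_r2_gives_grid_maximum(self):
        assert area_under_r2(self._curve(1.0), 10.0).area == pytest.approx(200.0)

    def test_table_magnitude_convention(self):
        # constant 0.4 over 10 s -> 80, the magnitude regime of the
        # whole-test coupling index on a 0-200 scale
        assert area_under_r2(self._curve(0.4), 10.0).area == pytest.approx(80.0)

    def test_short_term_grid(self):
        a = area_under_r2(self._curve(1.0, 10), 0.5)
        assert a.area == pytest.approx(10.0)
        assert a.n_grid == 10

    def test_insufficient_curve_raises(self):
        with pytest.raises(ValueError):
            area_under_r2(self._curve(1.0, 10), 10.0)
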