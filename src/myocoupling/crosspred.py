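"""Locally linear k-nearest-neighbour cross-prediction between envelopes.

One muscle's delay-embedded envelope serves as the state space; for every
state (row) the k nearest neighbouring states are found (leave-one-out),
an affine map from those neighbours to the *target* muscle's envelope a
prediction horizon PH ahead is fitted by least squares, and the map is
evaluated at the query state. Goodness of prediction over all admissible
query points, R^2 = 1 - SSE/SST (clamped to [0, 1]), is reported as a
function of PH; the area under the R^2-vs-PH curve is the coupling index.

Two code paths produce identical numbers: the readable per-point API
(`find_neighbors`, `local_linear_predict`) and a vectorised engine used by
`r2_curve` and the sliding-window `TemplatePredictor`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddedSeries, embed
from .records import Envelope

__all__ = [
    "PredictionCurve",
    "AreaIndex",
    "find_neighbors",
    "local_linear_predict",
    "r2_curve",
    "area_under_r2",
    "TemplatePredictor",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictionCurve:
    """R^2 as a function of prediction horizon for an ordered muscle pair."""

    pair: tuple[str, str]
    ph_grid: np.ndarray  # horizons in envelope samples (1 sample = 50 ms at 20 Hz)
    r2: np.ndarray
    n_points: int
    fs_env: float = 20.0

    def __post_init__(self) -> None:
        self.ph_grid = np.asarray(self.ph_grid, dtype=int)
        self.r2 = np.asarray(self.r2, dtype=float)
        if len(self.ph_grid) != len(self.r2):
            raise ValueError("ph_grid and r2 must have equal length")
        if np.any(np.diff(self.ph_grid) <= 0):
            raise ValueError("ph_grid must be strictly increasing")

    @property
    def ph_seconds(self) -> np.ndarray:
        return self.ph_grid / self.fs_env


@dataclass
class AreaIndex:
    """Sum of R^2 over the PH grid up to ph_max (unitless, max = n_grid)."""

    pair: tuple[str, str]
    area: float
    ph_max_s: float
    n_grid: int


def _values(env) -> np.ndarray:
    return env.values if isinstance(env, Envelope) else np.asarray(env, float)


def find_neighbors(
    E: EmbeddedSeries,
    query_row: int,
    k: int,
    ph: int = 0,
    theiler: int = 0,
    max_index: int | None = None,
) -> np.ndarray:
    """Indices of the k rows nearest to ``query_row`` (Euclidean distance).

    The query row itself is excluded (leave-one-out), as is any row whose
    future image ``row + ph`` would fall beyond the last usable index.
    Ties are broken by lower row index. ``theiler`` optionally excludes
    temporal neighbours within that many rows of the query (default 0:
    pure leave-one-out).
    """
    P = E.P
    limit = P - 1 if max_index is None else min(P - 1, max_index)
    d = np.einsum("ij,ij->i", E.S - E.S[query_row], E.S - E.S[query_row])
    idx = np.arange(P)
    mask = (idx != query_row) & (idx + ph <= limit)
    if theiler > 0:
        mask &= np.abs(idx - query_row) > theiler
    cand = idx[mask]
    if len(cand) < k:
        raise ValueError(
            f"only {len(cand)} eligible neighbours for query {query_row} at PH={ph} "
            f"(need k={k}): segment too short for this horizon"
        )
    order = np.lexsort((cand, d[cand]))
    return cand[order][:k]


def local_linear_predict(
    E_pred: EmbeddedSeries,
    target: np.ndarray,
    t: int,
    ph: int,
    k: int,
    theiler: int = 0,
) -> float:
    """Affine local model fitted on the k neighbours, evaluated at row t.

    The model maps neighbour rows of the predictor embedding to the target
    signal's values at (neighbour index + ph); rank-deficient systems are
    solved by minimum-norm least squares. A fully degenerate neighbourhood
    (all rows identical) falls back to the neighbour-target mean.
    """
    target = np.asarray(target, float)
    nbrs = find_neighbors(E_pred, t, k, ph=ph, theiler=theiler,
                          max_index=len(target) - 1)
    Xn = E_pred.S[nbrs]
    y = target[nbrs + ph]
    if np.all(np.ptp(Xn, axis=0) == 0):
        logger.debug("degenerate neighbourhood at t=%d: using neighbour-target mean", t)
        return float(y.mean())
    xm, ym = Xn.mean(axis=0), y.mean()
    U, s, Vt = np.linalg.svd(Xn - xm, full_matrices=False)
    keep = s > _svd_tol(s[0], k, float(E_pred.S.std()))
    w = Vt[keep].T @ ((U[:, keep].T @ (y - ym)) / s[keep])
    return float(ym + (E_pred.S[t] - xm) @ w)


def _neighbor_table(S: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-row candidate neighbours, the nearest m first (ties by index)."""
    sq = np.einsum("ij,ij->i", S, S)
    D = sq[:, None] + sq[None, :] - 2.0 * (S @ S.T)
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, np.inf)
    P = S.shape[0]
    m = min(m, P - 1)
    idx = np.argpartition(D, m - 1, axis=1)[:, :m]
    idx.sort(axis=1)  # ascending index, so the stable distance sort breaks ties low
    sub = np.take_along_axis(D, idx, axis=1)
    order = np.argsort(sub, axis=1, kind="stable")
    return np.take_along_axis(idx, order, axis=1), D


def _select_neighbors(
    nbr_tab: np.ndarray,
    D: np.ndarray,
    queries: np.ndarray,
    cutoff: int,
    k: int,
    theiler: int,
) -> np.ndarray:
    """First k eligible candidates per query; rare misses re-sort the full row."""
    nb = nbr_tab[queries]
    elig = nb <= cutoff
    if theiler > 0:
        elig &= np.abs(nb - queries[:, None]) > theiler
    cnt = np.cumsum(elig, axis=1)
    nbrs = np.empty((len(queries), k), dtype=int)
    sel = elig & (cnt <= k)
    qq, cc = np.nonzero(sel)
    nbrs[qq, cnt[qq, cc] - 1] = nb[qq, cc]
    short = np.nonzero(cnt[:, -1] < k)[0]
    for r in short:  # candidate table exhausted: fall back to the full row
        q = queries[r]
        d = D[q]
        idx = np.arange(len(d))
        mask = (idx <= cutoff) & (idx != q)
        if theiler > 0:
            mask &= np.abs(idx - q) > theiler
        cand = idx[mask]
        if len(cand) < k:
            raise ValueError(
                f"only {len(cand)} eligible neighbours at query {q} (need k={k}): "
                "segment too short for this horizon"
            )
        order = np.lexsort((cand, d[cand]))
        nbrs[r] = cand[order][:k]
    return nbrs


#: Truncation rule of the local least-squares fit. A direction of the
#: centered neighbourhood whose singular value falls below _SPREAD_FRAC of
#: the envelope's global scale (times sqrt(k), the singular value a
#: per-coordinate spread of that size would produce) is dominated by
#: measurement noise rather than state information: fitting along it only
#: amplifies target noise. Truncated directions degrade the fit gracefully
#: toward the neighbour-target mean — the zeroth-order fallback of locally
#: linear forecasting — which is exact when all neighbour rows coincide
#: (noise-free periodic envelopes). _RCOND is the purely numerical rank
#: cutoff. The same rule applies to every fit path, so the vectorised
#: engine and a plain per-point SVD implementation agree exactly.
_RCOND = 1e-8
_SPREAD_FRAC = 0.1


def _svd_tol(s_max, k: int, scale: float):
    """Singular-value cutoff combining numerical rank and the noise floor."""
    return np.maximum(_RCOND * s_max, _SPREAD_FRAC * scale * np.sqrt(k))


def _fit_predict(Xn: np.ndarray, Y: np.ndarray, xq: np.ndarray, scale: float) -> np.ndarray:
    """Batched affine least squares in centered form, with truncation.

    The intercept is carried by the neighbourhood means (identical to the
    ED+1-coefficient affine solution when full rank), so the singular-value
    truncation acts on the coordinate block only and the fit is equivariant
    under common rescaling of the envelopes (``scale`` is the global scale
    of the embedded signal and rescales with it). Solved via the
    eigendecomposition of the centered normal matrix: its eigenvalues are
    the squared singular values, its eigenvectors the right singular
    vectors.
    """
    k = Xn.shape[1]
    xm = Xn.mean(axis=1, keepdims=True)
    ym = Y.mean(axis=1, keepdims=True)
    Xc = Xn - xm
    Yc = Y - ym
    G = Xc.transpose(0, 2, 1) @ Xc
    B = Xc.transpose(0, 2, 1) @ Yc
    ev, V = np.linalg.eigh(G)
    tol = _svd_tol(np.sqrt(np.maximum(ev[:, -1:], 0.0)), k, scale) ** 2
    inv = np.where(ev > tol, 1.0 / np.where(ev > 0, ev, 1.0), 0.0)
    W = V @ (inv[:, :, None] * (V.transpose(0, 2, 1) @ B))
    return ym[:, 0] + np.einsum("ne,ned->nd", xq - xm[:, 0], W)


def _r2_for_grid(
    E: EmbeddedSeries,
    T: np.ndarray,
    ph_grid: np.ndarray,
    k: int,
    theiler: int = 0,
) -> np.ndarray:
    """R^2(PH) of predicting the columns of T (len L x dy) from embedding E."""
    S = E.S
    P = E.P
    if T.ndim == 1:
        T = T[:, None]
    maxidx = min(P - 1, len(T) - 1)
    nbr_tab, D = _neighbor_table(S, m=max(4 * k, 64))
    scale = float(S.std())
    r2 = np.empty(len(ph_grid))
    for gi, ph in enumerate(ph_grid):
        cutoff = maxidx - ph
        if cutoff < k:
            raise ValueError(
                f"PH={ph}: only {max(cutoff + 1, 0)} admissible points (need > k={k})"
            )
        q = np.arange(cutoff + 1)
        nbrs = _select_neighbors(nbr_tab, D, q, cutoff, k, theiler)
        preds = _fit_predict(S[nbrs], T[nbrs + ph], S[q], scale)
        truth = T[q + ph]
        sst = np.sum((truth - truth.mean(axis=0)) ** 2, axis=0)
        if np.any(sst == 0):
            raise ValueError(f"constant target over admissible points at PH={ph}: SST = 0")
        sse = np.sum((truth - preds) ** 2, axis=0)
        r2[gi] = float(np.mean(np.clip(1.0 - sse / sst, 0.0, 1.0)))
    return r2


def r2_curve(
    envA,
    envB,
    ph_max_s: float = 10.0,
    ed: int = 4,
    dt: int = 10,
    k: int = 12,
    fs_env: float = 20.0,
    theiler: int = 0,
    target_mode: str = "scalar",
    pair: tuple[str, str] | None = None,
) -> PredictionCurve:
    """Leave-one-out R^2(PH) curve predicting envB from envA's embedding.

    PH runs over every envelope sample (50 ms at 20 Hz) from 1 to
    ``ph_max_s * fs_env``. ``target_mode`` selects what is predicted: the
    target's scalar future sample (default) or its full embedded vector
    (R^2 averaged across coordinates).
    """
    a = _values(envA)
    b = _values(envB)
    E = embed(a, ed=ed, dt=dt)
    if target_mode == "scalar":
        T = b[:, None]
    elif target_mode == "vector":
        T = embed(b, ed=ed, dt=dt).S
    else:
        raise ValueError("target_mode must be 'scalar' or 'vector'")
    ph_grid = np.arange(1, int(round(ph_max_s * fs_env)) + 1)
    r2 = _r2_for_grid(E, T, ph_grid, k=k, theiler=theiler)
    if pair is None:
        na = envA.muscle if isinstance(envA, Envelope) else "A"
        nb_ = envB.muscle if isinstance(envB, Envelope) else "B"
        pair = (na, nb_)
    return PredictionCurve(pair=pair, ph_grid=ph_grid, r2=r2, n_points=E.P, fs_env=fs_env)


def area_under_r2(curve: PredictionCurve, ph_max_s: float) -> AreaIndex:
    """Sum of R^2 over grid points with PH <= ph_max (10 s long-term -> 200
    points; 0.5 s short-term -> 10 points)."""
    n = int(round(ph_max_s * curve.fs_env))
    mask = curve.ph_grid <= n
    if curve.ph_grid[-1] < n:
        raise ValueError(f"curve covers PH up to {curve.ph_grid[-1]} samples, need {n}")
    return AreaIndex(pair=curve.pair, area=float(curve.r2[mask].sum()),
                     ph_max_s=ph_max_s, n_grid=int(mask.sum()))


class TemplatePredictor:
    """Cross-prediction from a fixed template embedding to sliding targets.

    The template (typically the first 15 cycles of the predictor muscle) is
    embedded once; because the fitted prediction is linear in the target
    values, per-query weight vectors can be precomputed so each new target
    window costs only a weighted gather. Numbers are identical to
    `r2_curve` run on (template, window).
    """

    def __init__(
        self,
        template,
        ph_grid: np.ndarray,
        ed: int = 4,
        dt: int = 10,
        k: int = 12,
        theiler: int = 0,
    ) -> None:
        self.E = embed(_values(template), ed=ed, dt=dt)
        self.ph_grid = np.asarray(ph_grid, dtype=int)
        self.k = k
        self.theiler = theiler
        S = self.E.S
        P = self.E.P
        scale = float(S.std())
        nbr_tab, D = _neighbor_table(S, m=max(4 * k, 64))
        self._plans: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for ph in self.ph_grid:
            cutoff = P - 1 - ph
            if cutoff < k:
                raise ValueError(f"template too short for PH={ph} with k={k}")
            q = np.arange(cutoff + 1)
            nbrs = _select_neighbors(nbr_tab, D, q, cutoff, k, theiler)
            Xn = S[nbrs]
            xm = Xn.mean(axis=1)
            U, s, Vt = np.linalg.svd(Xn - xm[:, None], full_matrices=False)
            keep = s > _svd_tol(s[:, :1], k, scale)
            s_inv = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
            pinv = Vt.transpose(0, 2, 1) @ (s_inv[:, :, None] * U.transpose(0, 2, 1))
            # prediction is linear in the targets: ym + (xq - xm) W (y - ym)
            # collapses to a single weight vector per query
            g = np.einsum("ne,nek->nk", S[q] - xm, pinv)
            H = g + (1.0 - g.sum(axis=1, keepdims=True)) / k
            self._plans.append((q, nbrs, H))

    def r2(self, target: np.ndarray) -> np.ndarray:
        """R^2 at each precomputed PH for one target window.

        The window must provide at least P samples (the template's row
        count); shorter windows fall back to the generic engine restricted
        to the available indices.
        """
        y = np.asarray(target, float)
        if len(y) < self.E.P:
            return _r2_for_grid(self.E, y[:, None], self.ph_grid,
                                k=self.k, theiler=self.theiler)
        out = np.empty(len(self.ph_grid))
        for gi, ph in enumerate(self.ph_grid):
            q, nbrs, H = self._plans[gi]
            preds = np.sum(H * y[nbrs + ph], axis=1)
            truth = y[q + ph]
            sst = np.sum((truth - truth.mean()) ** 2)
            if sst == 0:
                raise ValueError(f"constant target over admissible points at PH={ph}")
            out[gi] = float(np.clip(1.0 - np.sum((truth - preds) ** 2) / sst, 0.0, 1.0))
        return out
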