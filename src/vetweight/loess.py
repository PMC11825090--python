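"""Local polynomial regression (loess) with data-driven span selection.

A vectorised tricube-weighted local regression smoother of degree 1 or 2 on a
single predictor, with the smoothing span selected by minimising either the
bias-corrected AIC for nonparametric smoothers,

    AICc = log(sigma_hat^2) + 1 + 2 (tr(L) + 1) / (n - tr(L) - 2),

or generalised cross-validation,

    GCV = sigma_hat^2 / (1 - tr(L)/n)^2,

where ``L`` is the smoother ("hat") matrix and ``sigma_hat^2`` the mean squared
residual.  The trace is accumulated exactly from each observation's leverage on
its own fit, so no n-by-n matrix is formed.  Windows are the ``k`` nearest
neighbours in the predictor (k = ceil(span * n)), located on the sorted data.
"""

from __future__ import annotations

import numpy as np

_CHUNK = 512


class DegenerateInputError(ValueError):
    """All predictor values in some window coincide; no local fit exists."""


def _windows(xs: np.ndarray, x0: np.ndarray, k: int) -> np.ndarray:
    """Start index of the k-nearest-neighbour window in sorted ``xs``.

    For sorted data the optimal window is contiguous; the best start ``j``
    balances the distances to the two window edges, located by a binary search
    on the nondecreasing edge-sum sequence c[j] = xs[j] + xs[j+k-1].
    """
    n = len(xs)
    c = xs[: n - k + 1] + xs[k - 1 :]
    j = np.searchsorted(c, 2.0 * x0, side="left")
    j = np.clip(j, 0, n - k)
    # compare j-1 and j; pick the smaller max-edge distance
    jm = np.maximum(j - 1, 0)
    d_j = np.maximum(x0 - xs[j], xs[j + k - 1] - x0)
    d_jm = np.maximum(x0 - xs[jm], xs[jm + k - 1] - x0)
    return np.where(d_jm < d_j, jm, j)


def _local_fit(
    xs: np.ndarray,
    ys: np.ndarray,
    x0: np.ndarray,
    k: int,
    degree: int,
    leverage: bool,
    cs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Fitted values at ``x0``; optionally each point's own hat diagonal.

    ``cs`` are optional per-observation weights multiplying the tricube
    kernel.  With ``leverage=True`` the points ``x0`` must be the training
    points themselves (the hat value uses the tricube weight 1 at distance 0,
    times the point's own observation weight).
    """
    n = len(xs)
    fit = np.empty(len(x0))
    lev = np.empty(len(x0)) if leverage else None
    for lo in range(0, len(x0), _CHUNK):
        sl = slice(lo, lo + _CHUNK)
        xb = x0[sl]
        j = _windows(xs, xb, k)
        idx = j[:, None] + np.arange(k)[None, :]
        xw = xs[idx]
        yw = ys[idx]
        dx = xw - xb[:, None]
        dmax = np.abs(dx).max(axis=1)
        if np.any(dmax == 0):
            raise DegenerateInputError("constant predictor within a window")
        w = (1.0 - np.abs(dx / dmax[:, None]) ** 3) ** 3
        if cs is not None:
            w = w * cs[idx]
        if degree == 1:
            s0 = w.sum(1)
            s1 = (w * dx).sum(1)
            s2 = (w * dx * dx).sum(1)
            det = s0 * s2 - s1 * s1
            t0 = (w * yw).sum(1)
            t1 = (w * dx * yw).sum(1)
            fit[sl] = (s2 * t0 - s1 * t1) / det
            if leverage:
                # x0 is xs itself here, so the own observation weight is cs[sl]
                c_own = cs[sl] if cs is not None else 1.0
                lev[sl] = c_own * s2 / det  # own tricube weight is 1 at dx = 0
        elif degree == 2:
            powers = np.stack([np.ones_like(dx), dx, dx * dx], axis=2)
            A = np.einsum("ij,ijp,ijq->ipq", w, powers, powers)
            b = np.einsum("ij,ijp,ij->ip", w, powers, yw)
            sol = np.linalg.solve(A, b[..., None])[..., 0]
            fit[sl] = sol[:, 0]
            if leverage:
                e0 = np.tile([1.0, 0.0, 0.0], (len(xb), 1))[..., None]
                Ainv0 = np.linalg.solve(A, e0)[..., 0]
                c_own = cs[sl] if cs is not None else 1.0
                lev[sl] = c_own * Ainv0[:, 0]
        else:
            raise ValueError("degree must be 1 or 2")
    return fit, lev


class LoessSmoother:
    """Tricube local polynomial smoother on one predictor.

    Parameters
    ----------
    x, y : arrays of equal length (unsorted accepted).
    span : fraction of points in each local window, in (0, 1].
    degree : local polynomial degree, 1 or 2.
    weights : optional per-observation weights (e.g. bin counts); they
        multiply the tricube kernel and are normalised to mean 1 for the
        selection criteria.
    """

    def __init__(self, x, y, span: float, degree: int = 1, weights=None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be equal-length 1-d arrays")
        if np.ptp(x) == 0:
            raise DegenerateInputError("predictor is constant")
        order = np.argsort(x, kind="stable")
        self.xs = x[order]
        self.ys = y[order]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)[order]
            if np.any(weights <= 0):
                raise ValueError("weights must be positive")
            weights = weights / weights.mean()
        self.cs = weights
        self.span = float(span)
        self.degree = int(degree)
        self.k = max(self.degree + 2, int(np.ceil(self.span * len(x))))
        self.k = min(self.k, len(x))

    def predict(self, x_new) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=float)
        fit, _ = _local_fit(
            self.xs, self.ys, x_new, self.k, self.degree, False, self.cs
        )
        return fit

    def criterion(self, which: str = "aicc") -> float:
        """AICc or GCV of this fit (np.inf when the fit saturates)."""
        fit, lev = _local_fit(
            self.xs, self.ys, self.xs, self.k, self.degree, True, self.cs
        )
        n = len(self.xs)
        trace = float(lev.sum())
        resid2 = (self.ys - fit) ** 2
        if self.cs is not None:
            resid2 = self.cs * resid2
        sigma2 = float(np.mean(resid2))
        if sigma2 <= 0:
            sigma2 = np.finfo(float).tiny
        if which == "aicc":
            denom = n - trace - 2.0
            if denom <= 0:
                return np.inf
            return float(np.log(sigma2) + 1.0 + 2.0 * (trace + 1.0) / denom)
        if which == "gcv":
            if trace >= n:
                return np.inf
            return float(sigma2 / (1.0 - trace / n) ** 2)
        raise ValueError("criterion must be 'aicc' or 'gcv'")


def select_span(
    x,
    y,
    criterion: str = "aicc",
    degree: int = 1,
    bounds: tuple[float, float] = (0.05, 0.95),
    coarse_step: float = 0.1,
    tol: float = 0.01,
    weights=None,
) -> tuple[float, float]:
    """Span minimising the criterion: coarse scan then golden-section refine.

    Returns ``(span, criterion_value)``.
    """
    lo, hi = bounds

    cache: dict[float, float] = {}

    def f(s: float) -> float:
        s = round(s, 6)
        if s not in cache:
            cache[s] = LoessSmoother(x, y, s, degree, weights).criterion(criterion)
        return cache[s]

    grid = np.arange(lo, hi + 1e-9, coarse_step)
    vals = [f(s) for s in grid]
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    while b - a > tol:
        if f(c) < f(d):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    best = min(cache, key=cache.get)
    return float(best), float(cache[best])
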