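"""Periodic cubic smoothing splines.

Fits, per data column, the minimizer of

    sum_i (y_i - s(t_i))^2 + lam * int_0^T s''(t)^2 dt

over periodic cubic splines with breakpoints at the data sites.  With
``lam = 0`` this reduces to the periodic interpolating cubic spline.
Evaluation and derivatives are analytic (B-spline form).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["PeriodicSmoothingSpline", "choose_smoothing_gcv"]


class PeriodicSmoothingSpline:
    """Periodic smoothing spline shared across many data columns.

    Parameters
    ----------
    times : (n,) strictly increasing sample times inside one period.
    values : (n,) or (n, m) samples; each column is fitted independently.
    period : period T > times[-1] - times[0].
    lam : smoothing weight >= 0 (0 = interpolation).
    """

    def __init__(self, times, values, period, lam=0.0):
        t = np.asarray(times, dtype=float)
        y = np.asarray(values, dtype=float)
        if t.ndim != 1 or len(t) < 4:
            raise ValueError("need at least 4 sample times")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if not (period > t[-1] - t[0]):
            raise ValueError("period must exceed the sampled time span")
        if lam < 0:
            raise ValueError("smoothing weight must be >= 0")
        self._scalar = y.ndim == 1
        y2 = y[:, None] if self._scalar else y
        if y2.shape[0] != len(t):
            raise ValueError("values and times length mismatch")

        self.period = float(period)
        self.t0 = float(t[0])
        self.lam = float(lam)
        n = len(t)
        breaks = np.concatenate([t, [t[0] + period]])
        self.knots = np.concatenate([t[-3:] - period, breaks, t[1:4] + period])
        self._n = n

        D = self._basis_matrix(t, nu=0)
        if lam == 0.0:
            coef = np.linalg.solve(D, y2) if n == D.shape[1] else np.linalg.lstsq(D, y2, rcond=None)[0]
        else:
            Om = self._penalty_matrix()
            G = D.T @ D + lam * Om
            coef = np.linalg.solve(G, D.T @ y2)
        self.coef = coef  # (n, m)
        self._D_fit = D

    # ------------------------------------------------------------------
    def _full_basis(self, x, nu=0):
        """(len(x), n+3) matrix of the extended B-spline basis (deriv nu)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        nb = self._n + 3
        if nu == 0:
            return BSpline.design_matrix(x, self.knots, 3).toarray()
        out = np.empty((len(x), nb))
        e = np.zeros(nb)
        for j in range(nb):
            e[j] = 1.0
            out[:, j] = BSpline(self.knots, e, 3)(x, nu=nu)
            e[j] = 0.0
        return out

    def _fold(self, M):
        n = self._n
        F = M[:, :n].copy()
        F[:, :3] += M[:, n : n + 3]
        return F

    def _basis_matrix(self, x, nu=0):
        return self._fold(self._full_basis(x, nu))

    def _penalty_matrix(self):
        # B'' is piecewise linear: 2-point Gauss per break interval is exact.
        br = np.concatenate(
            [self.knots[3 : 3 + self._n], [self.t0 + self.period]]
        )
        a, b = br[:-1], br[1:]
        h = b - a
        gp = np.concatenate(
            [a + h * (0.5 - 0.5 / np.sqrt(3)), a + h * (0.5 + 0.5 / np.sqrt(3))]
        )
        gw = np.concatenate([h / 2, h / 2])
        B2 = self._basis_matrix(gp, nu=2)
        return (B2 * gw[:, None]).T @ B2

    def _wrap(self, t):
        return (np.asarray(t, dtype=float) - self.t0) % self.period + self.t0

    # ------------------------------------------------------------------
    def __call__(self, t, nu=0):
        """Evaluate the spline (or its nu-th derivative) at times ``t``.

        Times are wrapped into the base period, making the result exactly
        periodic.  Returns shape ``t.shape + (m,)`` (column axis dropped
        for scalar fits).
        """
        tw = self._wrap(t)
        scalar_t = np.isscalar(t) or np.ndim(t) == 0
        B = self._basis_matrix(np.atleast_1d(tw), nu=nu)
        out = B @ self.coef
        if self._scalar:
            out = out[:, 0]
        if scalar_t:
            out = out[0]
        return out


def choose_smoothing_gcv(times, values, period, grid=None):
    """Pick a smoothing weight by generalized cross-validation.

    Scans a logarithmic grid and returns the weight minimizing the pooled
    GCV score across all value columns.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    y2 = y[:, None] if y.ndim == 1 else y
    n = len(t)
    if grid is None:
        span = (period / n) ** 3  # natural scale of the penalty
        grid = span * np.logspace(-4, 4, 17)
    best, best_score = 0.0, np.inf
    ref = PeriodicSmoothingSpline(t, y2, period, lam=0.0)
    D = ref._basis_matrix(t, 0)
    Om = ref._penalty_matrix()
    DtD = D.T @ D
    Dty = D.T @ y2
    for lam in grid:
        G = DtD + lam * Om
        coef = np.linalg.solve(G, Dty)
        H = D @ np.linalg.solve(G, D.T)
        tr = float(np.trace(H))
        resid = y2 - D @ coef
        rss = float((resid**2).sum()) / y2.shape[1]
        score = n * rss / max((n - tr) ** 2, 1e-300)
        if score < best_score:
            best, best_score = float(lam), score
    return best
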