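"""Natural cubic smoothing splines parameterised by effective degrees of freedom.

The smoother solves

    min_f  sum_i (y_i - f(x_i))^2  +  lam * int f''(t)^2 dt

over natural cubic splines with knots at the observation points
(Reinsch form).  Rather than exposing the penalty ``lam`` directly, the
public entry point takes the effective degrees of freedom
``df = trace(S_lam)`` of the smoother matrix, the parameterisation used
throughout growth-curve work, and solves for ``lam`` by root finding.

Limits: ``df = 2`` recovers the ordinary least-squares straight line
(the null space of the roughness penalty) and ``df = n`` recovers the
natural-spline interpolant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

__all__ = ["SplineFit", "smoothing_spline", "smoother_matrix", "effective_df"]

#: tolerance on trace(S) - df when solving for the penalty
DF_TOL = 1e-3


def _reinsch_matrices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Band matrices Q (n, n-2) and R (n-2, n-2) with K = Q R^-1 Q^T."""
    h = np.diff(x)
    n = x.size
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(n - 2):
        Q[j, j] = 1.0 / h[j]
        Q[j + 1, j] = -1.0 / h[j] - 1.0 / h[j + 1]
        Q[j + 2, j] = 1.0 / h[j + 1]
        R[j, j] = (h[j] + h[j + 1]) / 3.0
        if j + 1 < n - 2:
            R[j, j + 1] = h[j + 1] / 6.0
            R[j + 1, j] = h[j + 1] / 6.0
    return Q, R


def _penalty_matrix(x: np.ndarray) -> np.ndarray:
    """Roughness penalty K with f^T K f = int f''(t)^2 dt for natural splines."""
    Q, R = _reinsch_matrices(x)
    return Q @ np.linalg.solve(R, Q.T)


def smoother_matrix(x: np.ndarray, lam: float) -> np.ndarray:
    """Dense smoother matrix S = (I + lam*K)^-1 for knots ``x``."""
    x = np.asarray(x, dtype=float)
    K = _penalty_matrix(x)
    return np.linalg.inv(np.eye(x.size) + lam * K)


def effective_df(x: np.ndarray, lam: float) -> float:
    """trace of the smoother matrix at penalty ``lam``."""
    return float(np.trace(smoother_matrix(x, lam)))


@dataclass
class SplineFit:
    """A fitted natural cubic smoothing spline.

    Attributes
    ----------
    x, y : observation abscissae (strictly increasing) and responses.
    fitted : smoothed values at the observation points.
    df : effective degrees of freedom requested.
    lam : penalty that realises ``df`` (np.inf for df == 2).
    """

    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    df: float
    lam: float
    _interp: CubicSpline | None = field(default=None, repr=False, compare=False)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the spline at arbitrary points.

        The smoothing spline is itself a natural cubic spline through its
        fitted values, so the natural-spline interpolant of ``fitted``
        reproduces it exactly between the knots.
        """
        if self._interp is None:
            if self.lam == np.inf:
                # straight line: evaluate directly to avoid interpolant end effects
                b, a = np.polyfit(self.x, self.y, 1)
                return a + b * np.asarray(t, dtype=float)
            self._interp = CubicSpline(self.x, self.fitted, bc_type="natural")
        return self._interp(t)

    def derivative(self, t: np.ndarray | float) -> np.ndarray | float:
        if self.lam == np.inf:
            b, _ = np.polyfit(self.x, self.y, 1)
            return np.full_like(np.asarray(t, dtype=float), b)
        if self._interp is None:
            self._interp = CubicSpline(self.x, self.fitted, bc_type="natural")
        return self._interp(t, 1)


def smoothing_spline(x: np.ndarray, y: np.ndarray, df: float) -> SplineFit:
    """Fit a natural cubic smoothing spline with a given effective df.

    Parameters
    ----------
    x : strictly increasing abscissae (e.g. days after salting), n >= 3.
    y : responses at ``x``.
    df : target effective degrees of freedom, 2 <= df <= n.  ``df = 2``
        yields the least-squares line; ``df = n`` the interpolant.

    Returns
    -------
    SplineFit with ``trace(S) = df`` within ``DF_TOL``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be one-dimensional and equal length")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("x and y must be finite")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    n = x.size
    if df < 2:
        raise ValueError(f"df must be >= 2, got {df}")
    if df > n:
        raise ValueError(f"df must be <= number of points ({n}), got {df}")

    if np.isclose(df, n):
        fitted = y.copy()
        return SplineFit(x=x, y=y, fitted=fitted, df=float(df), lam=0.0)
    if np.isclose(df, 2.0):
        b, a = np.polyfit(x, y, 1)
        return SplineFit(x=x, y=y, fitted=a + b * x, df=2.0, lam=np.inf)

    K = _penalty_matrix(x)
    eye = np.eye(n)

    def trace_minus_df(log_lam: float) -> float:
        S = np.linalg.inv(eye + np.exp(log_lam) * K)
        return float(np.trace(S)) - df

    # bracket the root in log-lambda; trace is monotone decreasing in lam
    lo, hi = -20.0, 20.0
    while trace_minus_df(lo) < 0 and lo > -60:
        lo -= 10.0
    while trace_minus_df(hi) > 0 and hi < 60:
        hi += 10.0
    log_lam = brentq(trace_minus_df, lo, hi, xtol=1e-10)
    # refine so that |trace - df| <= DF_TOL
    lam = float(np.exp(log_lam))
    S = np.linalg.inv(eye + lam * K)
    achieved = float(np.trace(S))
    if abs(achieved - df) > DF_TOL:
        raise RuntimeError(
            f"penalty search did not reach df={df}: achieved {achieved:.6f}"
        )
    fitted = S @ y
    return SplineFit(x=x, y=y, fitted=fitted, df=float(df), lam=lam)
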