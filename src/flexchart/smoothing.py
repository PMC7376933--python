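"""Time transformation and penalized cubic smoothing splines.

The single covariate is days post-surgery, entered through a power
transform ``t -> t**p`` (p around 0.5 linearises the early, fast phase of
recovery).  Each distribution-parameter curve is a natural cubic smoothing
spline in the transformed time, fitted by penalized weighted least squares

    min_g  sum_i w_i (y_i - g(x_i))**2 + lam * integral g''(x)**2 dx

with knots at the distinct observed x.  Flexibility is expressed as the
*effective degrees of freedom* of the linear smoother, edf =
trace((W + lam*K)^{-1} W), a continuous quantity: edf = 2 is the weighted
least-squares straight line (lam -> inf) and edf = n_distinct is exact
interpolation (lam -> 0).  Fractional smoothing "knots" therefore mean edf
in excess of the linear term; ``fit_smooth(..., extra_df=d)`` solves for
the penalty that achieves edf = 2 + d.

Prediction outside the observed x range continues the natural spline
linearly from the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
import numpy.linalg as _nla

#: tolerance on the achieved effective degrees of freedom
DF_TOL = 1e-3


def transform_time(day, power):
    """Power transform of postoperative day: ``day**power`` (order preserving)."""
    day = np.asarray(day, dtype=float)
    if power <= 0:
        raise ValueError("time power must be > 0")
    if np.any(day < 0):
        raise ValueError("days post-surgery must be non-negative")
    out = day**power
    return float(out) if out.ndim == 0 else out


def _aggregate(x, y, w):
    """Collapse duplicate x to distinct knots with pooled weights."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    xu, inv = np.unique(x, return_inverse=True)
    wu = np.bincount(inv, weights=w)
    yu = np.bincount(inv, weights=w * y) / wu
    return xu, yu, wu, inv


def penalty_matrix(x):
    """Roughness penalty K with g' K g = integral g''**2 for a natural spline.

    ``x`` must be strictly increasing.  K = D' C^{-1} D in the usual
    second-difference / tridiagonal construction; K annihilates constants
    and linear functions.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        return np.zeros((n, n))
    h = np.diff(x)
    D = np.zeros((n - 2, n))
    idx = np.arange(n - 2)
    D[idx, idx] = 1.0 / h[:-1]
    D[idx, idx + 1] = -1.0 / h[:-1] - 1.0 / h[1:]
    D[idx, idx + 2] = 1.0 / h[1:]
    C = np.diag((h[:-1] + h[1:]) / 3.0)
    off = h[1:-1] / 6.0
    C[idx[:-1], idx[:-1] + 1] = off
    C[idx[:-1] + 1, idx[:-1]] = off
    return D.T @ _nla.solve(C, D)


def smoother_matrix(x, w, lam, K=None):
    """The linear smoother S with fitted = S y, on distinct x with weights w."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if K is None:
        K = penalty_matrix(x)
    A = lam * K + np.diag(w)
    return _nla.solve(A, np.diag(w))


def _edf(w, lam, K):
    # at extreme penalties the weight matrix is lost to rounding and A is
    # numerically singular; the smoother is then the linear fit (edf = 2)
    A = lam * K + np.diag(w)
    try:
        return float(np.trace(_nla.solve(A, np.diag(w))))
    except _nla.LinAlgError:
        return 2.0


def _weighted_line(x, y, w):
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    slope = 0.0 if sxx == 0 else (w * (x - xm) * (y - ym)).sum() / sxx
    return ym - slope * xm, slope


def df_to_lambda(x, w, target_df, K=None, lam_hint=None, tol=DF_TOL):
    """Solve for the penalty achieving trace(S_lambda) = target_df.

    Monotone in the target (larger df -> smaller lambda); solved by
    bisection on log10(lambda).  Boundary targets return ``inf`` (linear
    fit) and ``0`` (interpolation).
    """
    xu, _, wu, _ = _aggregate(x, np.zeros_like(np.asarray(x, float)), w)
    n = len(xu)
    if not (2.0 - tol <= target_df <= n + tol):
        raise ValueError(
            f"target_df {target_df} unattainable: must lie in [2, {n}]"
        )
    if target_df <= 2.0 + tol:
        return np.inf
    if target_df >= n - tol:
        return 0.0
    if K is None:
        K = penalty_matrix(xu)

    if lam_hint is not None and np.isfinite(lam_hint) and lam_hint > 0:
        if abs(_edf(wu, lam_hint, K) - target_df) < tol:
            return lam_hint
    # work on a scale-relative penalty so the bracket is data-independent
    scale = np.log10(np.trace(np.diag(wu)) / max(np.trace(K), 1e-300))
    lo, hi = scale - 10.0, scale + 10.0
    # trace is decreasing in lambda: expand the bracket as needed
    while _edf(wu, 10.0**lo, K) < target_df and lo > scale - 24:
        lo -= 4.0
    while _edf(wu, 10.0**hi, K) > target_df and hi < scale + 24:
        hi += 4.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        tr = _edf(wu, 10.0**mid, K)
        if abs(tr - target_df) < tol:
            return 10.0**mid
        if tr > target_df:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13:
            break
    return 10.0 ** (0.5 * (lo + hi))


@dataclass
class SmoothFit:
    """A fitted natural cubic smoothing spline.

    ``knots`` are the distinct x values, ``values`` the fitted curve at the
    knots; the curve between knots is the natural interpolating spline of
    ``values`` and the extension beyond the boundary knots is linear.
    """

    knots: np.ndarray
    values: np.ndarray
    lam: float
    edf: float
    fitted: np.ndarray = field(repr=False)  # at the original (unaggregated) x
    _cs: CubicSpline | None = field(default=None, repr=False, compare=False)

    def _spline(self):
        if self._cs is None:
            self._cs = CubicSpline(
                self.knots, self.values, bc_type="natural", extrapolate=False
            )
        return self._cs

    def predict(self, xq):
        """Evaluate the curve; linear extrapolation beyond the knot range."""
        xq = np.atleast_1d(np.asarray(xq, dtype=float))
        x0, x1 = self.knots[0], self.knots[-1]
        if len(self.knots) == 1:
            return np.full(xq.shape, self.values[0])
        cs = self._spline()
        out = np.empty(xq.shape)
        inside = (xq >= x0) & (xq <= x1)
        out[inside] = cs(xq[inside])
        d0 = float(cs(x0, 1))
        d1 = float(cs(x1, 1))
        lo = xq < x0
        hi = xq > x1
        out[lo] = self.values[0] + d0 * (xq[lo] - x0)
        out[hi] = self.values[-1] + d1 * (xq[hi] - x1)
        return out

    def in_range(self, xq):
        """True where prediction does not extrapolate."""
        xq = np.asarray(xq, dtype=float)
        return (xq >= self.knots[0]) & (xq <= self.knots[-1])


def fit_smooth(x, y, w=None, extra_df=0.0, K=None, lam_hint=None):
    """Weighted natural cubic smoothing spline at edf = 2 + extra_df.

    ``extra_df = 0`` reproduces the weighted least-squares straight line;
    an ``extra_df`` exceeding n_distinct - 2 is capped with a warning.
    """
    if extra_df < 0:
        raise ValueError("extra_df must be >= 0")
    xu, yu, wu, inv = _aggregate(x, y, w)
    n = len(xu)
    if n < 2:
        raise ValueError("need at least 2 distinct x values")
    target = 2.0 + float(extra_df)
    if target > n:
        warnings.warn(
            f"requested edf {target:.2f} exceeds the {n} distinct x values; capping",
            stacklevel=2,
        )
        target = float(n)

    if target <= 2.0 + DF_TOL or n == 2:
        a, b = _weighted_line(xu, yu, wu)
        g = a + b * xu
        lam, edf = np.inf, 2.0
    elif target >= n - DF_TOL:
        g, lam, edf = yu.copy(), 0.0, float(n)
    else:
        if K is None:
            K = penalty_matrix(xu)
        lam = df_to_lambda(xu, wu, target, K=K, lam_hint=lam_hint)
        A = lam * K + np.diag(wu)
        g = _nla.solve(A, wu * yu)
        edf = _edf(wu, lam, K)
    return SmoothFit(knots=xu, values=g, lam=float(lam), edf=float(edf), fitted=g[inv])
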