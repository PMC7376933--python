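"""Response families for centile modelling of knee-flexion range of motion.

Six candidate distributions of increasing complexity are supported, named by
their conventional abbreviations:

====== ======================== ========= ==================================
name   distribution             n_params  parameters
====== ======================== ========= ==================================
NO     normal                   2         mu (median), sigma (sd, degrees)
GA     gamma                    2         mu (median), sigma (~CV)
TF     t family                 3         mu (median), sigma (scale),
                                          nu (degrees of freedom, > 0)
BCCG   Box-Cox Cole-Green (LMS) 3         mu (median), sigma (relative
                                          scale), nu (skewness power)
BCT    Box-Cox t                4         ... plus tau (t df, > 0)
BCPE   Box-Cox power exponen.   4         ... plus tau (kurtosis power, > 0)
====== ======================== ========= ==================================

Every family is parameterised so that ``mu`` is the *median* of the
distribution: ``centile_value(family, 0.5, mu, ...) == mu``.  For the gamma
family this is achieved by rescaling the conventional shape/scale
parameterisation (shape ``1/sigma**2``) so its 50th percentile sits at
``mu``; deviances are invariant to this reparameterisation.

The Box-Cox families transform the response through

    z = ((y / mu)**nu - 1) / (nu * sigma)        for nu != 0
    z = log(y / mu) / sigma                      for nu == 0

and model ``z`` as standard normal (BCCG), standard t with ``tau`` degrees
of freedom (BCT), or standardised power-exponential with kurtosis power
``tau`` (BCPE), truncated so the density integrates to one on the positive
half line.  The truncation bound is ``c = 1 / (sigma * |nu|)`` and the
truncation constant is evaluated in log space, so for the small values of
``sigma * |nu|`` typical of flexion data it is numerically exact.  The
``nu == 0`` branch (lognormal-type) is taken whenever ``|nu| < 1e-7``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

#: crossover below which the Box-Cox power is treated as exactly zero
_NU_EPS = 1e-7


@dataclass(frozen=True)
class Family:
    """A response family: its name, parameter count and support."""

    name: str
    n_params: int
    positive_support: bool
    param_names: tuple[str, ...]


_FAMILIES = {
    "NO": Family("NO", 2, False, ("mu", "sigma")),
    "GA": Family("GA", 2, True, ("mu", "sigma")),
    "TF": Family("TF", 3, False, ("mu", "sigma", "nu")),
    "BCCG": Family("BCCG", 3, True, ("mu", "sigma", "nu")),
    "BCT": Family("BCT", 4, True, ("mu", "sigma", "nu", "tau")),
    "BCPE": Family("BCPE", 4, True, ("mu", "sigma", "nu", "tau")),
}

FAMILY_NAMES = tuple(_FAMILIES)


def get_family(family) -> Family:
    """Resolve a family name (or pass a :class:`Family` through)."""
    if isinstance(family, Family):
        return family
    key = str(family).upper()
    if key not in _FAMILIES:
        raise ValueError(
            f"unknown family {family!r}; choose one of {', '.join(_FAMILIES)}"
        )
    return _FAMILIES[key]


def _broadcast(fam, y, mu, sigma, nu, tau):
    """Broadcast response and parameters to a common float shape."""
    needed = fam.param_names
    if "nu" in needed and nu is None:
        raise ValueError(f"family {fam.name} requires a nu parameter")
    if "tau" in needed and tau is None:
        raise ValueError(f"family {fam.name} requires a tau parameter")
    parts = [np.asarray(y, dtype=float), np.asarray(mu, dtype=float),
             np.asarray(sigma, dtype=float)]
    parts.append(np.asarray(nu if "nu" in needed else 0.0, dtype=float))
    parts.append(np.asarray(tau if "tau" in needed else 1.0, dtype=float))
    scalar = all(p.ndim == 0 for p in parts)
    return (*np.broadcast_arrays(*parts), scalar)


def _check_params(fam, mu, sigma, nu, tau):
    if np.any(~np.isfinite(mu)) or np.any(~np.isfinite(sigma)):
        raise ValueError("mu and sigma must be finite")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    if fam.positive_support and np.any(mu <= 0):
        raise ValueError(f"family {fam.name} requires mu > 0")
    if fam.name == "TF" and np.any(nu <= 0):
        raise ValueError("TF degrees of freedom (nu) must be > 0")
    if fam.name in ("BCT", "BCPE") and np.any(tau <= 0):
        raise ValueError(f"{fam.name} tau must be > 0")


def _maybe_scalar(out, scalar):
    return float(out) if scalar else out


def _pe_scale(tau):
    """Scale making the power-exponential kernel unit-variance (tau=2 -> N(0,1))."""
    return np.sqrt(special.gamma(1.0 / tau) / special.gamma(3.0 / tau))


def _bc_parts(y, mu, sigma, nu):
    """Box-Cox transform z, truncation bound c, and log-Jacobian for y > 0."""
    r = y / mu
    small = np.abs(nu) < _NU_EPS
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z_pow = (np.power(r, nu) - 1.0) / (nu * sigma)
        z_log = np.log(r) / sigma
        z = np.where(small, z_log, z_pow)
        c = np.where(small, np.inf, 1.0 / (sigma * np.abs(np.where(small, 1.0, nu))))
        logjac = np.where(
            small,
            -np.log(y) - np.log(sigma),
            (nu - 1.0) * np.log(y) - nu * np.log(mu) - np.log(sigma),
        )
    return z, c, logjac


def _kernel_logpdf(fam, z, tau):
    if fam.name == "BCCG":
        return stats.norm.logpdf(z)
    if fam.name == "BCT":
        return stats.t.logpdf(z, tau)
    return stats.gennorm.logpdf(z, tau, scale=_pe_scale(tau))


def _kernel_cdf(fam, z, tau):
    if fam.name == "BCCG":
        return stats.norm.cdf(z)
    if fam.name == "BCT":
        return stats.t.cdf(z, tau)
    return stats.gennorm.cdf(z, tau, scale=_pe_scale(tau))


def _kernel_logcdf(fam, z, tau):
    if fam.name == "BCCG":
        return stats.norm.logcdf(z)
    if fam.name == "BCT":
        return stats.t.logcdf(z, tau)
    return stats.gennorm.logcdf(z, tau, scale=_pe_scale(tau))


def _kernel_ppf(fam, p, tau):
    if fam.name == "BCCG":
        return stats.norm.ppf(p)
    if fam.name == "BCT":
        return stats.t.ppf(p, tau)
    return stats.gennorm.ppf(p, tau, scale=_pe_scale(tau))


def _ga_shape_scale(mu, sigma):
    shape = 1.0 / sigma**2
    scale = mu / stats.gamma.ppf(0.5, shape)
    return shape, scale


def log_density(family, y, mu, sigma, nu=None, tau=None, *, validate=True):
    """Log density of ``y`` under the family at (mu, sigma, nu, tau).

    Values of ``y`` outside the family's support get ``-inf``.
    """
    fam = get_family(family)
    y, mu, sigma, nu, tau, scalar = _broadcast(fam, y, mu, sigma, nu, tau)
    if validate:
        _check_params(fam, mu, sigma, nu, tau)

    if fam.name == "NO":
        out = stats.norm.logpdf(y, loc=mu, scale=sigma)
    elif fam.name == "TF":
        out = stats.t.logpdf(y, nu, loc=mu, scale=sigma)
    elif fam.name == "GA":
        shape, scale = _ga_shape_scale(mu, sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = stats.gamma.logpdf(y, shape, scale=scale)
        out = np.where(y > 0, out, -np.inf)
    else:
        pos = y > 0
        ysafe = np.where(pos, y, 1.0)
        z, c, logjac = _bc_parts(ysafe, mu, sigma, nu)
        out = logjac + _kernel_logpdf(fam, z, tau) - _kernel_logcdf(fam, c, tau)
        out = np.where(pos, out, -np.inf)
    return _maybe_scalar(out, scalar)


def cdf(family, y, mu, sigma, nu=None, tau=None, *, validate=True):
    """Cumulative distribution function, truncation-adjusted for Box-Cox families."""
    fam = get_family(family)
    y, mu, sigma, nu, tau, scalar = _broadcast(fam, y, mu, sigma, nu, tau)
    if validate:
        _check_params(fam, mu, sigma, nu, tau)

    if fam.name == "NO":
        out = stats.norm.cdf(y, loc=mu, scale=sigma)
    elif fam.name == "TF":
        out = stats.t.cdf(y, nu, loc=mu, scale=sigma)
    elif fam.name == "GA":
        shape, scale = _ga_shape_scale(mu, sigma)
        out = stats.gamma.cdf(y, shape, scale=scale)
    else:
        pos = y > 0
        ysafe = np.where(pos, y, 1.0)
        z, c, _ = _bc_parts(ysafe, mu, sigma, nu)
        small = np.abs(nu) < _NU_EPS
        kz = _kernel_cdf(fam, z, tau)
        kmc = _kernel_cdf(fam, -c, tau)
        kc = _kernel_cdf(fam, c, tau)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                small,
                kz,
                np.where(nu > 0, (kz - kmc) / (1.0 - kmc), kz / kc),
            )
        out = np.where(pos, out, 0.0)
    return _maybe_scalar(np.clip(out, 0.0, 1.0), scalar)


def centile_value(family, alpha, mu, sigma, nu=None, tau=None, *, validate=True):
    """The ``alpha``-quantile (centile) of the family; alpha in (0, 1).

    Strictly increasing in ``alpha``; ``alpha = 0.5`` returns ``mu`` for
    every family (median parameterisation).
    """
    fam = get_family(family)
    alpha_arr = np.asarray(alpha, dtype=float)
    if np.any(alpha_arr <= 0.0) or np.any(alpha_arr >= 1.0):
        raise ValueError("alpha must lie strictly inside (0, 1)")
    alpha_b, mu, sigma, nu, tau, scalar = _broadcast(fam, alpha_arr, mu, sigma, nu, tau)
    if validate:
        _check_params(fam, mu, sigma, nu, tau)

    if fam.name == "NO":
        out = stats.norm.ppf(alpha_b, loc=mu, scale=sigma)
    elif fam.name == "TF":
        out = stats.t.ppf(alpha_b, nu, loc=mu, scale=sigma)
    elif fam.name == "GA":
        shape, scale = _ga_shape_scale(mu, sigma)
        out = stats.gamma.ppf(alpha_b, shape, scale=scale)
    else:
        small = np.abs(nu) < _NU_EPS
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            c = 1.0 / (sigma * np.abs(np.where(small, 1.0, nu)))
            c = np.where(small, np.inf, c)
            kmc = _kernel_cdf(fam, -c, tau)
            kc = _kernel_cdf(fam, c, tau)
            p_eff = np.where(
                small,
                alpha_b,
                np.where(nu > 0, kmc + alpha_b * (1.0 - kmc), alpha_b * kc),
            )
            zp = _kernel_ppf(fam, p_eff, tau)
            base = np.maximum(1.0 + nu * sigma * zp, 1e-300)
            out = np.where(
                small,
                mu * np.exp(sigma * zp),
                mu * np.power(base, 1.0 / np.where(small, 1.0, nu)),
            )
    return _maybe_scalar(out, scalar)


def z_transform(family, y, mu, sigma, nu=None, tau=None, *, validate=True):
    """Standardised residual.

    For NO/TF this is ``(y - mu) / sigma``; for the Box-Cox families it is
    the Box-Cox ``z`` (standard normal / t / power-exponential under the
    model, up to truncation); for GA it is the normal quantile residual
    ``Phi^{-1}(F(y))``.  Values outside the support map to ``-inf``.
    """
    fam = get_family(family)
    y, mu, sigma, nu, tau, scalar = _broadcast(fam, y, mu, sigma, nu, tau)
    if validate:
        _check_params(fam, mu, sigma, nu, tau)

    if fam.name in ("NO", "TF"):
        out = (y - mu) / sigma
    elif fam.name == "GA":
        shape, scale = _ga_shape_scale(mu, sigma)
        p = stats.gamma.cdf(y, shape, scale=scale)
        out = stats.norm.ppf(np.clip(p, 1e-300, 1.0 - 1e-16))
        out = np.where(y > 0, out, -np.inf)
    else:
        pos = y > 0
        ysafe = np.where(pos, y, 1.0)
        z, _, _ = _bc_parts(ysafe, mu, sigma, nu)
        out = np.where(pos, z, -np.inf)
    return _maybe_scalar(out, scalar)


def quantile_residuals(family, y, mu, sigma, nu=None, tau=None):
    """Normalised (randomised-free) quantile residuals Phi^{-1}(F(y))."""
    p = cdf(family, y, mu, sigma, nu, tau)
    return stats.norm.ppf(np.clip(p, 1e-15, 1.0 - 1e-15))


def sample(family, n, mu, sigma, nu=None, tau=None, *, seed=None, rng=None):
    """Draw ``n`` values by inverse-CDF sampling; reproducible given ``seed``.

    Parameters may be scalars or arrays of length ``n`` (e.g. centile curves
    evaluated at per-observation days).
    """
    n = int(n)
    if n < 0:
        raise ValueError("n must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    u = rng.uniform(low=1e-12, high=1.0 - 1e-12, size=n)
    out = centile_value(family, u, mu, sigma, nu, tau)
    return np.atleast_1d(out)
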