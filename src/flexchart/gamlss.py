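"""Distributional regression of flexion on transformed time.

Each parameter of the response family (median mu, scale sigma, and where
present the shape parameters nu and tau) is modelled as either a constant
or a penalized cubic smoothing spline in transformed time x = day**power.
Fitting maximises the penalized likelihood by RS-type backfitting: cycle
over the parameters and, for each one in turn, form a working response and
iterative weights from the first and second derivatives of the
log-likelihood with respect to that parameter's linear predictor (holding
the others fixed), fit the weighted smooth at the requested effective
degrees of freedom, and repeat until the global deviance stabilises.

Derivatives are obtained by central finite differences of the exact
log-density, which keeps the scheme uniform across all six families; each
parameter update is step-halved until the global deviance does not
increase, so the outer deviance trace is non-increasing by construction.

Link functions: identity for mu (flexion is far from zero) and for the
Box-Cox skewness power nu; log for sigma and for the strictly positive
shape parameters (TF and BCT degrees of freedom, BCPE kurtosis power).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import get_family, log_density, centile_value, z_transform
from .exceptions import ConvergenceError, DataValidationError
from .smoothing import SmoothFit, fit_smooth, penalty_matrix, transform_time

#: bounds on log-link linear predictors (exp(12) ~ 1.6e5)
_ETA_CLAMP = 12.0


def _links_for(family):
    fam = get_family(family)
    links = {"mu": "identity", "sigma": "log"}
    if fam.name == "TF":
        links["nu"] = "log"  # degrees of freedom, > 0
    elif "nu" in fam.param_names:
        links["nu"] = "identity"  # Box-Cox power, unrestricted
    if "tau" in fam.param_names:
        links["tau"] = "log"
    return links


def _link_apply(link, theta):
    return np.log(theta) if link == "log" else np.asarray(theta, dtype=float)


def _link_invert(link, eta):
    if link == "log":
        return np.exp(np.clip(eta, -_ETA_CLAMP, _ETA_CLAMP))
    return np.asarray(eta, dtype=float)


def _norm_df(value):
    """Normalise a per-parameter df spec: None/'constant' -> None, else float."""
    if value is None:
        return None
    if isinstance(value, str):
        if value.lower() in ("constant", "const", "c"):
            return None
        raise ValueError(f"unrecognised df spec {value!r}")
    v = float(value)
    if v < 0:
        raise ValueError("extra df must be >= 0")
    return v


@dataclass(frozen=True)
class ModelSpec:
    """Family plus per-parameter smoothing layout.

    ``df_*`` is the extra effective df of that parameter's spline beyond
    the linear term; ``None`` (or ``"constant"``) fits a constant.  Entries
    for parameters the family does not have must be left ``None``.
    """

    family: str = "BCCG"
    time_power: float = 1.0
    df_mu: float | str | None = 2.0
    df_sigma: float | str | None = 1.0
    df_nu: float | str | None = None
    df_tau: float | str | None = None

    def __post_init__(self):
        fam = get_family(self.family)
        object.__setattr__(self, "family", fam.name)
        if self.time_power <= 0:
            raise ValueError("time_power must be > 0")
        for p in ("mu", "sigma", "nu", "tau"):
            v = _norm_df(getattr(self, f"df_{p}"))
            if p not in fam.param_names and v is not None:
                raise ValueError(f"family {fam.name} has no parameter {p}")
            object.__setattr__(self, f"df_{p}", v)

    def df_for(self, param):
        return getattr(self, f"df_{param}")

    @property
    def total_df(self):
        """Sum of per-parameter df: 2 + extra for smooth terms, 1 for constants."""
        fam = get_family(self.family)
        total = 0.0
        for p in fam.param_names:
            d = self.df_for(p)
            total += 1.0 if d is None else 2.0 + d
        return total


@dataclass
class FittedCentileModel:
    """A converged fit: family, per-parameter curves, deviance and df.

    ``terms`` maps parameter name to either
    ``{"type": "constant", "eta": float}`` or
    ``{"type": "smooth", "knots": [...], "values": [...], "lam": float,
    "edf": float}`` (on the linear-predictor scale, over transformed time).
    All public prediction methods take days post-surgery; the time
    transform is applied internally.
    """

    spec: ModelSpec
    links: dict
    terms: dict
    global_deviance: float
    n_obs: int
    n_iter: int
    converged: bool
    deviance_trace: list = field(default_factory=list, repr=False)
    _splines: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def family(self):
        return self.spec.family

    @property
    def total_df(self):
        return self.spec.total_df

    def _eta(self, param, x):
        term = self.terms[param]
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if term["type"] == "constant":
            return np.full(x.shape, term["eta"])
        sf = self._splines.get(param)
        if sf is None:
            knots = np.asarray(term["knots"], dtype=float)
            values = np.asarray(term["values"], dtype=float)
            sf = SmoothFit(knots=knots, values=values, lam=term["lam"],
                           edf=term["edf"], fitted=values)
            self._splines[param] = sf
        return sf.predict(x)

    def params_at(self, day):
        """Distribution parameters (theta scale) at the given day(s)."""
        x = transform_time(day, self.spec.time_power)
        fam = get_family(self.family)
        return {
            p: _link_invert(self.links[p], self._eta(p, x))
            for p in fam.param_names
        }

    def median(self, day):
        return self.params_at(day)["mu"]

    def centile(self, day, alpha):
        """Centile curve value(s) at day(s); the alpha-quantile of the fit."""
        pars = self.params_at(day)
        return centile_value(self.family, alpha, **pars)

    def z_scores(self, day, y):
        """Standardised residuals of observations against the fitted curves."""
        pars = self.params_at(day)
        return z_transform(self.family, np.asarray(y, dtype=float), **pars)


def _extract_columns(data):
    """Accept a CohortTable, a DataFrame, or a (day, y) pair."""
    if hasattr(data, "frame"):
        frame = data.frame
    else:
        frame = data
    if hasattr(frame, "columns"):
        day = np.asarray(frame["day_post_op"], dtype=float)
        y = np.asarray(frame["flexion_deg"], dtype=float)
        return day, y
    day, y = data
    return np.asarray(day, dtype=float), np.asarray(y, dtype=float)


class _FitState:
    """Mutable per-parameter state during backfitting."""

    def __init__(self, kind, value):
        self.kind = kind  # "constant" | "smooth"
        self.value = value  # scalar eta, or g over knots
        self.lam = None
        self.edf = None

    def eta_obs(self, inv, n):
        if self.kind == "constant":
            return np.full(n, self.value)
        return self.value[inv]


def fit_gamlss(data, spec, *, tol=1e-7, max_iter=200, min_obs=10, strict=True):
    """Fit the spec to the data by penalized-likelihood backfitting.

    Parameters
    ----------
    data : CohortTable, DataFrame with day_post_op/flexion_deg, or (day, y)
    spec : ModelSpec
    tol : convergence threshold on |change in global deviance|, required on
        two consecutive outer cycles
    max_iter : maximum outer cycles; exceeding it raises
        :class:`ConvergenceError` when ``strict`` (the error carries the
        deviance trace), otherwise returns the best model so far flagged
        ``converged=False``
    """
    day, y = _extract_columns(data)
    n = len(y)
    if n < min_obs:
        raise DataValidationError(f"need at least {min_obs} observations, got {n}")
    fam = get_family(spec.family)
    if fam.positive_support and np.any(y <= 0):
        raise DataValidationError(
            f"family {fam.name} requires strictly positive outcomes"
        )
    links = _links_for(fam)
    x = transform_time(day, spec.time_power)
    xu, inv = np.unique(x, return_inverse=True)
    K = penalty_matrix(xu) if len(xu) >= 3 else None

    # --- initial values ------------------------------------------------
    states: dict[str, _FitState] = {}
    mu_df = spec.df_for("mu")
    if mu_df is None:
        states["mu"] = _FitState("constant", float(np.median(y)))
    else:
        sf = fit_smooth(x, y, None, extra_df=mu_df, K=K)
        states["mu"] = _FitState("smooth", sf.values.copy())
        states["mu"].lam, states["mu"].edf = sf.lam, sf.edf
    mu0 = states["mu"].eta_obs(inv, n)
    mu0 = np.maximum(mu0, 1e-6) if fam.positive_support else mu0
    if fam.positive_support:
        s0 = float(np.std(y / np.maximum(mu0, 1e-6)))
    else:
        s0 = float(np.std(y - mu0))
    eta_s0 = float(np.log(np.clip(s0, 1e-3, None)))
    if spec.df_for("sigma") is None:
        states["sigma"] = _FitState("constant", eta_s0)
    else:
        states["sigma"] = _FitState("smooth", np.full(len(xu), eta_s0))
    if "nu" in fam.param_names:
        eta_nu0 = float(np.log(10.0)) if links["nu"] == "log" else 1.0
        if spec.df_for("nu") is None:
            states["nu"] = _FitState("constant", eta_nu0)
        else:
            states["nu"] = _FitState("smooth", np.full(len(xu), eta_nu0))
    if "tau" in fam.param_names:
        eta_tau0 = float(np.log(10.0 if fam.name == "BCT" else 2.0))
        if spec.df_for("tau") is None:
            states["tau"] = _FitState("constant", eta_tau0)
        else:
            states["tau"] = _FitState("smooth", np.full(len(xu), eta_tau0))

    # --- likelihood plumbing -------------------------------------------
    def loglik_vec(etas):
        theta = {p: _link_invert(links[p], e) for p, e in etas.items()}
        if fam.positive_support and np.any(theta["mu"] <= 0):
            return np.full(n, -np.inf)
        if links.get("nu") == "log" or "nu" not in theta:
            pass
        with np.errstate(all="ignore"):
            ll = log_density(fam, y, validate=False, **theta)
        return np.atleast_1d(ll)

    def deviance_of(etas):
        ll = loglik_vec(etas)
        if not np.all(np.isfinite(ll)):
            return np.inf
        return -2.0 * float(ll.sum())

    def current_etas():
        return {p: st.eta_obs(inv, n) for p, st in states.items()}

    dev = deviance_of(current_etas())
    if not np.isfinite(dev):
        raise DataValidationError("initial parameter values give infinite deviance")
    trace = [dev]

    # --- backfitting cycles --------------------------------------------
    converged = False
    streak = 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for p, st in states.items():
            etas = current_etas()
            eta_p = etas[p]
            h = 1e-4 * (1.0 + np.abs(eta_p))
            lp = loglik_vec({**etas, p: eta_p + h})
            lm = loglik_vec({**etas, p: eta_p - h})
            l0 = loglik_vec(etas)
            ok = np.isfinite(lp) & np.isfinite(lm) & np.isfinite(l0)
            u = np.where(ok, (lp - lm) / (2.0 * h), 0.0)
            f = np.where(ok, -(lp - 2.0 * l0 + lm) / h**2, 0.0)
            fpos = f[f > 0]
            floor = 1e-4 * (float(np.median(fpos)) if fpos.size else 1.0)
            floor = max(floor, 1e-10)
            w = np.where(f > floor, f, floor)
            e = eta_p + u / w

            if st.kind == "smooth":
                sf = fit_smooth(x, e, w, extra_df=spec.df_for(p), K=K,
                                lam_hint=st.lam)
                new_val, old_val = sf.values, st.value
            else:
                new_val = float(np.sum(w * e) / np.sum(w))
                old_val = st.value
            if links[p] == "log":
                new_val = np.clip(new_val, -_ETA_CLAMP, _ETA_CLAMP)

            accepted = False
            step = 1.0
            for _ in range(13):
                cand = old_val + step * (np.asarray(new_val) - np.asarray(old_val))
                cand = float(cand) if st.kind == "constant" else cand
                st.value = cand
                dev_c = deviance_of(current_etas())
                if dev_c <= dev + 1e-10:
                    dev = dev_c
                    accepted = True
                    if st.kind == "smooth" and step == 1.0:
                        st.lam, st.edf = sf.lam, sf.edf
                    break
                step *= 0.5
            if not accepted:
                st.value = old_val
        trace.append(dev)
        if abs(trace[-2] - trace[-1]) < tol:
            streak += 1
            if streak >= 2:
                converged = True
                break
        else:
            streak = 0

    if not converged and strict:
        raise ConvergenceError(
            f"backfitting did not converge in {max_iter} cycles "
            f"(last deviance change {abs(trace[-2] - trace[-1]):.3g})",
            deviance_trace=trace,
        )

    terms = {}
    for p, st in states.items():
        if st.kind == "constant":
            terms[p] = {"type": "constant", "eta": float(st.value)}
        else:
            terms[p] = {
                "type": "smooth",
                "knots": xu.tolist(),
                "values": np.asarray(st.value, dtype=float).tolist(),
                "lam": float(st.lam) if st.lam is not None else float("inf"),
                "edf": float(st.edf) if st.edf is not None else 2.0 + spec.df_for(p),
            }
    return FittedCentileModel(
        spec=spec,
        links=links,
        terms=terms,
        global_deviance=float(dev),
        n_obs=n,
        n_iter=n_iter,
        converged=converged,
        deviance_trace=trace,
    )


def global_deviance(model, data):
    """-2 * sum of log-densities of the data at the model's fitted parameters."""
    day, y = _extract_columns(data)
    pars = model.params_at(day)
    ll = log_density(model.family, y, **pars)
    return -2.0 * float(np.sum(ll))


def model_df(model):
    """Total effective degrees of freedom: 2 + extra per smooth term, 1 per constant."""
    spec = model.spec if hasattr(model, "spec") else model
    return spec.total_df
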