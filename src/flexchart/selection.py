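"""Model scoring and selection: SBC, cross-validated MSE, and the
strategy of ranking candidate distributions.

The information criterion is the Schwarz Bayesian Criterion,

    SBC = global deviance + total_df * log(n_obs),

with the effective (possibly fractional) model degrees of freedom.  The
selection strategy ranks candidates by SBC, then — among candidates within
a small SBC margin of the best — prefers accurate centile coverage, then
lower cross-validated MSE, then fewer degrees of freedom (the less complex
model wins near-ties).

Cross-validation folds partition *patients*, not observations: repeated
measures within a patient would otherwise leak across folds and flatter
every model.  An observation-level mode exists behind a flag for
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .chart import DEFAULT_LEVELS, coverage
from .exceptions import ConvergenceError, DataValidationError, FlexchartError
from .gamlss import ModelSpec, fit_gamlss

logger = logging.getLogger(__name__)


def sbc(deviance, total_df, n_obs):
    """Schwarz Bayesian Criterion: deviance + df * log(n); lower is better."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return float(deviance) + float(total_df) * float(np.log(n_obs))


def model_sbc(model):
    return sbc(model.global_deviance, model.total_df, model.n_obs)


def patient_folds(patient_ids, k, seed):
    """Deterministic k-fold partition of patients.

    Patients are sorted, shuffled with the seeded generator, and dealt into
    k folds; the assignment depends only on the patient-id *set* and the
    seed, never on record order.  Returns {patient_id: fold}.
    """
    ids = sorted(set(patient_ids))
    if len(ids) < k:
        raise DataValidationError(f"need at least {k} patients for {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return {ids[j]: int(i % k) for i, j in enumerate(perm)}


@dataclass
class CVResult:
    mse: float
    per_fold: list
    failed_folds: list

    @property
    def flagged(self):
        return bool(self.failed_folds)


def cv_mse(data, spec, k=5, seed=0, by_patient=True, fit_kwargs=None):
    """Mean squared error of the median prediction under k-fold CV.

    Pools squared errors over all held-out observations.  A fold whose fit
    fails is reported in ``failed_folds`` and the aggregate is flagged.
    """
    frame = data.frame if hasattr(data, "frame") else data
    fit_kwargs = dict(fit_kwargs or {})
    if by_patient:
        folds = patient_folds(frame["patient_id"], k, seed)
        fold_of = frame["patient_id"].map(folds).to_numpy()
    else:
        rng = np.random.default_rng(seed)
        fold_of = rng.permutation(len(frame)) % k

    sq_errors, per_fold, failed = [], [], []
    for fold in range(k):
        test = frame[fold_of == fold]
        train = frame[fold_of != fold]
        if len(test) == 0:
            continue
        try:
            model = fit_gamlss(train, spec, **fit_kwargs)
        except FlexchartError as exc:
            logger.warning("CV fold %d failed: %s", fold, exc)
            failed.append(fold)
            continue
        pred = model.median(test["day_post_op"].to_numpy())
        err = (test["flexion_deg"].to_numpy() - pred) ** 2
        sq_errors.append(err)
        per_fold.append(float(err.mean()))
    if not sq_errors:
        raise ConvergenceError("every cross-validation fold failed")
    pooled = float(np.concatenate(sq_errors).mean())
    return CVResult(mse=pooled, per_fold=per_fold, failed_folds=failed)


@dataclass
class CandidateScore:
    """Scorecard for one candidate model (one row of a comparison table)."""

    spec: ModelSpec
    sbc: float
    total_df: float
    deviance: float
    cv_mse: float | None = None
    coverage_error: float | None = None
    coverage_pct: dict = field(default_factory=dict)

    @property
    def family(self):
        return self.spec.family


def score_candidates(data, specs, seed=0, with_cv=True, levels=DEFAULT_LEVELS,
                     fit_kwargs=None):
    """Fit and score each candidate spec on the data.

    Returns (scores, failures): converged candidates with SBC, within-sample
    centile coverage, and (optionally) patient-fold CV MSE; specs that fail
    to fit are returned separately.
    """
    scores, failures = [], []
    for spec in specs:
        try:
            model = fit_gamlss(data, spec, **(fit_kwargs or {}))
            cov = coverage(model, data, levels=levels)
        except FlexchartError as exc:
            logger.warning("candidate %s failed: %s", spec.family, exc)
            failures.append((spec, exc))
            continue
        cv = None
        if with_cv:
            try:
                cv = cv_mse(data, spec, seed=seed, fit_kwargs=fit_kwargs).mse
            except FlexchartError as exc:
                logger.warning("CV for %s failed: %s", spec.family, exc)
        scores.append(
            CandidateScore(
                spec=spec,
                sbc=model_sbc(model),
                total_df=model.total_df,
                deviance=model.global_deviance,
                cv_mse=cv,
                coverage_error=cov.coverage_error,
                coverage_pct={
                    float(r.level): float(r.observed_pct)
                    for r in cov.table.itertuples()
                },
            )
        )
    return scores, failures


@dataclass
class SelectionResult:
    ranked: list  # CandidateScore, best first
    rationale: str

    @property
    def best(self):
        return self.ranked[0]


def select_best(candidates, delta_sbc=5.0):
    """Rank candidates by the chart-development strategy.

    SBC orders the field; among candidates within ``delta_sbc`` of the
    minimum, accurate centile coverage, then lower CV MSE, then fewer
    degrees of freedom decide.  Order-invariant: ties beyond these keys
    break on family name and the df layout.
    """
    if not candidates:
        raise ValueError("need at least one candidate")

    def stable_key(c):
        return (c.sbc, c.family, c.total_df)

    ranked = sorted(candidates, key=stable_key)
    if len(ranked) == 1:
        return SelectionResult(ranked, "only candidate")

    best_sbc = ranked[0].sbc
    shortlist = [c for c in ranked if c.sbc - best_sbc <= delta_sbc]
    rest = [c for c in ranked if c.sbc - best_sbc > delta_sbc]

    def shortlist_key(c):
        cov = c.coverage_error if c.coverage_error is not None else np.inf
        cv = c.cv_mse if c.cv_mse is not None else np.inf
        return (round(cov, 6), round(cv, 6), c.total_df, c.sbc, c.family)

    shortlist.sort(key=shortlist_key)
    winner = shortlist[0]
    lines = [
        f"{len(candidates)} candidates; best SBC {best_sbc:.1f} "
        f"({ranked[0].family}); {len(shortlist)} within ΔSBC ≤ {delta_sbc:g}.",
        f"Among these, {winner.family} selected on (coverage error, CV MSE, "
        f"total df) = ({_fmt(winner.coverage_error)}, {_fmt(winner.cv_mse)}, "
        f"{winner.total_df:.2f}).",
    ]
    return SelectionResult(shortlist + rest, " ".join(lines))


def _fmt(v):
    return "n/a" if v is None else f"{v:.2f}"


def optimize_hyperparameters(
    data,
    family,
    init=None,
    bounds=None,
    seed=0,
    n_starts=3,
    maxfev=40,
    fit_kwargs=None,
):
    """Minimise SBC over (df_mu, df_sigma, time power) for one family.

    Derivative-free simplex search from jittered starts (the objective is
    cheap but non-smooth in places; the multistart guards local minima).
    Shape parameters stay constant during the search.  Returns the best
    :class:`ModelSpec`, its SBC, and the full evaluation trace; the
    returned optimum is never worse than the initial spec because the
    initial point is part of the trace.
    """
    init = dict(init or {})
    x0 = np.array(
        [init.get("df_mu", 2.0), init.get("df_sigma", 1.0), init.get("power", 0.5)]
    )
    bounds = bounds or {"df": (0.0, 10.0), "power": (0.05, 1.5)}
    df_lo, df_hi = bounds["df"]
    p_lo, p_hi = bounds["power"]
    fit_kwargs = {"tol": 1e-3, "max_iter": 80, "strict": False, **(fit_kwargs or {})}

    fam = family
    base = ModelSpec(family=fam, time_power=0.5, df_mu=0.0, df_sigma=0.0)
    trace = []

    def objective(v):
        dmu = float(np.clip(v[0], df_lo, df_hi))
        dsg = float(np.clip(v[1], df_lo, df_hi))
        power = float(np.clip(v[2], p_lo, p_hi))
        spec = replace(base, time_power=power, df_mu=dmu, df_sigma=dsg)
        try:
            model = fit_gamlss(data, spec, **fit_kwargs)
            value = model_sbc(model)
        except FlexchartError as exc:
            logger.debug("hyperopt eval failed at %s: %s", v, exc)
            value = np.inf
        trace.append({"df_mu": dmu, "df_sigma": dsg, "power": power, "sbc": value})
        return value

    objective(x0)  # anchor: the returned optimum can never be worse than init
    rng = np.random.default_rng(seed)
    starts = [x0] + [
        x0 + rng.normal(0, [0.8, 0.5, 0.12], size=3) for _ in range(n_starts - 1)
    ]
    for s in starts:
        s = np.clip(s, [df_lo, df_lo, p_lo], [df_hi, df_hi, p_hi])
        minimize(
            objective,
            s,
            method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 0.05, "fatol": 0.5},
        )
    finite = [t for t in trace if np.isfinite(t["sbc"])]
    if not finite:
        raise ConvergenceError("every hyperparameter evaluation failed")
    best = min(finite, key=lambda t: t["sbc"])
    best_spec = replace(
        base, time_power=best["power"], df_mu=best["df_mu"], df_sigma=best["df_sigma"]
    )
    return best_spec, best["sbc"], trace
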