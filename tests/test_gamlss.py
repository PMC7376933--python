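"""Backfitting correctness: closed forms, deviance behaviour, df accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

from flexchart.exceptions import ConvergenceError, DataValidationError
from flexchart.gamlss import (
    FittedCentileModel,
    ModelSpec,
    fit_gamlss,
    global_deviance,
    model_df,
)
from flexchart.simulate import GeneratorConfig, TrueModel


def _frame(day, y):
    return pd.DataFrame({"day_post_op": day, "flexion_deg": y})


def _constant_model(family, eta_by_param, links):
    spec_kwargs = {p: None for p in ("df_mu", "df_sigma", "df_nu", "df_tau")}
    spec = ModelSpec(family=family, **spec_kwargs)
    terms = {p: {"type": "constant", "eta": e} for p, e in eta_by_param.items()}
    return FittedCentileModel(
        spec=spec, links=links, terms=terms, global_deviance=np.nan,
        n_obs=0, n_iter=0, converged=True,
    )


def test_normal_intercept_matches_closed_form_mle(rng):
    y = rng.normal(100, 12, 200)
    day = rng.integers(2, 121, 200).astype(float)
    m = fit_gamlss(_frame(day, y), ModelSpec(family="NO", df_mu=None, df_sigma=None))
    pars = m.params_at([10.0])
    assert pars["mu"][0] == pytest.approx(y.mean(), abs=1e-6)
    assert pars["sigma"][0] == pytest.approx(y.std(ddof=0), abs=1e-6)


def test_gamma_intercept_matches_brute_force(rng):
    y = rng.gamma(30.0, 3.5, 200)
    day = rng.integers(2, 121, 200).astype(float)
    m = fit_gamlss(_frame(day, y), ModelSpec(family="GA", df_mu=None, df_sigma=None))

    def neg2ll(v):  # independent oracle on the conventional shape/scale axes
        shape, scale = np.exp(v)
        return -2.0 * stats.gamma.logpdf(y, shape, scale=scale).sum()

    res = minimize(neg2ll, [np.log(30.0), np.log(3.5)], method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-11, "maxfev": 4000})
    assert m.global_deviance == pytest.approx(res.fun, abs=1e-3)


def test_deviance_closed_form_single_observation():
    m = _constant_model(
        "NO", {"mu": 0.0, "sigma": 0.0}, {"mu": "identity", "sigma": "log"}
    )
    dev = global_deviance(m, _frame([5.0], [0.0]))  # y = 0 at NO(0, 1)
    assert dev == pytest.approx(np.log(2 * np.pi), abs=1e-9)


def test_deviance_order_invariance(small_cohort):
    spec = ModelSpec(family="NO", time_power=0.56, df_mu=2.0, df_sigma=1.0)
    m = fit_gamlss(small_cohort, spec)
    shuffled = small_cohort.frame.sample(frac=1.0, random_state=0)
    assert global_deviance(m, shuffled) == pytest.approx(
        global_deviance(m, small_cohort.frame), rel=1e-12
    )


def test_nested_models_deviance_decreases(small_cohort):
    base = ModelSpec(family="NO", time_power=0.56, df_mu=0.0, df_sigma=None)
    rich = ModelSpec(family="NO", time_power=0.56, df_mu=4.0, df_sigma=None)
    dev0 = fit_gamlss(small_cohort, base).global_deviance
    dev1 = fit_gamlss(small_cohort, rich).global_deviance
    assert dev1 <= dev0 + 1e-6


def test_outer_deviance_trace_monotone(default_cohort):
    spec = ModelSpec(family="BCCG", time_power=0.56, df_mu=2.2, df_sigma=1.2)
    m = fit_gamlss(default_cohort, spec)
    diffs = np.diff(m.deviance_trace)
    assert np.all(diffs <= 1e-6)


def test_fitted_z_scores_calibrated(default_cohort):
    spec = ModelSpec(family="BCCG", time_power=0.56, df_mu=2.2, df_sigma=1.2)
    m = fit_gamlss(default_cohort, spec)
    z = m.z_scores(
        default_cohort.frame["day_post_op"].to_numpy(),
        default_cohort.frame["flexion_deg"].to_numpy(),
    )
    assert -0.1 < z.mean() < 0.1
    assert 0.9 < z.var() < 1.1


def test_median_curve_recovery(default_cohort):
    cfg = GeneratorConfig(n_patients=500, seed=1)
    truth = TrueModel(cfg)
    spec = ModelSpec(family="BCCG", time_power=0.56, df_mu=2.2, df_sigma=1.2)
    m = fit_gamlss(default_cohort, spec)
    days = np.arange(2, 121, dtype=float)
    rmse = float(np.sqrt(np.mean((m.median(days) - truth.median(days)) ** 2)))
    assert rmse <= 2.0


@pytest.mark.parametrize(
    "family,kwargs,expected",
    [
        ("NO", dict(df_mu=2.2, df_sigma=1.2), 7.4),
        ("GA", dict(df_mu=2.2, df_sigma=1.2), 7.4),
        ("TF", dict(df_mu=2.2, df_sigma=1.2, df_nu=None), 8.4),
        ("BCCG", dict(df_mu=2.2, df_sigma=1.2, df_nu=None), 8.4),
        ("BCT", dict(df_mu=2.2, df_sigma=1.2, df_nu=None, df_tau=None), 9.4),
        ("BCPE", dict(df_mu=2.2, df_sigma=1.2, df_nu=None, df_tau=None), 9.4),
        ("NO", dict(df_mu=None, df_sigma=None), 2.0),
    ],
)
def test_df_accounting(family, kwargs, expected):
    spec = ModelSpec(family=family, **kwargs)
    assert model_df(spec) == pytest.approx(expected)


def test_spec_rejects_extraneous_parameters():
    with pytest.raises(ValueError, match="no parameter tau"):
        ModelSpec(family="BCCG", df_tau=1.0)
    with pytest.raises(ValueError, match="no parameter nu"):
        ModelSpec(family="NO", df_nu=2.0)


def test_spec_accepts_constant_keyword():
    spec = ModelSpec(family="BCCG", df_mu=2.2, df_sigma="constant", df_nu="constant")
    assert spec.df_sigma is None and spec.df_nu is None
    assert spec.total_df == pytest.approx(4.2 + 1 + 1)


def test_support_violation_rejected(rng):
    day = rng.integers(2, 121, 20).astype(float)
    y = rng.normal(100, 10, 20)
    y[3] = -5.0
    with pytest.raises(DataValidationError, match="positive"):
        fit_gamlss(_frame(day, y), ModelSpec(family="BCCG"))


def test_too_few_observations_rejected(rng):
    with pytest.raises(DataValidationError, match="at least"):
        fit_gamlss(_frame([5.0] * 4, [100.0] * 4), ModelSpec(family="NO"))


def test_nonconvergence_raises_with_trace(small_cohort):
    spec = ModelSpec(family="BCCG", time_power=0.56, df_mu=2.2, df_sigma=1.2)
    with pytest.raises(ConvergenceError) as err:
        fit_gamlss(small_cohort, spec, max_iter=1)
    assert len(err.value.deviance_trace) >= 2
    m = fit_gamlss(small_cohort, spec, max_iter=1, strict=False)
    assert not m.converged
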