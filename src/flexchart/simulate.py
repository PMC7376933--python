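"""Synthetic cohorts with known ground-truth centile curves.

The generator emulates routine-rehabilitation flexion data over the first
120 postoperative days: a positive outcome whose median rises fast and
then plateaus, a relative spread that shrinks as patients recover, mild
left skew (slow recoverers dominate the lower tail), semi-weekly visits,
and staggered entry into observation.

Ground truth uses closed forms so every pipeline stage has an exact
oracle:

* median   mu(t)   = mu_inf - (mu_inf - mu_0) * exp(-t / theta),
  defaults mu_0 = 80 deg, mu_inf = 116 deg, theta = 25 days -- the implied
  quartile band is roughly 70-90 deg right after surgery, 95-115 deg at
  one month and 109-122 deg at three months;
* scale    sigma(t) log-linear from 0.18 at day 2 down to 0.085 at day
  120 (interquartile range roughly 13-22 deg throughout);
* skewness nu constant, default 2 (left skew);
* response drawn from a Box-Cox family (default BCCG) at the true curves.

Visit process: a patient enters observation either immediately (first
visit uniform on days 2-7) or part-way through recovery (uniform on days
8-110, emulating patients transferring into the clinic network after
starting rehabilitation elsewhere); subsequent visits follow every 3-4
days; after each visit the episode ends with a fixed dropout hazard; at
most 10 visits, truncated at day 120.  The defaults give about three
observations per patient, so 500 patients yield roughly 1,500-1,700
observations spread over the whole window.

An optional multiplicative per-patient random effect on mu induces
within-patient correlation; the default of zero gives exactly independent
draws from the configured family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .data_io import CohortTable
from .distributions import centile_value, get_family
from .exceptions import ConfigError


@dataclass(frozen=True)
class TrueCurves:
    """Closed-form ground-truth parameter curves on the day scale."""

    mu_0: float = 80.0       # median immediately after surgery, degrees
    mu_inf: float = 116.0    # plateau median, degrees
    theta: float = 25.0      # recovery time constant, days
    sigma_start: float = 0.18   # relative scale at sigma_days[0]
    sigma_end: float = 0.085    # relative scale at sigma_days[1]
    sigma_days: tuple = (2.0, 120.0)
    nu: float = 2.0          # Box-Cox skewness power (constant)
    tau: float | None = None  # kurtosis parameter where the family needs one

    def mu(self, day):
        day = np.asarray(day, dtype=float)
        out = self.mu_inf - (self.mu_inf - self.mu_0) * np.exp(-day / self.theta)
        return float(out) if out.ndim == 0 else out

    def sigma(self, day):
        day = np.asarray(day, dtype=float)
        d0, d1 = self.sigma_days
        frac = np.clip((day - d0) / (d1 - d0), 0.0, 1.0)
        out = self.sigma_start * (self.sigma_end / self.sigma_start) ** frac
        return float(out) if out.ndim == 0 else out

    def params_at(self, day):
        pars = {"mu": self.mu(day), "sigma": self.sigma(day)}
        return pars


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic cohort."""

    n_patients: int = 500
    family: str = "BCCG"
    curves: TrueCurves = field(default_factory=TrueCurves)
    surgery_start: date = date(2013, 1, 1)
    surgery_end: date = date(2016, 5, 31)
    p_immediate: float = 0.4      # fraction entering observation at days 2-7
    late_entry_days: tuple = (8, 110)
    visit_gap_days: tuple = (3, 4)
    dropout_hazard: float = 0.30  # per-visit probability the episode ends
    max_visits: int = 10
    max_day: int = 120
    patient_effect_sd: float = 0.0  # sd of the log-scale random effect on mu
    seed: int = 0


class TrueModel:
    """Predictor wrapper over the true curves (same protocol as a fitted model)."""

    def __init__(self, config_or_curves, family=None):
        if isinstance(config_or_curves, GeneratorConfig):
            self.curves = config_or_curves.curves
            self.family = get_family(config_or_curves.family).name
        else:
            self.curves = config_or_curves
            self.family = get_family(family or "BCCG").name

    def params_at(self, day):
        fam = get_family(self.family)
        pars = self.curves.params_at(day)
        day_arr = np.atleast_1d(np.asarray(day, dtype=float))
        if fam.name in ("NO", "TF"):
            # curves.sigma is a relative (CV-like) scale; NO/TF take degrees
            pars["sigma"] = pars["sigma"] * pars["mu"]
        if "nu" in fam.param_names:
            pars["nu"] = np.full(day_arr.shape, self.curves.nu)
        if "tau" in fam.param_names:
            if self.curves.tau is None:
                raise ConfigError(f"family {self.family} needs a tau in TrueCurves")
            pars["tau"] = np.full(day_arr.shape, self.curves.tau)
        return pars

    def median(self, day):
        return self.curves.mu(day)

    def centile(self, day, alpha):
        return centile_value(self.family, alpha, **self.params_at(day))


def true_centile(config, day, alpha):
    """Exact ground-truth centile at a day; oracle for recovery/coverage tests."""
    return TrueModel(config).centile(day, alpha)


def _visit_days(rng, config):
    if rng.uniform() < config.p_immediate:
        day = int(rng.integers(2, 8))
    else:
        lo, hi = config.late_entry_days
        day = int(rng.integers(lo, hi + 1))
    days = [day]
    glo, ghi = config.visit_gap_days
    while len(days) < config.max_visits:
        if rng.uniform() < config.dropout_hazard:
            break
        day = day + int(rng.integers(glo, ghi + 1))
        if day > config.max_day:
            break
        days.append(day)
    return days


def generate_cohort(config=None, **overrides):
    """Draw a synthetic cohort; byte-identical output for a given seed."""
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    if config.n_patients < 0:
        raise ConfigError("n_patients must be >= 0")
    curves = config.curves
    if curves.mu_0 <= 0 or curves.mu_inf <= 0:
        raise ConfigError("true median curve must be strictly positive")
    if curves.mu_inf <= curves.mu_0:
        raise ConfigError("mu_inf must exceed mu_0 (recovery must be rising)")
    fam = get_family(config.family)
    model = TrueModel(config)

    rng = np.random.default_rng(config.seed)
    span = (config.surgery_end - config.surgery_start).days
    rows = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        sdate = config.surgery_start + timedelta(days=int(rng.integers(0, span + 1)))
        days = _visit_days(rng, config)
        effect = (
            float(np.exp(rng.normal(0.0, config.patient_effect_sd)))
            if config.patient_effect_sd > 0
            else 1.0
        )
        pars = model.params_at(days)
        pars["mu"] = pars["mu"] * effect
        u = rng.uniform(low=1e-12, high=1.0 - 1e-12, size=len(days))
        y = centile_value(fam, u, **pars)
        for d, v in zip(days, np.atleast_1d(y)):
            rows.append((pid, sdate.isoformat(), int(d), float(np.round(v, 4))))

    frame = pd.DataFrame(
        rows, columns=["patient_id", "surgery_date", "day_post_op", "flexion_deg"]
    )
    frame["surgery_date"] = pd.to_datetime(frame["surgery_date"])
    return CohortTable(frame, provenance=f"synthetic seed={config.seed}")


def generate_demographics(config=None, **overrides):
    """Per-patient age, BMI and sex with TKA-typical moments.

    Defaults: age ~ N(64.3, 9.4) years, BMI ~ N(32.9, 6.6) kg/m2,
    P(female) = 0.571.  Seeded independently of the outcome stream.
    """
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 90210]))
    n = config.n_patients
    frame = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:05d}" for i in range(n)],
            "age": np.round(rng.normal(64.3, 9.4, size=n), 1),
            "bmi": np.round(rng.normal(32.9, 6.6, size=n), 1),
            "sex": np.where(rng.uniform(size=n) < 0.571, "F", "M"),
        }
    )
    return frame
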