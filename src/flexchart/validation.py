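"""Temporal out-of-sample validation of a reference chart.

The cohort is split by surgery date: patients are ordered by date and the
cut falls between patients at the point where the cumulative measurement
count first reaches the target fraction (default 75%), so the development
set holds the earlier measurements, the test set the later ones, and no
patient straddles the split.  Performance on the test set is summarised
by per-centile coverage with two-sided z-tests for proportions, and the
average bias — the mean difference between observed flexion and the
model's predicted median (negative: observations sit below the curves).
Cohort comparability (age, BMI, sex) uses Welch t-tests and a
continuity-corrected chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chart import DEFAULT_LEVELS, coverage
from .data_io import CohortTable
from .exceptions import DataValidationError


def temporal_split(table, fraction=0.75):
    """Development/test split by surgery date, respecting patients.

    Patients are ordered by (surgery_date, patient_id); the development set
    is the shortest prefix of patients whose cumulative measurement count
    reaches ``fraction`` of all measurements.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    frame = table.frame
    if frame["surgery_date"].isna().any():
        raise DataValidationError("every patient needs a surgery date")
    counts = (
        frame.groupby(["patient_id"])
        .agg(surgery_date=("surgery_date", "first"), n=("day_post_op", "size"))
        .reset_index()
        .sort_values(["surgery_date", "patient_id"], kind="mergesort")
    )
    total = int(counts["n"].sum())
    target = fraction * total
    cum = counts["n"].cumsum()
    n_dev_patients = int(np.searchsorted(cum.to_numpy(), target) + 1)
    n_dev_patients = min(n_dev_patients, len(counts))
    dev_ids = set(counts["patient_id"].iloc[:n_dev_patients])
    dev_mask = frame["patient_id"].isin(dev_ids)
    dev = CohortTable(frame[dev_mask], provenance=f"{table.provenance} | development")
    test = CohortTable(frame[~dev_mask], provenance=f"{table.provenance} | test")
    return dev, test


def proportion_z_test(observed_prop, expected_prop, n):
    """One-sample z-test for a proportion against its nominal value.

    z = (p_obs - p_exp) / sqrt(p_exp (1 - p_exp) / n), two-sided p, no
    continuity correction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < expected_prop < 1.0:
        raise ValueError("expected proportion must lie strictly in (0, 1)")
    if not 0.0 <= observed_prop <= 1.0:
        raise ValueError("observed proportion must lie in [0, 1]")
    se = np.sqrt(expected_prop * (1.0 - expected_prop) / n)
    z = (observed_prop - expected_prop) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def average_bias(model, data):
    """Mean of (observed flexion - predicted median), in degrees."""
    frame = data.frame if hasattr(data, "frame") else data
    if len(frame) == 0:
        raise DataValidationError("average bias is undefined on empty data")
    pred = model.median(np.asarray(frame["day_post_op"], dtype=float))
    return float(np.mean(np.asarray(frame["flexion_deg"], dtype=float) - pred))


@dataclass
class ValidationReport:
    """Out-of-sample chart performance on a test cohort."""

    table: pd.DataFrame  # level, expected_pct, observed_pct, n, z, p
    average_bias: float
    n_records: int
    n_patients: int

    def all_nonsignificant(self, alpha=0.05):
        return bool((self.table["p"] > alpha).all())

    def to_dict(self):
        return {
            "levels": self.table.to_dict(orient="records"),
            "average_bias_deg": self.average_bias,
            "n_records": self.n_records,
            "n_patients": self.n_patients,
        }


def validate_model(model, test_data, levels=DEFAULT_LEVELS):
    """Coverage z-tests and average bias of a fitted model on test data."""
    cov = coverage(model, test_data, levels=levels)
    rows = []
    for r in cov.table.itertuples():
        z, p = proportion_z_test(r.observed_pct / 100.0, r.level, r.n)
        rows.append((r.level, r.expected_pct, r.observed_pct, r.n, z, p))
    table = pd.DataFrame(
        rows, columns=["level", "expected_pct", "observed_pct", "n", "z", "p"]
    )
    frame = test_data.frame if hasattr(test_data, "frame") else test_data
    return ValidationReport(
        table=table,
        average_bias=average_bias(model, test_data),
        n_records=len(frame),
        n_patients=frame["patient_id"].nunique()
        if "patient_id" in frame.columns
        else 0,
    )


def compare_cohorts(dev_demo, test_demo):
    """Demographic comparability: Welch t for age/BMI, Yates chi-square for sex.

    Returns a table with group summaries (mean ± sd for continuous fields,
    % female for sex), the test statistic and the two-sided p-value.
    All-missing columns are skipped with a note.
    """
    rows = []
    for col in ("age", "bmi"):
        if col not in dev_demo.columns or col not in test_demo.columns:
            continue
        a = pd.to_numeric(dev_demo[col], errors="coerce").dropna()
        b = pd.to_numeric(test_demo[col], errors="coerce").dropna()
        if len(a) == 0 or len(b) == 0:
            rows.append((col, "all missing", "all missing", np.nan, np.nan, "skipped"))
            continue
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            (
                col,
                f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
                f"{b.mean():.1f} ± {b.std(ddof=1):.1f}",
                float(stat),
                float(p),
                "Welch t",
            )
        )
    if "sex" in dev_demo.columns and "sex" in test_demo.columns:
        a = dev_demo["sex"].dropna()
        b = test_demo["sex"].dropna()
        if len(a) and len(b):
            tab = np.array(
                [
                    [(a == "F").sum(), (a != "F").sum()],
                    [(b == "F").sum(), (b != "F").sum()],
                ]
            )
            res = stats.chi2_contingency(tab, correction=True)
            rows.append(
                (
                    "sex",
                    f"{100.0 * (a == 'F').mean():.1f}% F",
                    f"{100.0 * (b == 'F').mean():.1f}% F",
                    float(res.statistic),
                    float(res.pvalue),
                    "chi-square (Yates)",
                )
            )
        else:
            rows.append(("sex", "all missing", "all missing", np.nan, np.nan, "skipped"))
    return pd.DataFrame(
        rows, columns=["variable", "development", "test", "statistic", "p", "test_name"]
    )
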