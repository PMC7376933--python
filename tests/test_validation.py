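"""Temporal split arithmetic, proportion z-tests, bias, cohort comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from flexchart.data_io import CohortTable
from flexchart.exceptions import DataValidationError
from flexchart.simulate import (
    GeneratorConfig,
    TrueCurves,
    TrueModel,
    generate_cohort,
    generate_demographics,
)
from flexchart.validation import (
    average_bias,
    compare_cohorts,
    proportion_z_test,
    temporal_split,
    validate_model,
)


def _cohort_with_counts(counts):
    """One patient per count, surgery dates strictly increasing."""
    rows = []
    start = pd.Timestamp("2013-01-01")
    for i, c in enumerate(counts):
        for j in range(c):
            rows.append((f"P{i:04d}", start + pd.Timedelta(days=i), 5 + j, 90.0))
    return CohortTable(
        pd.DataFrame(
            rows,
            columns=["patient_id", "surgery_date", "day_post_op", "flexion_deg"],
        )
    )


def test_temporal_split_measurement_count_cut():
    """With per-patient counts summing to 1550 where the first 327 patients
    hold 1173 measurements, a 75% measurement cut keeps exactly those
    patients in development (1173/1550 = 75.7%) and 171/377 in test."""
    counts = [4] * 184 + [3] * 142 + [11] + [3] * 35 + [2] * 136
    assert sum(counts) == 1550 and sum(counts[:327]) == 1173
    table = _cohort_with_counts(counts)
    dev, test = temporal_split(table, fraction=0.75)
    assert (dev.n_patients, dev.n_records) == (327, 1173)
    assert (test.n_patients, test.n_records) == (171, 377)


def test_temporal_split_boundary_and_partition(small_cohort):
    dev, test = temporal_split(small_cohort, fraction=1.0)
    assert dev.n_records == small_cohort.n_records and test.n_records == 0

    dev, test = temporal_split(small_cohort, fraction=0.75)
    assert dev.n_records + test.n_records == small_cohort.n_records
    assert not set(dev.frame["patient_id"]) & set(test.frame["patient_id"])
    # brute-force order property: every development surgery precedes test ones
    assert dev.frame["surgery_date"].max() <= test.frame["surgery_date"].min()
    # within one patient's worth of the target
    last = dev.frame.groupby("patient_id").size().max()
    assert abs(dev.n_records - 0.75 * small_cohort.n_records) <= last


def test_proportion_z_trivials():
    z, p = proportion_z_test(0.25, 0.25, 400)
    assert z == 0.0 and p == 1.0
    z1, _ = proportion_z_test(0.6, 0.5, 100)
    z2, _ = proportion_z_test(0.6, 0.5, 200)
    assert z2 == pytest.approx(z1 * np.sqrt(2))


def test_proportion_z_worked_comparison():
    """80% observed below the 75th centile at n = 377: z ≈ 2.24, p ≈ 0.025
    (0.03 when the observed proportion is rounded from e.g. 301/377)."""
    z, p = proportion_z_test(0.80, 0.75, 377)
    assert z == pytest.approx(2.2417, abs=1e-3)
    assert p == pytest.approx(0.0250, abs=1e-3)


@settings(max_examples=50, deadline=None)
@given(
    st.floats(0.0, 1.0),
    st.floats(0.02, 0.98),
    st.integers(1, 10_000),
)
def test_proportion_z_matches_textbook_oracle(obs, exp, n):
    z, p = proportion_z_test(obs, exp, n)
    se = (exp * (1 - exp) / n) ** 0.5
    z_ref = (obs - exp) / se
    p_ref = 2 * (1 - stats.norm.cdf(abs(z_ref)))
    assert z == pytest.approx(z_ref, abs=1e-9)
    assert p == pytest.approx(p_ref, abs=1e-9)


def test_proportion_z_domain():
    with pytest.raises(ValueError):
        proportion_z_test(0.5, 0.0, 100)
    with pytest.raises(ValueError):
        proportion_z_test(0.5, 0.5, 0)


def test_average_bias_definitions():
    model = TrueModel(GeneratorConfig())
    one = pd.DataFrame(
        {"day_post_op": [30.0], "flexion_deg": [model.median(30.0) + 3.0]}
    )
    assert average_bias(model, one) == pytest.approx(3.0, abs=1e-9)

    frame = generate_cohort(GeneratorConfig(n_patients=60, seed=9)).frame
    base = average_bias(model, frame)
    shifted = frame.assign(flexion_deg=frame["flexion_deg"] + 5.0)
    assert average_bias(model, shifted) == pytest.approx(base + 5.0, abs=1e-9)

    with pytest.raises(DataValidationError):
        average_bias(model, frame.iloc[0:0])


def test_average_bias_unbiased_under_symmetric_model():
    """Under a symmetric generating family the median predictor is unbiased."""
    cfg = GeneratorConfig(n_patients=3000, family="NO",
                          curves=TrueCurves(nu=0.0), seed=12)
    table = generate_cohort(cfg)
    bias = average_bias(TrueModel(cfg), table)
    assert abs(bias) < 0.5


def test_validate_model_report_shape(small_cohort):
    model = TrueModel(GeneratorConfig())
    rep = validate_model(model, small_cohort)
    assert list(rep.table["level"]) == [0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95]
    assert ((rep.table["p"] >= 0) & (rep.table["p"] <= 1)).all()
    assert rep.n_records == small_cohort.n_records
    assert np.isfinite(rep.average_bias)


def test_compare_identical_cohorts():
    demo = generate_demographics(GeneratorConfig(n_patients=200, seed=3))
    out = compare_cohorts(demo, demo)
    cont = out[out["variable"].isin(["age", "bmi"])]
    assert np.allclose(cont["p"], 1.0)
    sex_p = float(out[out["variable"] == "sex"]["p"].iloc[0])
    assert sex_p == pytest.approx(1.0)


def test_sex_table_chi_square_worked_example():
    """Female/male counts from 57.1% of 327 vs 55.7% of 171 give a
    continuity-corrected chi-square near 0.06 and p near 0.8."""
    dev = pd.DataFrame({"sex": ["F"] * 187 + ["M"] * 140})
    test = pd.DataFrame({"sex": ["F"] * 95 + ["M"] * 76})
    out = compare_cohorts(dev, test)
    row = out[out["variable"] == "sex"].iloc[0]
    # textbook Yates statistic computed from scratch
    tab = np.array([[187, 140], [95, 76]], dtype=float)
    exp = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
    yates = ((np.abs(tab - exp) - 0.5).clip(min=0) ** 2 / exp).sum()
    assert row["statistic"] == pytest.approx(yates, abs=1e-9)
    assert row["p"] == pytest.approx(stats.chi2.sf(yates, 1), abs=1e-9)
    assert 0.7 <= row["p"] <= 0.9
    assert row["statistic"] < 0.2


def test_compare_cohorts_type_one_error_calibrated():
    """Same-distribution cohorts: about 5% of Welch tests significant."""
    n_sig = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        a = pd.DataFrame({"age": rng.normal(64.3, 9.4, 120)})
        b = pd.DataFrame({"age": rng.normal(64.3, 9.4, 80)})
        out = compare_cohorts(a, b)
        n_sig += float(out["p"].iloc[0]) < 0.05
    assert n_sig <= 11  # Binomial(100, .05): P(>11) < 0.005


def test_missing_demographics_skipped():
    dev = pd.DataFrame({"age": [np.nan, np.nan], "sex": ["F", "M"]})
    test = pd.DataFrame({"age": [60.0, 70.0], "sex": ["F", "M"]})
    out = compare_cohorts(dev, test)
    assert (out[out["variable"] == "age"]["test_name"] == "skipped").all()
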