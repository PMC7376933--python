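"""Cohort ingest, window filtering, and model-file round trips."""

import json

import numpy as np
import pandas as pd
import pytest

from flexchart.chart import build_chart
from flexchart.data_io import (
    CohortTable,
    deserialize_model,
    filter_window,
    read_cohort,
    serialize_model,
)
from flexchart.exceptions import ConfigError, DataValidationError, SerializationError
from flexchart.gamlss import ModelSpec, fit_gamlss


def _write_csv(path, rows, header="patient_id,surgery_date,day_post_op,flexion_deg"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


def test_basic_ingest(tmp_path):
    p = _write_csv(
        tmp_path / "c.csv",
        ["A,2014-01-02,5,75", "A,2014-01-02,9,82.5", "B,2014-03-01,12,90"],
    )
    table = read_cohort(p)
    assert table.n_records == 3
    assert table.n_patients == 2
    assert list(table.frame["flexion_deg"]) == [75.0, 82.5, 90.0]


def test_nonpositive_flexion_names_row(tmp_path):
    p = _write_csv(
        tmp_path / "c.csv", ["A,2014-01-02,5,75", "B,2014-01-02,9,0"]
    )
    with pytest.raises(DataValidationError, match=r"\[1\]"):
        read_cohort(p)


def test_missing_column_is_config_error(tmp_path):
    p = (tmp_path / "c.csv")
    p.write_text("patient_id,surgery_date,flexion_deg\nA,2014-01-02,75\n")
    with pytest.raises(ConfigError, match="day_post_op"):
        read_cohort(p)


def test_column_remapping(tmp_path):
    p = (tmp_path / "c.csv")
    p.write_text("mrn,dos,pod,flex\nA,2014-01-02,5,75\n")
    table = read_cohort(
        p,
        column_map={"mrn": "patient_id", "dos": "surgery_date",
                    "pod": "day_post_op", "flex": "flexion_deg"},
    )
    assert table.n_records == 1


def test_bad_dates_rejected_with_rows(tmp_path):
    p = _write_csv(
        tmp_path / "c.csv", ["A,2014-01-02,5,75", "B,not-a-date,9,80"]
    )
    with pytest.raises(DataValidationError, match=r"\[1\]"):
        read_cohort(p)


def test_conflicting_surgery_dates_rejected():
    frame = pd.DataFrame(
        {
            "patient_id": ["A", "A"],
            "surgery_date": pd.to_datetime(["2014-01-01", "2014-02-01"]),
            "day_post_op": [5, 9],
            "flexion_deg": [75.0, 80.0],
        }
    )
    with pytest.raises(DataValidationError, match="conflicting surgery dates"):
        CohortTable(frame)


def test_cohort_roundtrip(tmp_path, small_cohort):
    path = tmp_path / "cohort.csv"
    small_cohort.write_csv(path)
    back = read_cohort(path)
    pd.testing.assert_frame_equal(
        back.frame[small_cohort.frame.columns], small_cohort.frame
    )


def test_window_closed_interval():
    frame = pd.DataFrame(
        {
            "patient_id": list("ABCD"),
            "surgery_date": pd.to_datetime(["2014-01-01"] * 4),
            "day_post_op": [1, 2, 120, 121],
            "flexion_deg": [70.0, 75.0, 110.0, 112.0],
        }
    )
    kept, removed = filter_window(CohortTable(frame), 2, 120, return_counts=True)
    assert sorted(kept.frame["day_post_op"]) == [2, 120]
    assert removed == 2


def test_window_identity_and_partition(small_cohort):
    same = filter_window(small_cohort, 0, 10**6)
    assert same.n_records == small_cohort.n_records
    kept, removed = filter_window(small_cohort, 10, 60, return_counts=True)
    days = small_cohort.frame["day_post_op"]
    brute = int(((days >= 10) & (days <= 60)).sum())
    assert kept.n_records == brute
    assert kept.n_records + removed == small_cohort.n_records


def test_empty_window_warns(small_cohort):
    with pytest.warns(UserWarning, match="removed every record"):
        filter_window(small_cohort, 500, 600)


def test_invalid_window_rejected(small_cohort):
    with pytest.raises(ValueError):
        filter_window(small_cohort, 50, 10)


@pytest.fixture(scope="module")
def fitted_model(small_cohort):
    spec = ModelSpec(family="BCCG", time_power=0.56, df_mu=2.0, df_sigma=1.0)
    return fit_gamlss(small_cohort, spec)


def test_model_roundtrip_preserves_predictions(tmp_path, fitted_model):
    path = tmp_path / "model.json"
    serialize_model(fitted_model, path)
    back = deserialize_model(path)
    days = np.linspace(2, 120, 10)
    for alpha in (0.05, 0.5, 0.95):
        np.testing.assert_allclose(
            back.centile(days, alpha),
            fitted_model.centile(days, alpha),
            rtol=1e-9,
        )
    assert back.global_deviance == fitted_model.global_deviance
    assert back.total_df == fitted_model.total_df


def test_chart_from_reloaded_model_matches(tmp_path, fitted_model):
    path = tmp_path / "model.json"
    serialize_model(fitted_model, path)
    original = build_chart(fitted_model)
    reloaded = build_chart(deserialize_model(path))
    np.testing.assert_allclose(reloaded.values, original.values, rtol=1e-9)


def test_truncated_model_file_rejected(tmp_path, fitted_model):
    path = tmp_path / "model.json"
    serialize_model(fitted_model, path)
    path.write_text(path.read_text()[: len(path.read_text()) // 2])
    with pytest.raises(SerializationError):
        deserialize_model(path)


def test_version_mismatch_rejected(tmp_path, fitted_model):
    path = tmp_path / "model.json"
    serialize_model(fitted_model, path)
    payload = json.loads(path.read_text())
    payload["version"] = 999
    path.write_text(json.dumps(payload))
    with pytest.raises(SerializationError, match="version"):
        deserialize_model(path)
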