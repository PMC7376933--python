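"""Reading, writing and filtering long-format cohort tables; model files.

A cohort is a long-format table of repeated flexion measurements:
one row per clinic visit with columns ``patient_id``, ``surgery_date``
(ISO-8601), ``day_post_op`` (whole days since surgery, surgery = day 0)
and ``flexion_deg`` (knee flexion AROM in degrees, strictly positive).
Clinical exports use varying column names, so :func:`read_cohort` accepts
a remapping.  Same-day duplicate measurements for a patient are kept and
reported through the module logger.

Fitted models serialise to a self-describing JSON text file (family, time
power, link functions, per-parameter knot/value vectors, penalties and fit
metadata) so that a model is inspectable and diffable; reloading restores
predictions exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataValidationError, SerializationError
from .gamlss import FittedCentileModel, ModelSpec

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "surgery_date", "day_post_op", "flexion_deg")
OPTIONAL_COLUMNS = ("age", "bmi", "sex")

MODEL_FORMAT = "flexchart-model"
MODEL_VERSION = 1


@dataclass
class CohortTable:
    """Ordered collection of flexion observations with provenance.

    Wraps a pandas DataFrame carrying at least :data:`REQUIRED_COLUMNS`.
    Invariants checked at construction: flexion strictly positive,
    non-negative integer days, and one surgery date per patient.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        frame = self.frame.reset_index(drop=True)
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigError(f"cohort table missing columns: {missing}")
        flex = pd.to_numeric(frame["flexion_deg"], errors="coerce")
        bad = frame.index[~(flex > 0)].tolist()
        if bad:
            raise DataValidationError(
                f"flexion_deg must be strictly positive; offending rows: {bad}"
            )
        days = pd.to_numeric(frame["day_post_op"], errors="coerce")
        bad = frame.index[~(days >= 0)].tolist()
        if bad:
            raise DataValidationError(
                f"day_post_op must be a non-negative day count; offending rows: {bad}"
            )
        per_patient = frame.groupby("patient_id")["surgery_date"].nunique()
        conflicted = per_patient[per_patient > 1].index.tolist()
        if conflicted:
            raise DataValidationError(
                f"patients with conflicting surgery dates: {conflicted}"
            )
        dup = frame.duplicated(subset=["patient_id", "day_post_op"], keep=False)
        if dup.any():
            logger.info(
                "%d same-day duplicate measurements kept (rows %s)",
                int(dup.sum()), frame.index[dup].tolist(),
            )
        self.frame = frame

    @property
    def n_records(self):
        return len(self.frame)

    @property
    def n_patients(self):
        return self.frame["patient_id"].nunique()

    def write_csv(self, path):
        out = self.frame.copy()
        out["surgery_date"] = pd.to_datetime(out["surgery_date"]).dt.strftime(
            "%Y-%m-%d"
        )
        out.to_csv(path, index=False)


def read_cohort(path, column_map=None, provenance=None):
    """Read a long-format cohort CSV.

    ``column_map`` maps file column names to the canonical names, e.g.
    ``{"mrn": "patient_id"}``.  Malformed rows are rejected with
    row-numbered diagnostics (0-based data rows).
    """
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigError(
            f"{path}: missing required columns {missing}; "
            f"present: {list(raw.columns)}"
        )
    dates = pd.to_datetime(raw["surgery_date"], errors="coerce")
    bad = raw.index[dates.isna()].tolist()
    if bad:
        raise DataValidationError(f"{path}: unparseable surgery_date in rows {bad}")
    raw["surgery_date"] = dates
    keep = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in raw.columns]
    return CohortTable(raw[keep], provenance=provenance or str(path))


def filter_window(table, min_day=2, max_day=120, return_counts=False):
    """Keep records with min_day <= day_post_op <= max_day (closed interval)."""
    if min_day > max_day:
        raise ValueError("min_day must not exceed max_day")
    days = table.frame["day_post_op"]
    mask = (days >= min_day) & (days <= max_day)
    removed = int((~mask).sum())
    kept = CohortTable(
        table.frame[mask],
        provenance=f"{table.provenance} | window [{min_day}, {max_day}]",
    )
    logger.info("filter_window [%s, %s]: kept %d, removed %d",
                min_day, max_day, kept.n_records, removed)
    if kept.n_records == 0:
        warnings.warn(
            f"window [{min_day}, {max_day}] removed every record", stacklevel=2
        )
    if return_counts:
        return kept, removed
    return kept


def serialize_model(model, path):
    """Write a fitted model to a self-describing JSON text file."""
    spec = model.spec
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "family": spec.family,
        "time_power": spec.time_power,
        "df": {p: spec.df_for(p) for p in ("mu", "sigma", "nu", "tau")},
        "links": model.links,
        "terms": model.terms,
        "global_deviance": model.global_deviance,
        "total_df": model.total_df,
        "n_obs": model.n_obs,
        "n_iter": model.n_iter,
        "converged": model.converged,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def deserialize_model(path):
    """Reload a model file; predictions match the original to full precision."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise SerializationError(f"{path}: not a valid model file ({exc})") from exc
    if payload.get("format") != MODEL_FORMAT:
        raise SerializationError(f"{path}: not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise SerializationError(
            f"{path}: model file version {payload.get('version')} "
            f"!= supported {MODEL_VERSION}"
        )
    df = payload["df"]
    spec = ModelSpec(
        family=payload["family"],
        time_power=payload["time_power"],
        df_mu=df.get("mu"),
        df_sigma=df.get("sigma"),
        df_nu=df.get("nu"),
        df_tau=df.get("tau"),
    )
    return FittedCentileModel(
        spec=spec,
        links=payload["links"],
        terms=payload["terms"],
        global_deviance=payload["global_deviance"],
        n_obs=payload["n_obs"],
        n_iter=payload["n_iter"],
        converged=payload["converged"],
    )
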