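"""Readers and writers for cohort tables (comma-delimited UTF-8 with header row).

Every numeric column carries a unit suffix in its header (``_umol_L``,
``_kg``, ``_m`` ...).  Readers validate the schema hard (a missing
mandatory column is an error; a recognizable column with the wrong unit
suffix raises a unit-mismatch error rather than converting silently) and
quarantine rows that breach invariants, reporting line numbers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import SchemaError, UnitMismatchError
from .mass_balance import SOLUTES
from .synthetic import CohortTruth, OUTCOME_COLUMNS, PATIENT_COLUMNS, SESSION_COLUMNS

__all__ = ["read_cohort", "write_cohort", "write_truth", "CohortRead"]

log = logging.getLogger(__name__)

_PATIENT_REQUIRED = [c for c in PATIENT_COLUMNS if not c.startswith("cis_item")]
_SESSION_REQUIRED = list(SESSION_COLUMNS[:6])  # urine columns optional


class CohortRead(NamedTuple):
    patients: pd.DataFrame
    sessions: pd.DataFrame
    report: list[str]  # row-level warnings/quarantine messages


def _unit_stem(col: str) -> str:
    for suffix in ("_umol_L", "_umol_24h", "_g_L", "_g_dL", "_g_24h", "_mg_L", "_mg_dL",
                   "_kg", "_m", "_L", "_L_24h", "_months", "_years", "_h", "_m2"):
        if col.endswith(suffix):
            return col[: -len(suffix)]
    return col


def _check_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    present_stems = {_unit_stem(c): c for c in df.columns}
    for col in required:
        if col in df.columns:
            continue
        stem = _unit_stem(col)
        if stem in present_stems:
            raise UnitMismatchError(
                f"{table}: column {present_stems[stem]!r} has a different unit suffix than the "
                f"documented schema column {col!r}; convert upstream, units are never guessed"
            )
        raise SchemaError(f"{table}: mandatory column {col!r} missing")


def _quarantine(df: pd.DataFrame, bad: pd.Series, reason: str, report: list[str]) -> pd.DataFrame:
    if bad.any():
        for idx in df.index[bad]:
            msg = f"line {idx + 2}: {reason}; row quarantined"
            report.append(msg)
            log.warning(msg)
        df = df[~bad]
    return df


def read_cohort(patients_path: str | Path, sessions_path: str | Path) -> CohortRead:
    """Read and validate the patient and per-solute session tables."""
    report: list[str] = []
    try:
        patients = pd.read_csv(patients_path)
    except pd.errors.EmptyDataError:
        patients = pd.DataFrame()
    try:
        sessions = pd.read_csv(sessions_path)
    except pd.errors.EmptyDataError:
        sessions = pd.DataFrame()
    if patients.empty and len(patients.columns) == 0:
        log.warning("empty patients file %s", patients_path)
        return CohortRead(
            pd.DataFrame(columns=PATIENT_COLUMNS),
            pd.DataFrame(columns=SESSION_COLUMNS),
            ["patients file empty"],
        )
    _check_columns(patients, _PATIENT_REQUIRED, "patients")
    _check_columns(sessions, _SESSION_REQUIRED, "sessions")

    bad = (patients["weight_pre_kg"] <= 0) | (patients["weight_post_kg"] <= 0) | (
        patients["height_m"] <= 0
    )
    patients = _quarantine(patients, bad, "non-positive weight or height", report)
    bad = ~patients["sessions_per_week"].isin([2, 3])
    patients = _quarantine(patients, bad, "sessions_per_week not in {2, 3}", report)

    bad = ~sessions["solute"].isin(SOLUTES)
    sessions = _quarantine(sessions, bad, "unknown solute", report)
    for col in ("plasma_pre_umol_L", "plasma_post_umol_L", "dialysate_conc_umol_L"):
        sessions = _quarantine(sessions, sessions[col] < 0, f"negative {col}", report)
    sessions = _quarantine(
        sessions, sessions["dialysate_volume_L"] <= 0, "non-positive dialysate volume", report
    )
    known = set(patients["patient_id"])
    sessions = _quarantine(
        sessions, ~sessions["patient_id"].isin(known), "session for unknown patient", report
    )
    for c in ("urine_day1_umol_24h", "urine_day2_umol_24h"):
        if c not in sessions.columns:
            sessions[c] = np.nan
    return CohortRead(patients.reset_index(drop=True), sessions.reset_index(drop=True), report)


def write_cohort(patients: pd.DataFrame, sessions: pd.DataFrame, outdir: str | Path,
                 outcomes: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write cohort tables as CSV; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": outdir / "patients.csv",
        "sessions": outdir / "sessions.csv",
    }
    patients.to_csv(paths["patients"], index=False)
    sessions.to_csv(paths["sessions"], index=False)
    if outcomes is not None:
        paths["outcomes"] = outdir / "outcomes.csv"
        outcomes.to_csv(paths["outcomes"], index=False)
    return paths


def write_truth(truth: CohortTruth, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "truth.json"
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1)
    return path
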