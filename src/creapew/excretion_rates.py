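"""Daily excretion rates from per-session dialysate losses and urine collections.

A thrice-weekly dialysis schedule removes solute in discrete sessions; to
compare with continuous renal excretion both routes are expressed per
24 h:

* dialysate rate (μmol/24-h) = V_dialysate * D_X * n / 7, with n sessions
  per week,
* urinary rate (μmol/24-h) = mean of two 24-h urine collections (patients
  with residual diuresis > 200 mL/24-h only; all others are assigned a
  urinary rate of exactly 0),
* urinary contribution (%) = 100 * urinary / (urinary + dialysate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError

__all__ = [
    "ExcretionRates",
    "dialysate_excretion_rate",
    "urinary_excretion_rate",
    "urinary_contribution",
    "excretion_table",
    "contribution_summary",
]


@dataclass(frozen=True)
class ExcretionRates:
    """Per-patient per-solute daily rates (μmol/24-h) and urinary share (%)."""

    dialysate_rate: float
    urinary_rate: float
    combined_rate: float
    urinary_fraction: float

    def __post_init__(self) -> None:
        if not math.isclose(self.combined_rate, self.dialysate_rate + self.urinary_rate):
            raise DomainError("combined_rate must equal dialysate_rate + urinary_rate")
        if not (0.0 <= self.urinary_fraction <= 100.0):
            raise DomainError("urinary_fraction must lie in [0, 100]")


def dialysate_excretion_rate(
    dialysate_volume: float, dialysate_conc: float, sessions_per_week: int
) -> float:
    """Daily dialysate excretion rate (μmol/24-h): V * D * n / 7."""
    if sessions_per_week <= 0:
        raise DomainError("sessions_per_week must be positive")
    if sessions_per_week not in (2, 3):
        warnings.warn(
            f"unusual dialysis schedule ({sessions_per_week}/week); formula applied as-is",
            stacklevel=2,
        )
    if dialysate_volume <= 0:
        raise DomainError("dialysate_volume must be positive")
    if dialysate_conc < 0:
        raise DomainError("dialysate_conc must be non-negative")
    return dialysate_volume * dialysate_conc * sessions_per_week / 7.0


def urinary_excretion_rate(day1, day2) -> float:
    """Daily urinary excretion rate (μmol/24-h): mean of the two collections.

    One missing collection falls back to the single available value with a
    warning; both missing is an error (callers must not reach this for
    patients without residual diuresis — those get a rate of 0 upstream).
    """
    missing1 = day1 is None or (isinstance(day1, float) and math.isnan(day1))
    missing2 = day2 is None or (isinstance(day2, float) and math.isnan(day2))
    if missing1 and missing2:
        raise DomainError("both urine collections missing for a patient with residual diuresis")
    if missing1 or missing2:
        warnings.warn("one urine collection missing; using the single value", stacklevel=2)
        return float(day2 if missing1 else day1)
    if day1 == 0 and day2 == 0:
        warnings.warn(
            "residual diuresis flagged but both collections measured zero excretion",
            stacklevel=2,
        )
    return (float(day1) + float(day2)) / 2.0


def urinary_contribution(urinary_rate: float, dialysate_rate: float) -> float:
    """Urinary share (%) of the combined daily excretion rate."""
    total = urinary_rate + dialysate_rate
    if total <= 0:
        raise DomainError("urinary_contribution undefined when both rates are zero")
    return 100.0 * urinary_rate / total


def excretion_table(sessions: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Per-patient per-solute daily excretion rates.

    Patients without residual diuresis get ``urinary_rate = 0`` by
    definition so combined rates (CER, CUER) are always defined.
    """
    meta = patients.set_index("patient_id")[["sessions_per_week", "residual_diuresis"]]
    rows = []
    for rec in sessions.itertuples(index=False):
        m = meta.loc[rec.patient_id]
        d_rate = dialysate_excretion_rate(
            float(rec.dialysate_volume_L),
            float(rec.dialysate_conc_umol_L),
            int(m.sessions_per_week),
        )
        if bool(m.residual_diuresis):
            u_rate = urinary_excretion_rate(rec.urine_day1_umol_24h, rec.urine_day2_umol_24h)
        else:
            u_rate = 0.0
        rows.append(
            {
                "patient_id": rec.patient_id,
                "solute": rec.solute,
                "dialysate_rate_umol_24h": d_rate,
                "urinary_rate_umol_24h": u_rate,
                "combined_rate_umol_24h": d_rate + u_rate,
                "urinary_fraction_pct": urinary_contribution(u_rate, d_rate)
                if d_rate + u_rate > 0
                else float("nan"),
                "residual_diuresis": bool(m.residual_diuresis),
            }
        )
    return pd.DataFrame(rows)


def contribution_summary(rates: pd.DataFrame) -> pd.DataFrame:
    """Cohort urinary-contribution summary among patients with residual diuresis.

    Reports the mean of per-patient urinary fractions per solute (the
    combined rate is the denominator of each per-patient fraction).
    """
    sub = rates[rates["residual_diuresis"]]
    out = (
        sub.groupby("solute")["urinary_fraction_pct"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "urinary_contribution_pct", "count": "n_patients"})
        .reset_index()
    )
    return out
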