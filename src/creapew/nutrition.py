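"""Protein-energy-wasting (PEW) phenotype variables and classification.

Five PEW-characteristic variables are derived per patient:

* skeletal muscle index (SMI, kg/m^2) from the combined creatinine
  excretion rate via the creatinine equivalence 1 g creatinine/24-h
  (8.84 mmol) = 22.73 kg skeletal muscle, divided by height squared;
* dietary protein intake (g/kg/24-h) from the combined urea excretion
  rate by the Maroni formula, indexed to postdialysis body weight;
* dialysis adequacy Kt/V by the second-generation Daugirdas estimate;
* BMI and plasma albumin (carried through from the clinical table);
* CIS fatigue-severity subscale score (8 items of the 20-item Checklist
  Individual Strength, 7-point Likert, range 8–56).

Classification thresholds (defaults, strict comparisons as stated):
SMI < 10.76 (males) / < 6.76 (females) kg/m^2; protein intake
< 0.8 g/kg/24-h; albumin < 38 g/L; BMI < 23 kg/m^2; fatigue score >= 35.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .anthropometry import bmi as _bmi
from .errors import DomainError
from .excretion_rates import dialysate_excretion_rate, urinary_excretion_rate

__all__ = [
    "Patient",
    "PewPhenotype",
    "PewThresholds",
    "DEFAULT_THRESHOLDS",
    "CIS_FATIGUE_ITEMS",
    "CIS_REVERSE_ITEMS",
    "CREATININE_MMOL_PER_G",
    "MUSCLE_KG_PER_G_CREATININE",
    "ktv_daugirdas",
    "cer_combined",
    "cuer",
    "smi",
    "protein_intake_maroni",
    "cis_fatigue",
    "classify_pew",
    "phenotype_table",
]

log = logging.getLogger(__name__)

#: 1 g of creatinine is 8.84 mmol; it marks 22.73 kg of skeletal muscle.
CREATININE_MMOL_PER_G = 8.84
MUSCLE_KG_PER_G_CREATININE = 22.73

#: Default CIS fatigue-severity subscale: 8 of the 20 items, with the
#: positively phrased items reverse-scored (response r contributes 8 - r).
CIS_FATIGUE_ITEMS = (1, 4, 6, 9, 12, 14, 16, 20)
CIS_REVERSE_ITEMS = (6, 12, 20)

ACCESS_TYPES = ("lower_arm_fistula", "upper_arm_fistula", "cvc", "graft")


@dataclass(frozen=True)
class PewThresholds:
    """Cutoffs for the five PEW-characteristic flags."""

    smi_male: float = 10.76  # kg/m^2, strict <
    smi_female: float = 6.76  # kg/m^2, strict <
    protein_intake: float = 0.8  # g/kg/24-h, strict <
    albumin: float = 38.0  # g/L, strict <
    bmi: float = 23.0  # kg/m^2, strict <
    cis_fatigue: float = 35.0  # score points, inclusive >=


DEFAULT_THRESHOLDS = PewThresholds()


@dataclass(frozen=True)
class Patient:
    """Demographic/anthropometric/clinical covariates for one subject."""

    id: str
    sex: str  # "male" | "female"
    age: float  # years
    height: float  # m
    weight_pre: float  # kg
    weight_post: float  # kg
    vintage: float  # months on dialysis
    sessions_per_week: int
    session_hours: float
    uf_volume: float  # L
    albumin: float  # g/L
    hs_crp: float  # mg/L
    residual_diuresis: bool
    urine_volume: float  # L/24-h
    access: str
    esa: bool = False
    vitd: bool = False
    steroid: bool = False
    androgen: bool = False
    cis_items: Sequence[int] = field(default_factory=tuple)
    urine_protein: Optional[float] = None  # g/24-h

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DomainError(f"unknown sex {self.sex!r}")
        if self.sessions_per_week not in (2, 3):
            raise DomainError("sessions_per_week must be 2 or 3")
        if not (3.0 <= self.session_hours <= 5.0):
            raise DomainError("session_hours must lie in [3, 5]")
        if self.access not in ACCESS_TYPES:
            raise DomainError(f"unknown vascular access {self.access!r}")
        if self.cis_items:
            if len(self.cis_items) != 20 or any(
                not (1 <= int(v) <= 7) for v in self.cis_items
            ):
                raise DomainError("cis_items must be 20 integers in 1..7")


@dataclass(frozen=True)
class PewPhenotype:
    """Continuous PEW variables plus the five binary flags."""

    smi: float  # kg/m^2
    protein_intake: float  # g/kg/24-h
    ktv: float
    cis_fatigue: float
    low_muscle: bool
    low_protein: bool
    hypoalbuminemia: bool
    low_bmi: bool
    severe_fatigue: bool


def ktv_daugirdas(R: float, t: float, UF: float, W: float) -> float:
    """Second-generation Daugirdas single-pool Kt/V.

    Kt/V = -ln(R - 0.008*t) + (4 - 3.5*R) * UF/W, with R the post/pre
    urea ratio, t session duration (h), UF ultrafiltration volume (L) and
    W postdialysis weight (kg).
    """
    if W <= 0:
        raise DomainError("postdialysis weight must be positive")
    inner = R - 0.008 * t
    if inner <= 0:
        raise DomainError(
            f"R - 0.008*t = {inner:.4g} <= 0; Kt/V undefined (check urea ratio and duration)"
        )
    return -math.log(inner) + (4.0 - 3.5 * R) * UF / W


def cer_combined(
    dialysate_volume: float,
    dialysate_creatinine: float,
    sessions_per_week: int,
    urinary_cre: float = 0.0,
) -> float:
    """Combined creatinine excretion rate (mmol/24-h).

    Dialysate creatinine concentration is in mmol/L here (presentation
    scale for creatinine); ``urinary_cre`` is the averaged 24-h urinary
    creatinine excretion in mmol/24-h (0 without residual diuresis).
    """
    rate = dialysate_excretion_rate(dialysate_volume, dialysate_creatinine, sessions_per_week)
    out = rate + urinary_cre
    if out == 0:
        import warnings

        warnings.warn("combined creatinine excretion rate is zero", stacklevel=2)
    return out


def cuer(
    dialysate_volume: float,
    dialysate_urea: float,
    sessions_per_week: int,
    urinary_urea: float = 0.0,
) -> float:
    """Combined urea excretion rate (mmol/24-h), dialysate urea in mmol/L."""
    return (
        dialysate_excretion_rate(dialysate_volume, dialysate_urea, sessions_per_week)
        + urinary_urea
    )


def smi(cer: float, height: float) -> float:
    """Skeletal muscle index (kg/m^2) from the combined CER (mmol/24-h)."""
    if height <= 0:
        raise DomainError("height must be positive")
    if cer < 0:
        raise DomainError("creatinine excretion rate must be non-negative")
    return cer * (MUSCLE_KG_PER_G_CREATININE / CREATININE_MMOL_PER_G) / height**2


def protein_intake_maroni(cuer_mmol: float, bw: float, upe: float = 0.0) -> float:
    """Maroni estimate of dietary protein intake (g/kg/24-h).

    (6.25 * (0.028 * CUER + 0.031 * BW) + UPE) / BW, with CUER in
    mmol/24-h, BW postdialysis body weight (kg) and UPE urinary protein
    excretion (g/24-h; defaults to 0 when unmeasured).
    """
    if bw <= 0:
        raise DomainError("body weight must be positive")
    return (6.25 * (0.028 * cuer_mmol + 0.031 * bw) + upe) / bw


def cis_fatigue(
    items: Sequence[int],
    item_map: Sequence[int] = CIS_FATIGUE_ITEMS,
    reverse_items: Sequence[int] = CIS_REVERSE_ITEMS,
) -> float:
    """CIS fatigue-severity subscale score (range 8–56 under the default map).

    ``items`` are the 20 recorded Likert responses (1..7), 1-indexed by
    ``item_map``.  Reverse-scored items contribute ``8 - response``.
    """
    if len(items) != 20:
        raise DomainError(f"expected 20 CIS items, got {len(items)}")
    vals = [int(v) for v in items]
    if any(not (1 <= v <= 7) for v in vals):
        raise DomainError("CIS responses must lie in 1..7")
    score = 0
    for idx in item_map:
        r = vals[idx - 1]
        score += (8 - r) if idx in reverse_items else r
    return float(score)


def classify_pew(
    sex: str,
    smi_value: float,
    protein_intake: float,
    albumin: float,
    bmi_value: float,
    cis_score: float,
    *,
    ktv: float = float("nan"),
    thresholds: PewThresholds = DEFAULT_THRESHOLDS,
) -> PewPhenotype:
    """Apply the five PEW-characteristic cutoffs (pure function, idempotent)."""
    if sex == "male":
        smi_cut = thresholds.smi_male
    elif sex == "female":
        smi_cut = thresholds.smi_female
    else:
        raise DomainError(f"unknown sex {sex!r}; SMI threshold is sex-specific")
    return PewPhenotype(
        smi=smi_value,
        protein_intake=protein_intake,
        ktv=ktv,
        cis_fatigue=cis_score,
        low_muscle=smi_value < smi_cut,
        low_protein=protein_intake < thresholds.protein_intake,
        hypoalbuminemia=albumin < thresholds.albumin,
        low_bmi=bmi_value < thresholds.bmi,
        severe_fatigue=cis_score >= thresholds.cis_fatigue,
    )


def phenotype_table(
    patients: pd.DataFrame,
    sessions: pd.DataFrame,
    thresholds: PewThresholds = DEFAULT_THRESHOLDS,
    cis_item_map: Sequence[int] = CIS_FATIGUE_ITEMS,
    cis_reverse_items: Sequence[int] = CIS_REVERSE_ITEMS,
) -> pd.DataFrame:
    """Per-patient phenotype table with continuous values and flags.

    Requires urea and creatinine rows in ``sessions`` for Kt/V, CER and
    CUER.  Session concentrations are μmol/L and are converted to mmol
    internally for CER/CUER.  UPE defaults to 0 when urine protein is
    unmeasured (logged per patient).
    """
    cis_cols = [f"cis_item_{i:02d}" for i in range(1, 21)]
    sess = sessions.set_index(["patient_id", "solute"])
    rows = []
    for p in patients.itertuples(index=False):
        pid = p.patient_id
        cre = sess.loc[(pid, "creatinine")]
        ure = sess.loc[(pid, "urea")]
        if bool(p.residual_diuresis):
            ucre = urinary_excretion_rate(cre.urine_day1_umol_24h, cre.urine_day2_umol_24h) / 1e3
            uure = urinary_excretion_rate(ure.urine_day1_umol_24h, ure.urine_day2_umol_24h) / 1e3
        else:
            ucre = uure = 0.0
        cer_v = cer_combined(
            float(cre.dialysate_volume_L),
            float(cre.dialysate_conc_umol_L) / 1e3,
            int(p.sessions_per_week),
            ucre,
        )
        cuer_v = cuer(
            float(ure.dialysate_volume_L),
            float(ure.dialysate_conc_umol_L) / 1e3,
            int(p.sessions_per_week),
            uure,
        )
        upe = getattr(p, "urine_protein_g_24h", None)
        if upe is None or (isinstance(upe, float) and math.isnan(upe)) or not bool(
            p.residual_diuresis
        ):
            if bool(p.residual_diuresis):
                log.info("patient %s: urine protein unmeasured, UPE set to 0", pid)
            upe = 0.0
        smi_v = smi(cer_v, float(p.height_m))
        protein_v = protein_intake_maroni(cuer_v, float(p.weight_post_kg), float(upe))
        R = float(ure.plasma_post_umol_L) / float(ure.plasma_pre_umol_L)
        ktv_v = ktv_daugirdas(
            R, float(p.session_hours_h), float(p.uf_volume_L), float(p.weight_post_kg)
        )
        bmi_v = float(_bmi(float(p.weight_post_kg), float(p.height_m)))
        items = [int(getattr(p, c)) for c in cis_cols]
        cis_v = cis_fatigue(items, cis_item_map, cis_reverse_items)
        ph = classify_pew(
            p.sex, smi_v, protein_v, float(p.albumin_g_L), bmi_v, cis_v,
            ktv=ktv_v, thresholds=thresholds,
        )
        rows.append(
            {
                "patient_id": pid,
                "sex": p.sex,
                "cer_mmol_24h": cer_v,
                "cuer_mmol_24h": cuer_v,
                "smi_kg_m2": ph.smi,
                "protein_intake_g_kg_24h": ph.protein_intake,
                "ktv": ph.ktv,
                "bmi_kg_m2": bmi_v,
                "albumin_g_L": float(p.albumin_g_L),
                "cis_fatigue_score": ph.cis_fatigue,
                "low_muscle": ph.low_muscle,
                "low_protein": ph.low_protein,
                "hypoalbuminemia": ph.hypoalbuminemia,
                "low_bmi": ph.low_bmi,
                "severe_fatigue": ph.severe_fatigue,
            }
        )
    return pd.DataFrame(rows)
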