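"""Intradialytic plasma changes and compartmental partition of dialysate losses.

For each solute (arginine, guanidinoacetate, creatine, creatinine, urea)
and each dialysis session the quantities of interest are:

* absolute decrease   = plasma_pre - plasma_post                (μmol/L)
* proportional decrease = 100 * absolute decrease / plasma_pre  (%)
* total loss          = dialysate volume * dialysate conc       (μmol)
* extracellular loss  = plasma_pre*ECV_pre - plasma_post*ECV_post
* intracellular loss  = total loss - extracellular loss

The intracellular loss estimates how much solute was shifted out of cells
during the session; a large value relative to the total indicates that the
dialyzer drained the intracellular pool, not just the plasma.  The sum
decomposition holds exactly by construction (intracellular is defined as
the remainder), and negative components are retained and flagged rather
than truncated.

Internal canonical unit is μmol for every solute; creatinine is converted
to mmol only at the presentation layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anthropometry import EcvEstimate, ecv_estimate
from .errors import DomainError

__all__ = [
    "SOLUTES",
    "SoluteSession",
    "MassBalanceResult",
    "absolute_decrease",
    "proportional_decrease",
    "total_loss",
    "extracellular_loss",
    "intracellular_loss",
    "compartment_shares",
    "mass_balance",
    "mass_balance_table",
    "cohort_summary",
    "CohortSummary",
]

log = logging.getLogger(__name__)

SOLUTES = ("arginine", "guanidinoacetate", "creatine", "creatinine", "urea")


@dataclass(frozen=True)
class SoluteSession:
    """One solute's measurements for one dialysis session.

    Plasma concentrations are in μmol/L; the postdialysis sample is drawn
    5 min before the end of the session (metadata only, no correction is
    applied).  Urine fields are per-24-h amounts (μmol/24-h) and are
    present only for patients with residual diuresis.
    """

    solute: str
    plasma_pre: float
    plasma_post: float
    dialysate_volume: float
    dialysate_conc: float
    urine_day1: Optional[float] = None
    urine_day2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.solute not in SOLUTES:
            raise DomainError(f"unknown solute {self.solute!r}; expected one of {SOLUTES}")
        for name in ("plasma_pre", "plasma_post", "dialysate_conc"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.dialysate_volume <= 0:
            raise DomainError("dialysate_volume must be positive")
        for name in ("urine_day1", "urine_day2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be non-negative when present")


@dataclass(frozen=True)
class MassBalanceResult:
    """Partitioned session losses for one patient/solute (all amounts in μmol)."""

    total_loss: float
    ec_loss: float
    ic_loss: float
    ecv: EcvEstimate
    abs_decrease: float
    prop_decrease: float
    flag_negative_ec: bool = False
    flag_negative_ic: bool = False


def absolute_decrease(plasma_pre: float, plasma_post: float) -> float:
    """Intradialytic absolute plasma decrease (μmol/L); negative means a rise."""
    return plasma_pre - plasma_post


def proportional_decrease(plasma_pre: float, plasma_post: float) -> float:
    """Intradialytic proportional plasma decrease (%) relative to predialysis."""
    if plasma_pre <= 0:
        raise DomainError("proportional decrease undefined for plasma_pre <= 0")
    return 100.0 * (plasma_pre - plasma_post) / plasma_pre


def total_loss(dialysate_volume: float, dialysate_conc: float) -> float:
    """Total solute removal (μmol): spent-dialysate volume (L) times concentration (μmol/L)."""
    if dialysate_volume <= 0:
        raise DomainError("dialysate_volume must be positive")
    if dialysate_conc < 0:
        raise DomainError("dialysate_conc must be non-negative")
    return dialysate_volume * dialysate_conc


def extracellular_loss(
    plasma_pre, plasma_post=None, ecv: EcvEstimate = None
) -> float:
    """Extracellular mass decrease (μmol): pre-mass minus post-mass in the ECV pool.

    Accepts either ``(session, ecv)`` with a :class:`SoluteSession`, or the
    explicit ``(plasma_pre, plasma_post, ecv)`` concentrations.  A negative
    return value (plasma rise outpacing volume loss) is reported as-is with
    a warning; the caller carries the flag.
    """
    if isinstance(plasma_pre, SoluteSession):
        session = plasma_pre
        if plasma_post is not None and ecv is None:
            ecv = plasma_post
        pre, post = session.plasma_pre, session.plasma_post
    else:
        pre, post = plasma_pre, plasma_post
    if ecv is None or ecv.ecv_pre <= 0 or ecv.ecv_post <= 0:
        raise DomainError("a valid EcvEstimate with positive volumes is required")
    value = pre * ecv.ecv_pre - post * ecv.ecv_post
    if value < 0:
        warnings.warn(
            "negative estimated extracellular loss (postdialysis extracellular mass "
            "exceeds predialysis); value retained, not clipped",
            stacklevel=2,
        )
    return value


def intracellular_loss(total: float, ec: float) -> float:
    """Intracellular loss (μmol) as the remainder: total minus extracellular."""
    return total - ec


def compartment_shares(
    total: float, ec: float, rounded: bool = False
) -> tuple[float, float]:
    """(extracellular %, intracellular %) of the total loss.

    Shares sum to 100 before rounding.  With ``rounded=True`` each share is
    independently rounded half-up to integer percent (presentation only).
    """
    if total <= 0:
        raise DomainError("compartment shares undefined for total <= 0")
    ec_share = 100.0 * ec / total
    ic_share = 100.0 * (total - ec) / total
    if rounded:
        ec_share = float(Decimal(str(float(ec_share))).quantize(0, rounding=ROUND_HALF_UP))
        ic_share = float(Decimal(str(float(ic_share))).quantize(0, rounding=ROUND_HALF_UP))
    return ec_share, ic_share


def mass_balance(session: SoluteSession, ecv: EcvEstimate) -> MassBalanceResult:
    """Full per-session mass balance for one solute."""
    tot = total_loss(session.dialysate_volume, session.dialysate_conc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ec = extracellular_loss(session.plasma_pre, session.plasma_post, ecv)
    ic = intracellular_loss(tot, ec)
    return MassBalanceResult(
        total_loss=tot,
        ec_loss=ec,
        ic_loss=ic,
        ecv=ecv,
        abs_decrease=absolute_decrease(session.plasma_pre, session.plasma_post),
        prop_decrease=proportional_decrease(session.plasma_pre, session.plasma_post)
        if session.plasma_pre > 0
        else float("nan"),
        flag_negative_ec=ec < 0,
        flag_negative_ic=ic < 0,
    )


def mass_balance_table(
    sessions: pd.DataFrame,
    patients: pd.DataFrame,
    ecv_formula: str = "abraham",
) -> pd.DataFrame:
    """Per-patient per-solute mass-balance table.

    ``sessions`` columns: patient_id, solute, plasma_pre_umol_L,
    plasma_post_umol_L, dialysate_volume_L, dialysate_conc_umol_L.
    ``patients`` columns must include patient_id, weight_pre_kg,
    weight_post_kg, height_m.
    """
    body = patients.set_index("patient_id")[["weight_pre_kg", "weight_post_kg", "height_m"]]
    rows = []
    for rec in sessions.itertuples(index=False):
        b = body.loc[rec.patient_id]
        ecv = ecv_estimate(
            float(b.weight_pre_kg), float(b.weight_post_kg), float(b.height_m), ecv_formula
        )
        session = SoluteSession(
            solute=rec.solute,
            plasma_pre=float(rec.plasma_pre_umol_L),
            plasma_post=float(rec.plasma_post_umol_L),
            dialysate_volume=float(rec.dialysate_volume_L),
            dialysate_conc=float(rec.dialysate_conc_umol_L),
        )
        res = mass_balance(session, ecv)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "solute": rec.solute,
                "plasma_pre_umol_L": session.plasma_pre,
                "plasma_post_umol_L": session.plasma_post,
                "abs_decrease_umol_L": res.abs_decrease,
                "prop_decrease_pct": res.prop_decrease,
                "total_loss_umol": res.total_loss,
                "ec_loss_umol": res.ec_loss,
                "ic_loss_umol": res.ic_loss,
                "ecv_pre_L": ecv.ecv_pre,
                "ecv_post_L": ecv.ecv_post,
                "ecv_formula": ecv.formula_id,
                "flag_negative_ec": res.flag_negative_ec,
                "flag_negative_ic": res.flag_negative_ic,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort summaries


class CohortSummary(NamedTuple):
    summary: pd.DataFrame  # per (solute, quantity, stratum) descriptive stats
    tests: pd.DataFrame  # per (solute, contrast, stratum) p-values


_SUMMARY_QUANTITIES = (
    "plasma_pre_umol_L",
    "plasma_post_umol_L",
    "abs_decrease_umol_L",
    "prop_decrease_pct",
    "total_loss_umol",
    "ec_loss_umol",
    "ic_loss_umol",
)


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3 or np.ptp(x) == 0:
        return True
    return stats.shapiro(x).pvalue > alpha


def _describe(x: np.ndarray, normal: bool) -> dict:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return {"n": 0}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    mean, sd = float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    display = (
        f"{mean:.3g} ± {sd:.3g}" if normal else f"{med:.3g} [{q1:.3g}–{q3:.3g}]"
    )
    return {
        "n": int(x.size),
        "mean": mean,
        "sd": sd,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "normal": normal,
        "display": display,
    }


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[~np.isnan(d)]
    if d.size < 2:
        return float("nan")
    if np.allclose(d, 0):
        return 1.0
    if _is_normal(d):
        return float(stats.ttest_rel(a, b, nan_policy="omit").pvalue)
    try:
        return float(stats.wilcoxon(d).pvalue)
    except ValueError:
        return 1.0


def _unpaired_p(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if min(a.size, b.size) < 2:
        return float("nan")
    if _is_normal(a) and _is_normal(b):
        return float(stats.ttest_ind(a, b).pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def cohort_summary(
    mb: pd.DataFrame,
    patients: pd.DataFrame,
    normality_override: Optional[dict] = None,
) -> CohortSummary:
    """Sex-stratified descriptive summary with paired and unpaired tests.

    Dispersion presentation follows a Shapiro–Wilk screen at α=0.05
    (mean ± SD when compatible with normality, else median [IQR]);
    ``normality_override`` maps solute → ``"mean"``/``"median"`` to force a
    presentation per solute.  Tests: paired pre-vs-post and EC-vs-IC per
    solute and stratum; unpaired male-vs-female per solute and quantity.
    """
    normality_override = normality_override or {}
    sexes = patients.set_index("patient_id")["sex"]
    df = mb.merge(sexes.rename("sex"), left_on="patient_id", right_index=True)
    strata = {"all": df}
    for sex in ("male", "female"):
        sub = df[df["sex"] == sex]
        if sub.empty:
            log.warning("empty stratum %r omitted from cohort summary", sex)
        else:
            strata[sex] = sub
    sum_rows, test_rows = [], []
    for solute in df["solute"].unique():
        for name, stratum in strata.items():
            sub = stratum[stratum["solute"] == solute]
            if sub.empty:
                continue
            for qty in _SUMMARY_QUANTITIES:
                if qty not in sub:
                    continue
                x = sub[qty].to_numpy(float)
                ov = normality_override.get(solute)
                normal = {"mean": True, "median": False}.get(ov, _is_normal(x))
                sum_rows.append(
                    {"solute": solute, "quantity": qty, "stratum": name, **_describe(x, normal)}
                )
            test_rows.append(
                {
                    "solute": solute,
                    "contrast": "pre_vs_post",
                    "stratum": name,
                    "p_value": _paired_p(
                        sub["plasma_pre_umol_L"].to_numpy(), sub["plasma_post_umol_L"].to_numpy()
                    ),
                }
            )
            test_rows.append(
                {
                    "solute": solute,
                    "contrast": "ec_vs_ic",
                    "stratum": name,
                    "p_value": _paired_p(
                        sub["ec_loss_umol"].to_numpy(), sub["ic_loss_umol"].to_numpy()
                    ),
                }
            )
        if "male" in strata and "female" in strata:
            males = df[(df["solute"] == solute) & (df["sex"] == "male")]
            females = df[(df["solute"] == solute) & (df["sex"] == "female")]
            for qty in _SUMMARY_QUANTITIES:
                if qty not in df:
                    continue
                test_rows.append(
                    {
                        "solute": solute,
                        "contrast": f"male_vs_female:{qty}",
                        "stratum": "between",
                        "p_value": _unpaired_p(
                            males[qty].to_numpy(), females[qty].to_numpy()
                        ),
                    }
                )
    return CohortSummary(pd.DataFrame(sum_rows), pd.DataFrame(test_rows))
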