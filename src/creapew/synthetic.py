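"""Synthetic dialysis-cohort generator with known ground truth.

Every estimator in this package is validated against cohorts produced
here.  Per patient and solute, a two-pool (intracellular/extracellular)
kinetic model is stepped through one dialysis session:

    d(Ce*Ve)/dt = -Kd*Ce - Quf*Ce + Kc*(Ci/λ - Ce)
    d(Ci*Vi)/dt =  G - Kc*(Ci/λ - Ce)
    dVe/dt      = -Quf

with Kd the dialyzer (diffusive) clearance, Quf the ultrafiltration rate
(volume leaves the extracellular pool only; convective solute removal
with sieving coefficient 1), Kc the intercompartmental clearance, λ the
intracellular/extracellular partition coefficient (λ = 1 recovers the
classic two-pool urea model; λ ≫ 1 represents solutes like creatine whose
intracellular concentration is actively maintained far above plasma, so
the pools are at flux equilibrium when Ci = λ·Ce and a falling plasma
level drives an intra- to extracellular shift), and G a constant
generation rate placed in the intracellular pool (creatine and creatinine
are produced in muscle).  The dialysate accumulates the
diffusive plus convective fluxes, so mass is conserved exactly step by
step: initial + generated = final + dialysate.

The generator emits the exact table schemas the analysis modules consume
(measured concentrations carry a small assay noise; urine collections are
two noisy replicates of a patient-level true rate) plus a ground-truth
ledger with the true compartmental mass changes and the true logistic
outcome coefficients.  Defaults emulate the cohort structure the analysis
assumes: 59 patients, ~63% male, thrice-weekly 4-h sessions, ~135 L
spent dialysate, ~54% with residual diuresis, and plasma concentrations
on realistic hemodialysis scales per solute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .anthropometry import ecv_abraham
from .association import PREDICTOR_TRANSFORMS, transform_predictor
from .errors import DomainError
from .mass_balance import SOLUTES

__all__ = [
    "KineticParams",
    "SessionTruth",
    "SessionResult",
    "CohortTables",
    "CohortTruth",
    "simulate_session",
    "generate_cohort",
    "generate_outcomes",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_INTERCEPTS",
    "SOLUTE_KINETICS",
]


@dataclass(frozen=True)
class KineticParams:
    """Two-pool kinetic parameters for one patient/solute session."""

    solute: str
    generation_rate: float  # μmol/min, into the intracellular pool
    dialyzer_clearance: float  # mL/min
    intercompartmental_clearance: float  # mL/min
    v_intracellular: float  # L
    v_extracellular: float  # L (predialysis)
    uf_rate: float  # mL/min, removed from the extracellular pool
    initial_ic_conc: float  # μmol/L
    initial_ec_conc: float  # μmol/L
    sieving: float = 1.0  # convective sieving coefficient
    partition: float = 1.0  # IC/EC equilibrium concentration ratio λ

    def __post_init__(self) -> None:
        if self.v_intracellular <= 0 or self.v_extracellular <= 0:
            raise DomainError("compartment volumes must be positive")
        for name in ("generation_rate", "dialyzer_clearance",
                     "intercompartmental_clearance", "uf_rate"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.initial_ic_conc < 0 or self.initial_ec_conc < 0:
            raise DomainError("initial concentrations must be non-negative")
        if self.partition <= 0:
            raise DomainError("partition coefficient must be positive")


@dataclass(frozen=True)
class SessionTruth:
    """Exact mass ledger of one simulated session (all masses in μmol)."""

    ec_mass_change: float  # final minus initial extracellular mass
    ic_mass_change: float  # final minus initial intracellular mass
    ic_to_ec_transfer: float  # ∫ Kc (Ci - Ce) dt
    dialysate_mass: float
    generated_mass: float
    ve_pre: float  # L
    ve_post: float  # L


class SessionResult(NamedTuple):
    plasma_pre: float
    plasma_post: float
    dialysate_mass: float
    truth: SessionTruth


def simulate_session(
    params: KineticParams,
    duration: float = 240.0,
    dt: float = 0.5,
    generation_boost: float = 0.0,
    _depth: int = 0,
) -> SessionResult:
    """Explicit time-stepping of the two-pool model over one session.

    ``duration`` and ``dt`` are in minutes.  If a step would drive a
    concentration negative the step size is halved internally (up to 6
    times) before failing loudly; nothing is clipped silently.
    ``generation_boost`` adds a constant to the generation rate during the
    session (optional intradialytic proteolysis surge; default off).
    """
    if dt <= 0 or duration <= 0:
        raise DomainError("duration and dt must be positive")
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9 * duration:
        n_steps = math.ceil(duration / dt)
        dt = duration / n_steps
    kd = params.dialyzer_clearance / 1000.0  # L/min
    kc = params.intercompartmental_clearance / 1000.0
    quf = params.uf_rate / 1000.0
    g = params.generation_rate + generation_boost
    ve = params.v_extracellular
    vi = params.v_intracellular
    me = params.initial_ec_conc * ve
    mi = params.initial_ic_conc * vi
    dialysate = 0.0
    transfer = 0.0
    if ve - quf * duration <= 0.05 * params.v_extracellular:
        raise DomainError("ultrafiltration would (nearly) exhaust the extracellular volume")
    for _ in range(n_steps):
        ce = me / ve
        ci = mi / vi
        j_dial = (kd + quf * params.sieving) * ce  # μmol/min to dialysate
        j_ic = kc * (ci / params.partition - ce)  # μmol/min, IC -> EC
        me_new = me + dt * (-j_dial + j_ic)
        mi_new = mi + dt * (g - j_ic)
        if me_new < 0 or mi_new < 0:
            if _depth >= 6:
                raise DomainError(
                    "negative compartment mass during simulation even at reduced dt"
                )
            return simulate_session(
                params, duration, dt / 2.0, generation_boost, _depth + 1
            )
        dialysate += dt * j_dial
        transfer += dt * j_ic
        me, mi = me_new, mi_new
        ve -= dt * quf
    truth = SessionTruth(
        ec_mass_change=me - params.initial_ec_conc * params.v_extracellular,
        ic_mass_change=mi - params.initial_ic_conc * vi,
        ic_to_ec_transfer=transfer,
        dialysate_mass=dialysate,
        generated_mass=g * duration,
        ve_pre=params.v_extracellular,
        ve_post=ve,
    )
    return SessionResult(params.initial_ec_conc, me / ve, dialysate, truth)


# ---------------------------------------------------------------------------
# Cohort generation

#: Per-solute kinetic sampling defaults.  ``ec0`` is (mean, sd) of the
#: predialysis plasma concentration in μmol/L ("lognormal": (median, sigma));
#: ``ic_ratio`` scales the initial intracellular concentration relative to
#: plasma; ``kd``/``kc`` are dialyzer and intercompartmental clearances in
#: mL/min; ``urinary_frac`` scales renal handling relative to residual GFR
#: (reabsorption < 1 < secretion); ``gen`` is the generation rate (μmol/min).
SOLUTE_KINETICS: dict[str, dict] = {
    "arginine": dict(ec0=("normal", 77.0, 22.0, 25.0), ic_ratio=(5.0, 0.25),
                     kd=(120.0, 20.0), kc=(400.0, 80.0), urinary_frac=0.035, gen=3.0),
    "guanidinoacetate": dict(ec0=("normal", 1.8, 0.6, 0.4), ic_ratio=(4.0, 0.25),
                             kd=(110.0, 20.0), kc=(240.0, 50.0), urinary_frac=0.85, gen=0.15),
    "creatine": dict(ec0=("lognormal_sex", 19.0, 33.0, 0.5, 5.0), ic_ratio=(150.0, 0.30),
                     kd=(125.0, 20.0), kc=(800.0, 150.0), urinary_frac=0.10, gen=1.0),
    "creatinine": dict(ec0=("normal", 689.0, 207.0, 200.0), ic_ratio=(1.15, 0.10),
                       kd=(175.0, 25.0), kc=(600.0, 100.0), urinary_frac=1.0, gen=7.0),
    "urea": dict(ec0=("normal", 24000.0, 5000.0, 8000.0), ic_ratio=(1.0, 0.05),
                 kd=(210.0, 25.0), kc=(800.0, 120.0), urinary_frac=0.55, gen=300.0),
}

#: True outcome-model coefficients (log-OR per transformed predictor unit:
#: per halving for creatine, per 1-SD decrease for the rest).  The scale
#: mirrors realistic cross-sectional effect sizes in a small dialysis
#: cohort; guanidinoacetate is a true null throughout.
DEFAULT_COEFFICIENTS: dict[str, dict[str, float]] = {
    "low_muscle": {"creatinine": math.log(2.5), "creatine": math.log(2.0)},
    "low_protein": {"arginine": math.log(1.9), "creatine": math.log(2.1)},
    "hypoalbuminemia": {"arginine": math.log(2.5), "creatine": math.log(3.1)},
    "low_bmi": {},
    "severe_fatigue": {"creatine": math.log(3.2)},
}
DEFAULT_INTERCEPTS: dict[str, float] = {
    "low_muscle": -1.0,
    "low_protein": -1.0,
    "hypoalbuminemia": -1.0,
    "low_bmi": -1.0,
    "severe_fatigue": -0.7,
}

ACCESS_P = {"lower_arm_fistula": 13 / 59, "upper_arm_fistula": 19 / 59,
            "cvc": 19 / 59, "graft": 8 / 59}

PATIENT_COLUMNS = (
    ["patient_id", "sex", "age_years", "height_m", "weight_pre_kg", "weight_post_kg",
     "vintage_months", "sessions_per_week", "session_hours_h", "uf_volume_L",
     "albumin_g_L", "hs_crp_mg_L", "residual_diuresis", "urine_volume_L_24h",
     "access", "esa", "vitd", "steroid", "androgen", "urine_protein_g_24h"]
    + [f"cis_item_{i:02d}" for i in range(1, 21)]
)
SESSION_COLUMNS = [
    "patient_id", "solute", "plasma_pre_umol_L", "plasma_post_umol_L",
    "dialysate_volume_L", "dialysate_conc_umol_L",
    "urine_day1_umol_24h", "urine_day2_umol_24h",
]
OUTCOME_COLUMNS = ["patient_id", "low_muscle", "low_protein", "hypoalbuminemia",
                   "low_bmi", "severe_fatigue"]


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort: mass ledgers and outcome coefficients."""

    seed: int
    coefficients: dict
    intercepts: dict
    sessions: pd.DataFrame  # per patient/solute true kinetic ledger
    predictor_scaling: dict  # per solute: transform mode + sample mean/sd used

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "coefficients": self.coefficients,
            "intercepts": self.intercepts,
            "predictor_scaling": self.predictor_scaling,
            "sessions": self.sessions.to_dict(orient="list"),
        }


class CohortTables(NamedTuple):
    patients: pd.DataFrame
    sessions: pd.DataFrame
    outcomes: pd.DataFrame
    truth: CohortTruth


def _sample_ec0(spec, sex: str, rng: np.random.Generator) -> float:
    kind = spec[0]
    if kind == "normal":
        _, mean, sd, lo = spec
        return float(max(rng.normal(mean, sd), lo))
    if kind == "lognormal_sex":
        _, med_m, med_f, sigma, lo = spec
        med = med_m if sex == "male" else med_f
        return float(max(rng.lognormal(math.log(med), sigma), lo))
    raise DomainError(f"unknown ec0 sampler {kind!r}")


def _cis_items_for_score(score: int, rng: np.random.Generator,
                         item_map=(1, 4, 6, 9, 12, 14, 16, 20),
                         reverse=(6, 12, 20)) -> list[int]:
    """20 Likert responses whose fatigue-severity subscale score equals ``score``."""
    contrib = np.ones(len(item_map), dtype=int)
    add = int(score) - len(item_map)
    while add > 0:
        open_idx = np.where(contrib < 7)[0]
        i = rng.choice(open_idx)
        contrib[i] += 1
        add -= 1
    items = rng.integers(1, 8, size=20)
    for pos, idx in enumerate(item_map):
        c = int(contrib[pos])
        items[idx - 1] = (8 - c) if idx in reverse else c
    return [int(v) for v in items]


def generate_outcomes(
    patients: pd.DataFrame,
    coefficients: Optional[dict] = None,
    seed: int | np.random.Generator = 0,
    intercepts: Optional[dict] = None,
) -> tuple[pd.DataFrame, dict]:
    """Bernoulli outcome draws from a logistic model on plasma predictors.

    ``patients`` must carry ``plasma_<solute>_umol_L`` columns for every
    solute named in ``coefficients``.  The linear predictor uses the same
    transforms as the association layer (per halving for creatine, per
    1-SD decrease otherwise).  Returns the binary outcome frame and the
    scaling record (sample mean/SD per predictor) for the truth ledger.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coefficients = DEFAULT_COEFFICIENTS if coefficients is None else coefficients
    intercepts = DEFAULT_INTERCEPTS if intercepts is None else intercepts
    n = len(patients)
    transformed: dict[str, np.ndarray] = {}
    scaling: dict[str, dict] = {}
    solutes = sorted({s for cc in coefficients.values() for s in cc})
    for solute in solutes:
        raw = patients[f"plasma_{solute}_umol_L"].to_numpy(float)
        mode = PREDICTOR_TRANSFORMS.get(solute, "per_sd_decrease")
        x, _ = transform_predictor(raw, mode)
        # center so the intercept sets baseline prevalence; a shift leaves
        # the refitted slope (and hence the OR) unchanged
        transformed[solute] = x - np.nanmean(x)
        scaling[solute] = {
            "mode": mode,
            "mean": float(np.nanmean(raw)),
            "sd": float(np.nanstd(raw, ddof=1)),
        }
    out = {"patient_id": patients["patient_id"].to_numpy()}
    for outcome, coefs in coefficients.items():
        lp = np.full(n, float(intercepts.get(outcome, -1.0)))
        for solute, beta in coefs.items():
            lp = lp + beta * transformed[solute]
        p = 1.0 / (1.0 + np.exp(-lp))
        out[outcome] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(out), scaling


def generate_cohort(
    n: int = 59,
    seed: int = 42,
    *,
    assay_cv: float = 0.04,
    urine_cv: float = 0.15,
    dt: float = 0.5,
    ecv_noise_cv: float = 0.08,
    coefficients: Optional[dict] = None,
    intercepts: Optional[dict] = None,
    generation_boost: float = 0.0,
    solute_kinetics: Optional[dict] = None,
) -> CohortTables:
    """Generate a full synthetic cohort (patients, sessions, outcomes, truth).

    Reproducible: the same seed yields byte-identical tables.  ``n = 0``
    returns empty, schema-valid tables.
    """
    if n < 0:
        raise DomainError("cohort size must be non-negative")
    for name, v in [("assay_cv", assay_cv), ("urine_cv", urine_cv),
                    ("ecv_noise_cv", ecv_noise_cv)]:
        if v < 0:
            raise DomainError(f"{name} must be non-negative")
    kinetics = SOLUTE_KINETICS if solute_kinetics is None else solute_kinetics
    rng = np.random.default_rng(seed)
    if n == 0:
        empty_truth = CohortTruth(seed, coefficients or DEFAULT_COEFFICIENTS,
                                  intercepts or DEFAULT_INTERCEPTS,
                                  pd.DataFrame(), {})
        return CohortTables(
            pd.DataFrame(columns=PATIENT_COLUMNS),
            pd.DataFrame(columns=SESSION_COLUMNS),
            pd.DataFrame(columns=OUTCOME_COLUMNS),
            empty_truth,
        )

    patients_rows, session_rows, truth_rows = [], [], []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        sex = "female" if rng.random() < 0.37 else "male"
        age = float(np.clip(rng.normal(65, 15), 20, 95))
        height = float(rng.normal(1.80, 0.07) if sex == "male" else rng.normal(1.67, 0.05))
        weight_post = float(max(rng.normal(82, 16) if sex == "male" else rng.normal(73, 13), 42))
        uf = float(np.clip(rng.normal(1.9, 0.9), 0.2, 4.5))
        weight_pre = weight_post + uf
        vintage = float(rng.lognormal(math.log(15), 1.0))
        spw = 2 if rng.random() < 0.05 else 3
        hours = float(rng.choice([3.5, 4.0, 4.5], p=[0.10, 0.81, 0.09]))
        duration = hours * 60.0
        dial_vol = float(max(rng.normal(135, 27), 60))
        diuresis = bool(rng.random() < 0.54)
        urine_vol = float(np.clip(rng.normal(0.9, 0.6), 0.25, 3.0)) if diuresis else float(
            rng.uniform(0.0, 0.2)
        )
        access = str(rng.choice(list(ACCESS_P), p=list(ACCESS_P.values())))
        esa, vitd = bool(rng.random() < 0.83), bool(rng.random() < 0.64)
        steroid, androgen = bool(rng.random() < 0.20), bool(rng.random() < 0.03)
        albumin = float(rng.normal(40, 3.5))
        hs_crp = float(rng.lognormal(math.log(4.9), 1.0))
        upe = float(rng.lognormal(math.log(0.15), 0.8)) if diuresis else float("nan")
        ve_true = float(ecv_abraham(weight_pre, height) * rng.lognormal(0.0, ecv_noise_cv))
        vi_true = float(max(0.58 * weight_post - ve_true, 10.0))
        residual_cl = urine_vol * 5.0 if diuresis else 0.0  # mL/min of effective clearance

        patients_rows.append(
            dict(
                patient_id=pid, sex=sex, age_years=age, height_m=height,
                weight_pre_kg=weight_pre, weight_post_kg=weight_post,
                vintage_months=vintage, sessions_per_week=spw, session_hours_h=hours,
                uf_volume_L=uf, albumin_g_L=albumin, hs_crp_mg_L=hs_crp,
                residual_diuresis=diuresis, urine_volume_L_24h=urine_vol,
                access=access, esa=esa, vitd=vitd, steroid=steroid, androgen=androgen,
                urine_protein_g_24h=upe,
            )
        )

        for solute in SOLUTES:
            spec = kinetics[solute]
            ec0 = _sample_ec0(spec["ec0"], sex, rng)
            ratio = float(rng.lognormal(math.log(spec["ic_ratio"][0]), spec["ic_ratio"][1]))
            kd = float(max(rng.normal(*spec["kd"]), 20.0))
            kc = float(max(rng.normal(*spec["kc"]), 0.05))
            params = KineticParams(
                solute=solute,
                generation_rate=spec["gen"],
                dialyzer_clearance=kd,
                intercompartmental_clearance=kc,
                v_intracellular=vi_true,
                v_extracellular=ve_true,
                uf_rate=uf * 1000.0 / duration,
                initial_ic_conc=ec0 * ratio,
                initial_ec_conc=ec0,
                partition=ratio,
            )
            res = simulate_session(params, duration, dt, generation_boost)
            noise = rng.lognormal(0.0, assay_cv, size=3)
            meas_pre = res.plasma_pre * noise[0]
            meas_post = res.plasma_post * noise[1]
            meas_dial_conc = (res.dialysate_mass / dial_vol) * noise[2]
            if diuresis:
                true_urate = residual_cl * spec["urinary_frac"] * res.plasma_pre * 1.44
                u1 = float(true_urate * rng.lognormal(0.0, urine_cv))
                u2 = float(true_urate * rng.lognormal(0.0, urine_cv))
            else:
                u1 = u2 = float("nan")
            session_rows.append(
                dict(
                    patient_id=pid, solute=solute,
                    plasma_pre_umol_L=meas_pre, plasma_post_umol_L=meas_post,
                    dialysate_volume_L=dial_vol, dialysate_conc_umol_L=meas_dial_conc,
                    urine_day1_umol_24h=u1, urine_day2_umol_24h=u2,
                )
            )
            truth_rows.append(
                dict(
                    patient_id=pid, solute=solute,
                    plasma_pre_true_umol_L=res.plasma_pre,
                    plasma_post_true_umol_L=res.plasma_post,
                    dialysate_mass_true_umol=res.dialysate_mass,
                    ec_mass_change_umol=res.truth.ec_mass_change,
                    ic_mass_change_umol=res.truth.ic_mass_change,
                    ic_to_ec_transfer_umol=res.truth.ic_to_ec_transfer,
                    generated_mass_umol=res.truth.generated_mass,
                    ve_pre_true_L=res.truth.ve_pre,
                    ve_post_true_L=res.truth.ve_post,
                )
            )

    patients = pd.DataFrame(patients_rows)
    sessions = pd.DataFrame(session_rows)
    truth_sessions = pd.DataFrame(truth_rows)

    # outcome draws on the measured predialysis plasma predictors
    plasma_wide = (
        sessions.pivot(index="patient_id", columns="solute", values="plasma_pre_umol_L")
        .rename(columns={s: f"plasma_{s}_umol_L" for s in SOLUTES})
        .reset_index()
    )
    plasma_wide = plasma_wide.set_index("patient_id").loc[patients["patient_id"]].reset_index()
    outcomes, scaling = generate_outcomes(plasma_wide, coefficients, rng, intercepts)

    # CIS items consistent with the generated severe-fatigue outcome
    cis_block = []
    for severe in outcomes["severe_fatigue"].to_numpy():
        score = int(rng.integers(35, 53)) if severe else int(rng.integers(10, 35))
        cis_block.append(_cis_items_for_score(score, rng))
    cis_df = pd.DataFrame(cis_block, columns=[f"cis_item_{i:02d}" for i in range(1, 21)])
    patients = pd.concat([patients, cis_df], axis=1)[PATIENT_COLUMNS]

    truth = CohortTruth(
        seed=seed,
        coefficients=coefficients or DEFAULT_COEFFICIENTS,
        intercepts=intercepts or DEFAULT_INTERCEPTS,
        sessions=truth_sessions,
        predictor_scaling=scaling,
    )
    return CohortTables(patients, sessions, outcomes, truth)
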