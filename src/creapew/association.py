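"""Logistic association layer: predictor scaling, model fits, grid and sensitivity runs.

Predictors are predialysis plasma concentrations (or dialysate losses in
the loss-predictor variant) scaled so that odds ratios read as risk per
*decrease*:

* ``per_sd_decrease`` — negated z-score: a patient 1 SD below the sample
  mean maps to +1, so OR > 1 means higher odds at lower levels;
* ``per_halving`` — negated log2: one transformed unit is one halving of
  the raw concentration (used for the right-skewed creatine).

Fits are maximum-likelihood logistic regressions (statsmodels), with Wald
95% confidence intervals on the log-odds scale and two-sided Wald p
values.  Separation and rank deficiency raise explicit errors instead of
returning silently absurd estimates; an optional Firth (Jeffreys-prior)
penalized fit is available for separated small samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, RankDeficiencyError, SeparationError

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "transform_predictor",
    "fit_logistic",
    "fit_association",
    "run_model_grid",
    "pearson_predialysis_vs_loss",
    "PREDICTOR_TRANSFORMS",
    "MULTIVARIABLE_COVARIATES",
]

log = logging.getLogger(__name__)

#: Default transform per solute predictor (creatine is right-skewed).
PREDICTOR_TRANSFORMS = {
    "arginine": "per_sd_decrease",
    "guanidinoacetate": "per_sd_decrease",
    "creatine": "per_halving",
    "creatinine": "per_sd_decrease",
}

OUTCOMES = ("low_muscle", "low_protein", "hypoalbuminemia", "low_bmi", "severe_fatigue")
SEX_COVARIATES = ("is_female",)
MULTIVARIABLE_COVARIATES = ("is_female", "age_years", "bsa_m2", "vintage_months", "hs_crp_mg_L")

_UNIT_NOTES = {"per_sd_decrease": "per 1-SD decrease", "per_halving": "per halving"}


@dataclass(frozen=True)
class ModelSpec:
    """One logistic model: outcome ~ transformed predictor + covariates."""

    outcome: str
    predictor: str
    transform: str
    covariates: tuple[str, ...] = ()
    exclude_above_percentile: Optional[float] = None

    def __post_init__(self) -> None:
        if self.transform not in _UNIT_NOTES:
            raise DomainError(f"unknown transform {self.transform!r}")
        if len(set(self.covariates)) != len(self.covariates):
            raise DomainError("covariates must be unique")


@dataclass(frozen=True)
class AssociationResult:
    """Odds ratio with 95% Wald CI and two-sided Wald p."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    unit_note: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise DomainError("CI must bracket the odds ratio")
        if self.odds_ratio <= 0:
            raise DomainError("odds ratio must be positive")


def transform_predictor(values, mode: str) -> tuple[np.ndarray, str]:
    """Scale a raw predictor; returns (transformed values, unit note).

    The SD for ``per_sd_decrease`` is the sample SD (ddof=1) of the values
    passed in, i.e. of the analysis sample after any exclusions.
    """
    x = np.asarray(values, dtype=float)
    if mode == "per_sd_decrease":
        sd = np.nanstd(x, ddof=1)
        if sd == 0 or np.isnan(sd):
            raise DomainError("predictor has zero standard deviation")
        return -(x - np.nanmean(x)) / sd, _UNIT_NOTES[mode]
    if mode == "per_halving":
        bad = np.where(~(x > 0))[0]
        if bad.size:
            raise DomainError(
                f"log2 transform requires positive values; offending rows: {bad.tolist()}"
            )
        return -np.log2(x), _UNIT_NOTES[mode]
    raise DomainError(f"unknown transform {mode!r}")


def _check_design(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            "design matrix is rank deficient (duplicated or collinear covariates)"
        )


def _firth_fit(y: np.ndarray, X: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth penalized logistic fit (Jeffreys prior) by adjusted Newton scoring."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        XtW = X.T * W
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"Firth information matrix singular: {e}") from e
        h = np.einsum("ij,jk,ik->i", X * W[:, None], info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise SeparationError("Firth fit did not converge")
    bse = np.sqrt(np.diag(info_inv))
    return beta, bse


def fit_logistic(
    y, X: pd.DataFrame, *, firth: bool = False
) -> tuple[pd.Series, pd.Series, int]:
    """ML (or Firth) logit fit of y on X plus an intercept.

    Returns (coefficients, standard errors, n).  Raises
    :class:`SeparationError` on detected separation and
    :class:`RankDeficiencyError` on a rank-deficient design.
    """
    y = np.asarray(y, dtype=float)
    Xc = sm.add_constant(pd.DataFrame(X), has_constant="add")
    if y.size <= Xc.shape[1]:
        raise DomainError(f"n={y.size} too small for {Xc.shape[1]} parameters")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise DomainError(
            f"outcome must contain both classes 0 and 1 (got values {classes.tolist()})"
        )
    _check_design(Xc.to_numpy(float))
    if firth:
        params, bse = _firth_fit(y, Xc.to_numpy(float))
        return (
            pd.Series(params, index=Xc.columns),
            pd.Series(bse, index=Xc.columns),
            int(y.size),
        )
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as e:  # statsmodels PerfectSeparationError and kin
        raise SeparationError(f"logistic fit failed: {e}") from e
    if (not res.mle_retvals.get("converged", False)) or np.max(
        np.abs(res.params)
    ) > 20 or np.max(res.bse) > 100:
        raise SeparationError(
            "logistic fit shows (quasi-)complete separation: non-convergence or "
            "exploding coefficient/standard error"
        )
    return res.params, res.bse, int(y.size)


def fit_association(
    spec: ModelSpec,
    data: pd.DataFrame,
    outcomes: Optional[pd.DataFrame] = None,
    *,
    firth: bool = False,
) -> AssociationResult:
    """Fit one model from a per-patient analysis frame.

    ``data`` must carry the raw predictor column named by ``spec.predictor``
    and all covariate columns; ``outcomes`` (defaults to ``data``) carries
    the binary outcome column.  Rows with missing values are dropped; the
    per-SD scaling is computed on the analysis sample after exclusions.
    """
    out = outcomes if outcomes is not None else data
    df = data[[spec.predictor, *spec.covariates]].copy()
    df["_y"] = np.asarray(out[spec.outcome], dtype=float)
    df = df.dropna()
    if spec.exclude_above_percentile is not None:
        cut = np.percentile(df[spec.predictor], spec.exclude_above_percentile)
        df = df[df[spec.predictor] <= cut]
    x, note = transform_predictor(df[spec.predictor].to_numpy(), spec.transform)
    X = pd.DataFrame({"predictor": x}, index=df.index)
    for c in spec.covariates:
        X[c] = df[c].to_numpy(float)
    params, bse, n = fit_logistic(df["_y"].to_numpy(), X, firth=firth)
    b, se = float(params["predictor"]), float(bse["predictor"])
    z = stats.norm.ppf(0.975)
    return AssociationResult(
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - z * se)),
        ci_high=float(np.exp(b + z * se)),
        p_value=float(2 * stats.norm.sf(abs(b / se))),
        n_used=n,
        unit_note=note,
    )


def _grid_variants(data: pd.DataFrame) -> dict[str, dict]:
    access_dummies = tuple(c for c in data.columns if c.startswith("access_"))
    meds = tuple(c for c in ("esa", "vitd", "steroid") if c in data.columns)
    multi = MULTIVARIABLE_COVARIATES
    return {
        "sex_adjusted": {"covariates": SEX_COVARIATES},
        "multivariable": {"covariates": multi},
        "excl_p95": {"covariates": multi, "exclude": 95.0},
        "plus_access": {"covariates": multi + access_dummies},
        "plus_ktv": {"covariates": multi + ("ktv",)},
        "plus_meds": {"covariates": multi + meds},
        "plus_diuresis": {"covariates": multi + ("residual_diuresis",)},
        "loss_sex_adjusted": {"covariates": SEX_COVARIATES, "loss_predictor": True},
        "loss_multivariable": {"covariates": multi, "loss_predictor": True},
    }


def run_model_grid(
    data: pd.DataFrame,
    outcomes: Optional[pd.DataFrame] = None,
    *,
    include_sensitivity: bool = True,
    firth: bool = False,
) -> pd.DataFrame:
    """Fit the predictors x outcomes x adjustments grid plus sensitivity variants.

    ``data`` is a per-patient frame with plasma predictor columns
    ``plasma_<solute>_umol_L``, loss columns ``loss_<solute>_umol`` and the
    covariates; ``outcomes`` the five binary outcome columns.  Per-cell
    failures are recorded in the ``error`` column and the grid continues.
    """
    variants = _grid_variants(data)
    if not include_sensitivity:
        variants = {k: variants[k] for k in ("sex_adjusted", "multivariable")}
    rows = []
    for variant, vcfg in variants.items():
        for solute, transform in PREDICTOR_TRANSFORMS.items():
            col = (
                f"loss_{solute}_umol" if vcfg.get("loss_predictor") else f"plasma_{solute}_umol_L"
            )
            if col not in data.columns:
                continue
            for outcome in OUTCOMES:
                spec = ModelSpec(
                    outcome=outcome,
                    predictor=col,
                    transform=transform,
                    covariates=tuple(vcfg["covariates"]),
                    exclude_above_percentile=vcfg.get("exclude"),
                )
                row = {
                    "variant": variant,
                    "predictor": solute,
                    "predictor_column": col,
                    "outcome": outcome,
                    "transform": transform,
                }
                try:
                    res = fit_association(spec, data, outcomes, firth=firth)
                    row.update(
                        odds_ratio=res.odds_ratio,
                        ci_low=res.ci_low,
                        ci_high=res.ci_high,
                        p_value=res.p_value,
                        n_used=res.n_used,
                        unit_note=res.unit_note,
                        error="",
                    )
                except Exception as e:
                    log.warning("grid cell %s failed: %s", row, e)
                    row.update(
                        odds_ratio=np.nan,
                        ci_low=np.nan,
                        ci_high=np.nan,
                        p_value=np.nan,
                        n_used=0,
                        unit_note=_UNIT_NOTES[transform],
                        error=f"{type(e).__name__}: {e}",
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def pearson_predialysis_vs_loss(plasma_pre, loss) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of predialysis plasma vs dialysate loss."""
    x = np.asarray(plasma_pre, dtype=float)
    y = np.asarray(loss, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DomainError("Pearson correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("Pearson correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
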