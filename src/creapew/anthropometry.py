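"""Body-size derived quantities.

Body surface area (Du Bois), body mass index, and two anthropometric
estimates of the extracellular fluid volume (ECV).  The ECV estimates are
what allows a single-session dialysate solute balance to be partitioned
into an extracellular and an intracellular component: the extracellular
mass change is plasma concentration times ECV evaluated before and after
the session, and whatever the dialysate received beyond that change must
have been shifted out of cells.

Two ECV formulas are supported:

* ``abraham`` — ECV (L) = sqrt(weight [kg]) * height [m].  This is the
  primary formula; with cohort-typical inputs (80 kg, 1.75 m) it gives
  ~15.7 L, i.e. ~20% of body weight, as expected physiologically.
* ``bird`` — ECV (L) = weight^0.6469 * (height [cm])^0.7236 * 0.02154,
  used as a sensitivity check.  Note the constant requires height in cm;
  this module stores height in metres and converts internally.

All functions accept scalars or numpy arrays and raise
:class:`~creapew.errors.DomainError` on non-positive inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

from .errors import DomainError

__all__ = [
    "BodyMeasure",
    "EcvEstimate",
    "bsa_du_bois",
    "bmi",
    "ecv_abraham",
    "ecv_bird",
    "ecv_estimate",
    "ECV_FORMULAS",
]

Number = Union[float, np.ndarray]
EcvFormula = Literal["abraham", "bird"]

#: Weight/height windows accepted without a plausibility warning.
PLAUSIBLE_WEIGHT_KG = (20.0, 250.0)
PLAUSIBLE_HEIGHT_M = (1.2, 2.2)


def _validated(weight: Number, height: Number) -> tuple[np.ndarray, np.ndarray]:
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise DomainError(
            f"weight and height must be positive (got weight={weight!r}, height={height!r})"
        )
    if np.any((w < PLAUSIBLE_WEIGHT_KG[0]) | (w > PLAUSIBLE_WEIGHT_KG[1])):
        warnings.warn(
            f"weight outside plausible adult range {PLAUSIBLE_WEIGHT_KG} kg", stacklevel=3
        )
    if np.any((h < PLAUSIBLE_HEIGHT_M[0]) | (h > PLAUSIBLE_HEIGHT_M[1])):
        warnings.warn(
            f"height outside plausible adult range {PLAUSIBLE_HEIGHT_M} m", stacklevel=3
        )
    return w, h


@dataclass(frozen=True)
class BodyMeasure:
    """A validated (weight, height) pair.

    Parameters
    ----------
    weight : float
        Body weight in kg; must be positive.
    height : float
        Standing height in m; must be positive.
    """

    weight: float
    height: float

    def __post_init__(self) -> None:
        _validated(self.weight, self.height)

    @property
    def bsa(self) -> float:
        return float(bsa_du_bois(self.weight, self.height))

    @property
    def bmi(self) -> float:
        return float(bmi(self.weight, self.height))


@dataclass(frozen=True)
class EcvEstimate:
    """Pre- and postdialysis extracellular-volume estimates (L) plus provenance."""

    ecv_pre: float
    ecv_post: float
    formula_id: EcvFormula

    def __post_init__(self) -> None:
        if self.ecv_pre <= 0 or self.ecv_post <= 0:
            raise DomainError("ECV estimates must be positive volumes")
        if self.formula_id not in ("abraham", "bird"):
            raise DomainError(f"unknown ECV formula {self.formula_id!r}")


def bsa_du_bois(weight: Number, height: Number) -> Number:
    """Body surface area (m^2) by Du Bois & Du Bois.

    BSA = 0.007184 * weight^0.425 * (height_cm)^0.725 with weight in kg and
    height in m (converted to cm internally).
    """
    w, h = _validated(weight, height)
    out = 0.007184 * w**0.425 * (h * 100.0) ** 0.725
    return float(out) if out.ndim == 0 else out


def bmi(weight_post: Number, height: Number) -> Number:
    """Body mass index (kg/m^2): postdialysis weight over height squared."""
    w, h = _validated(weight_post, height)
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def ecv_abraham(weight: Number, height: Number) -> Number:
    """Extracellular volume (L): sqrt(weight [kg]) * height [m]."""
    w, h = _validated(weight, height)
    out = np.sqrt(w) * h
    return float(out) if out.ndim == 0 else out


def ecv_bird(weight: Number, height: Number) -> Number:
    """Extracellular volume (L): weight^0.6469 * (height_cm)^0.7236 * 0.02154."""
    w, h = _validated(weight, height)
    out = w**0.6469 * (h * 100.0) ** 0.7236 * 0.02154
    return float(out) if out.ndim == 0 else out


ECV_FORMULAS = {"abraham": ecv_abraham, "bird": ecv_bird}


def ecv_estimate(
    weight_pre: float,
    weight_post: float,
    height: float,
    formula: EcvFormula = "abraham",
) -> EcvEstimate:
    """Pre/post ECV pair from pre/post weights and height.

    Both formulas are monotone in weight, so ``ecv_post <= ecv_pre``
    whenever ultrafiltration removed weight during the session.
    """
    try:
        fn = ECV_FORMULAS[formula]
    except KeyError:
        raise DomainError(f"unknown ECV formula {formula!r}") from None
    return EcvEstimate(
        ecv_pre=float(fn(weight_pre, height)),
        ecv_post=float(fn(weight_post, height)),
        formula_id=formula,
    )
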