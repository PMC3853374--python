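"""Clinical scalar formulas: Mosteller BSA, Cockcroft-Gault GFR, plasma AUC.

These are the quantities that connect the imaging metrics to patient
outcomes: cisplatin is dosed by body surface area, nephrotoxicity is tracked
through estimated creatinine clearance, and systemic drug exposure is the
trapezoidal area under the plasma concentration-time curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatientVitals",
    "PlasmaSeries",
    "mosteller_bsa",
    "cockcroft_gault_gfr",
    "trapezoid_auc",
]


@dataclass(frozen=True)
class PatientVitals:
    """Vitals at catheter placement: age (years), sex, height (cm),
    weight (kg), serum creatinine (mg/dL)."""

    age: float
    sex: str
    height: float
    weight: float
    serum_creatinine: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        for name in ("age", "height", "weight", "serum_creatinine"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.age < 18:
            warnings.warn("age below 18: adult formulas may not apply", stacklevel=2)


@dataclass(frozen=True)
class PlasmaSeries:
    """Sampled plasma concentrations: times in minutes (strictly increasing),
    concentrations in mg/L (non-negative)."""

    times: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size != c.size or t.size < 2:
            raise ValueError("times and concentrations must have equal length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")


def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area in m^2: sqrt(height_cm x weight_kg / 3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return float(np.sqrt(height_cm * weight_kg / 3600.0))


def cockcroft_gault_gfr(vitals: PatientVitals) -> float:
    """Estimated creatinine clearance in cc/min.

    (140 - age) x weight / (72 x serum creatinine), x 0.85 for females.
    Uses actual body weight.
    """
    if vitals.age >= 140:
        raise ValueError("age >= 140 gives a non-positive clearance")
    gfr = (140.0 - vitals.age) * vitals.weight / (72.0 * vitals.serum_creatinine)
    if vitals.sex == "female":
        gfr *= 0.85
    return float(gfr)


def trapezoid_auc(series: PlasmaSeries, assume_zero_at_t0: bool = False) -> float:
    """Trapezoidal-rule plasma AUC in mg.min/L over the sampled span.

    No extrapolation beyond the first and last samples is performed unless
    ``assume_zero_at_t0`` is set, which prepends a zero concentration at
    time 0 (an explicit modeling choice, off by default).
    """
    t = np.asarray(series.times, dtype=float)
    c = np.asarray(series.concentrations, dtype=float)
    if assume_zero_at_t0 and t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    return float(np.trapezoid(c, t))
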