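"""Widmark-style ethanol dose calculation from anthropometrics.

The dose targets a maximum blood alcohol concentration ``c`` (mg/ml,
default 1.5, chosen so that measured peak BAC lands near 0.6 mg/ml once
the absorption deficit is accounted for).  Total body water (TBW, liters)
is estimated from sex-specific regressions on height ``h`` (cm), weight
``w`` (kg) and, for men, age ``a`` (years):

    TBW_women = -2.097 + 0.1069 h + 0.2466 w
    TBW_men   =  2.447 - 0.09516 a + 0.1069 h + 0.2466 w

The alcohol mass A (grams) follows from inverting c = 0.8 A / (1.055 TBW),
and the beverage volume V (ml) from V = A / ((vol/100) * 0.8), with
``vol`` the beverage strength in percent by volume (default 40).  An equal
volume of orange juice is mixed in.  The constants keep the source
convention of mixing mg/ml and g/L units; no absorption-deficit
correction is applied (peak BAC is a measurement, not a model output).
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from .errors import ValidationError

SEXES = ("male", "female")


@dataclass(frozen=True)
class DoseInputs:
    """Anthropometrics and targets for one participant."""

    sex: str
    age: float
    height: float
    weight: float
    target_bac: float = 1.5
    beverage_strength: float = 40.0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for name in ("age", "height", "weight"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be positive, got {v!r}")
        if not self.target_bac > 0:
            raise ValidationError(f"target_bac must be positive, got {self.target_bac!r}")
        if not 0 < self.beverage_strength <= 100:
            raise ValidationError(
                f"beverage_strength must lie in (0, 100], got {self.beverage_strength!r}"
            )


@dataclass(frozen=True)
class DoseResult:
    tbw: float          # total body water, liters
    alcohol_grams: float
    beverage_ml: float
    juice_ml: float     # equal volume of juice mixed in


def total_body_water(inputs: DoseInputs) -> float:
    """Total body water in liters; the male regression uses age, the
    female one does not."""
    if inputs.sex == "female":
        tbw = -2.097 + 0.1069 * inputs.height + 0.2466 * inputs.weight
    else:
        tbw = (
            2.447
            - 0.09516 * inputs.age
            + 0.1069 * inputs.height
            + 0.2466 * inputs.weight
        )
    if tbw <= 0:
        raise ValidationError(
            f"degenerate anthropometrics yield non-positive TBW ({tbw:.3f} L)"
        )
    return tbw


def alcohol_grams(target_bac: float, tbw: float) -> float:
    """Grams of ethanol giving maximum BAC ``target_bac`` for the given
    TBW: A = c * 1.055 * TBW / 0.8 (linear in both arguments)."""
    if not (target_bac > 0 and tbw > 0):
        raise ValidationError("target_bac and tbw must be positive")
    return target_bac * 1.055 * tbw / 0.8


def beverage_volume(grams: float, beverage_strength: float) -> float:
    """Beverage volume in ml delivering ``grams`` of ethanol at the given
    percent-by-volume strength: V = A / ((vol/100) * 0.8)."""
    if grams < 0:
        raise ValidationError("alcohol mass must be non-negative")
    if not 0 < beverage_strength <= 100:
        raise ValidationError("beverage_strength must lie in (0, 100]")
    return grams / ((beverage_strength / 100.0) * 0.8)


def compute_dose(inputs: DoseInputs) -> DoseResult:
    """Full dosing chain TBW -> grams -> beverage volume (+ equal juice)."""
    tbw = total_body_water(inputs)
    grams = alcohol_grams(inputs.target_bac, tbw)
    volume = beverage_volume(grams, inputs.beverage_strength)
    return DoseResult(tbw=tbw, alcohol_grams=grams, beverage_ml=volume, juice_ml=volume)
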