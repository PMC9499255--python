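"""Anthropometry and blood-volume scaling.

Total blood volume follows the sex-specific Nadler regression equations
(height in metres, weight in kg); hepatic blood is taken as a fixed 13% of
the total.  A bounded adjustment factor (0.7-1.3) lets calibration move the
volume within +/-30% of the regression value when a subject's baseline data
demand it.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Anthropometry", "BloodVolumes", "blood_volumes", "LIVER_BLOOD_FRACTION"]

LIVER_BLOOD_FRACTION = 0.13

# Nadler (1962) regression coefficients: V = a*h^3 + b*w + c  [litres]
_NADLER = {
    "male": (0.3669, 0.03219, 0.6041),
    "female": (0.3561, 0.03308, 0.1833),
}


@dataclass(frozen=True)
class Anthropometry:
    """Subject descriptors used to scale the model to a person."""

    sex: str = "male"
    weight_kg: float = 80.0
    height_m: float = 1.80
    age_y: float | None = None  # informational only
    diabetic: bool = False

    def __post_init__(self) -> None:
        if self.sex not in _NADLER:
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 30.0 <= self.weight_kg <= 250.0:
            raise ValueError(f"weight {self.weight_kg} kg outside supported range [30, 250]")
        if not 1.2 <= self.height_m <= 2.2:
            raise ValueError(f"height {self.height_m} m outside supported range [1.2, 2.2]")


@dataclass(frozen=True)
class BloodVolumes:
    """Total and hepatic blood volume (litres) with the applied adjustment."""

    total_l: float
    liver_l: float
    adjustment: float


def blood_volumes(anthropometry: Anthropometry, adjustment: float = 1.0) -> BloodVolumes:
    """Sex-specific blood volume from height and weight, liver = 13% of total.

    ``adjustment`` scales the regression value and must stay within the
    +/-30% plausibility band.
    """
    if not 0.7 <= adjustment <= 1.3:
        raise ValueError(
            f"blood-volume adjustment {adjustment} outside the +/-30% band [0.7, 1.3]"
        )
    a, b, c = _NADLER[anthropometry.sex]
    total = (a * anthropometry.height_m**3 + b * anthropometry.weight_kg + c) * adjustment
    return BloodVolumes(total_l=total, liver_l=LIVER_BLOOD_FRACTION * total, adjustment=adjustment)
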