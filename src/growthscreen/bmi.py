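"""BMI-for-age overweight classification ("with BMI calculation" arm).

A child is overweight under the WHO school-age definition when their BMI
lies above the +1 SD BMI-for-age curve for their sex and completed age in
months.  The classifier works on the measurement scale: the +1 SD cutoff
is inverted to a BMI threshold at the child's month row and the child's
BMI is compared to it with a strict ``>`` ("exceeding" the cutoff); a BMI
exactly on the cutoff is healthy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .errors import DomainError
from .lms import GrowthReference, value_at_zscore, zscore
from .utils import round_half_up, validate_sex

#: Reference coverage required for classification, in completed months.
CLASSIFIABLE_AGE_MONTHS = (61, 228)

#: z-score cutoffs of the WHO school-age definitions.
OVERWEIGHT_Z = 1.0
OBESE_Z = 2.0


@dataclass(frozen=True)
class ChildRecord:
    """One child's measurements.

    ``age_months`` is the completed (floored) age in months — the row index
    used for reference-table lookup.  Weight and height are recorded to
    0.1 kg / 0.1 cm.
    """

    child_id: str
    sex: str
    age_months: int
    weight_kg: float
    height_cm: float

    def __post_init__(self) -> None:
        validate_sex(self.sex)
        if not self.weight_kg > 0:
            raise ValueError(f"weight must be > 0, got {self.weight_kg}")
        if not self.height_cm > 0:
            raise ValueError(f"height must be > 0, got {self.height_cm}")


@dataclass(frozen=True)
class WeightStatus:
    """Outcome of one classification: 'healthy' or 'unhealthy', with audit detail.

    ``detail`` records the threshold(s) applied and the value compared, so a
    worked-example narrative can be reconstructed for any child.
    """

    label: str
    method: str
    detail: dict[str, Any] = field(default_factory=dict)

    @property
    def unhealthy(self) -> bool:
        return self.label == "unhealthy"


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index in kg/m^2, from weight in kg and height in cm.

    Returned unrounded; presentation layers round to 1 decimal.
    """
    if weight_kg <= 0:
        raise DomainError(f"weight must be > 0, got {weight_kg}")
    if height_cm <= 0:
        raise DomainError(f"height must be > 0, got {height_cm}")
    return weight_kg / (height_cm / 100.0) ** 2


def bmi_zscore(child: ChildRecord, bmi_ref: GrowthReference) -> float:
    """BMI-for-age z-score at the child's month row."""
    L, M, S = bmi_ref.lms_at(child.sex, child.age_months)
    return zscore(compute_bmi(child.weight_kg, child.height_cm), L, M, S)


def classify_who(
    child: ChildRecord,
    bmi_ref: GrowthReference,
    annotate_obesity: bool = False,
) -> WeightStatus:
    """Classify a child against the +1 SD BMI-for-age cutoff.

    The binary collapses overweight and obese into "unhealthy"; with
    ``annotate_obesity`` the detail additionally flags BMI above the +2 SD
    cutoff.  Raises :class:`OutOfRangeError` when the reference does not
    cover the child's age.
    """
    L, M, S = bmi_ref.lms_at(child.sex, child.age_months)
    threshold = value_at_zscore(OVERWEIGHT_Z, L, M, S)
    bmi = compute_bmi(child.weight_kg, child.height_cm)
    label = "unhealthy" if bmi > threshold else "healthy"
    detail: dict[str, Any] = {
        "bmi": bmi,
        "bmi_1dp": round_half_up(bmi, 1),
        "threshold": threshold,
        "bmi_z": zscore(bmi, L, M, S),
    }
    if annotate_obesity:
        detail["obese"] = bmi > value_at_zscore(OBESE_Z, L, M, S)
    return WeightStatus(label=label, method="who_bmi", detail=detail)
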