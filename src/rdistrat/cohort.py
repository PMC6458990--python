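"""Core data model for cycle-level chemotherapy delivery records.

A cohort is a collection of treatment courses, one per patient. Each course
holds the ordered per-cycle delivery records (administration day, per-agent
dose in mg/m², adaptation flags and cause) together with patient-level
surgery and outcome fields. All days are integers relative to randomization
(day 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class Arm(str, Enum):
    """Randomized treatment arm: 3-weekly control or 2-weekly dose-intense."""

    REG_C = "reg-c"
    REG_DI = "reg-di"


class AdaptationCause(str, Enum):
    """Recorded cause of a per-cycle delay or dose reduction."""

    MYELOTOXICITY = "myelotoxicity"
    OTHER_TOXICITY = "other_toxicity"
    NON_TOXICITY = "non_toxicity"
    UNKNOWN = "unknown"
    NONE = "none"


#: Causes that can be attached to an adapted (delayed or reduced) cycle.
ADAPTATION_CAUSES = (
    AdaptationCause.MYELOTOXICITY,
    AdaptationCause.OTHER_TOXICITY,
    AdaptationCause.NON_TOXICITY,
    AdaptationCause.UNKNOWN,
)

MAX_CYCLES = 6


class SchemaError(ValueError):
    """A cohort file does not match the documented column schema."""


class ValidationError(ValueError):
    """A cohort violates a data-model invariant."""


@dataclass
class CycleRecord:
    """One administered chemotherapy cycle.

    Parameters
    ----------
    cycle_index : int
        1-based cycle number within the protocol (1..6).
    admin_day : int
        Administration day, in days since randomization.
    dox_dose, cddp_dose : float
        Delivered doxorubicin / cisplatin dose in mg/m² (non-negative).
    delayed, reduced : bool
        Whether the cycle was delayed or dose-reduced relative to plan.
    adaptation_cause : AdaptationCause
        Recorded cause; ``NONE`` iff the cycle was neither delayed nor
        reduced.
    """

    cycle_index: int
    admin_day: int
    dox_dose: float
    cddp_dose: float
    delayed: bool = False
    reduced: bool = False
    adaptation_cause: AdaptationCause = AdaptationCause.NONE

    def validate(self) -> None:
        if not 1 <= self.cycle_index <= MAX_CYCLES:
            raise ValidationError(
                f"cycle_index must be in 1..{MAX_CYCLES}, got {self.cycle_index}"
            )
        if self.admin_day < 0:
            raise ValidationError(f"admin_day must be >= 0, got {self.admin_day}")
        for name, dose in (("dox_dose", self.dox_dose), ("cddp_dose", self.cddp_dose)):
            if not math.isfinite(dose) or dose < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {dose}")
        adapted = self.delayed or self.reduced
        if adapted and self.adaptation_cause is AdaptationCause.NONE:
            raise ValidationError(
                f"cycle {self.cycle_index}: adapted cycle must carry a cause"
            )
        if not adapted and self.adaptation_cause is not AdaptationCause.NONE:
            raise ValidationError(
                f"cycle {self.cycle_index}: unadapted cycle must have cause 'none'"
            )


@dataclass
class TreatmentCourse:
    """One patient's ordered cycle records plus surgery and outcome fields.

    ``event_day`` is absent (None) for patients without an observed event;
    ``censor_day`` is the administrative censoring day. ``surgery_day`` is
    absent for patients who never reached surgery.
    """

    patient_id: str
    arm: Arm
    cycles: list[CycleRecord] = field(default_factory=list)
    surgery_day: int | None = None
    end_of_therapy_day: int = 0
    event_day: int | None = None
    event_observed: bool = False
    censor_day: int = 0

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def validate(self) -> None:
        if len(self.cycles) > MAX_CYCLES:
            raise ValidationError(
                f"patient {self.patient_id}: more than {MAX_CYCLES} cycles"
            )
        for cyc in self.cycles:
            cyc.validate()
        for prev, cur in zip(self.cycles, self.cycles[1:]):
            if cur.cycle_index <= prev.cycle_index:
                raise ValidationError(
                    f"patient {self.patient_id}: cycles not sorted by cycle_index"
                )
            if cur.admin_day <= prev.admin_day:
                raise ValidationError(
                    f"patient {self.patient_id}: admin_day not strictly increasing "
                    f"(cycle {prev.cycle_index} day {prev.admin_day} -> "
                    f"cycle {cur.cycle_index} day {cur.admin_day})"
                )
        if self.cycles and self.end_of_therapy_day < self.cycles[-1].admin_day:
            raise ValidationError(
                f"patient {self.patient_id}: end_of_therapy_day precedes last cycle"
            )
        if self.event_observed and self.event_day is None:
            raise ValidationError(
                f"patient {self.patient_id}: event_observed without event_day"
            )
        if self.event_day is not None and self.event_day <= 0:
            raise ValidationError(
                f"patient {self.patient_id}: event_day must be positive"
            )


@dataclass
class Cohort:
    """A list of treatment courses with free-text provenance metadata."""

    courses: list[TreatmentCourse] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.courses)

    def __iter__(self):
        return iter(self.courses)

    def patient_ids(self) -> list[str]:
        return [c.patient_id for c in self.courses]

    def by_id(self) -> dict[str, TreatmentCourse]:
        return {c.patient_id: c for c in self.courses}

    def validate(self) -> None:
        seen: set[str] = set()
        for course in self.courses:
            if course.patient_id in seen:
                raise ValidationError(f"duplicate patient_id {course.patient_id!r}")
            seen.add(course.patient_id)
            course.validate()
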