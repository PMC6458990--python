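"""Standardised dose-intensity metrics in the tau-delta plane.

For a patient with completed cycles 1..J the standardised cumulative dose
through cycle j is

    delta_j = 1/2 * ( sum_{i<=j} DOX_i / 450  +  sum_{i<=j} CDDP_i / 600 ),

the unweighted mean of the two agents' cumulative-dose fractions relative
to the full intended protocol (6 × 75 and 6 × 100 mg/m²). The standardised
time on treatment is

    tau_j = (admin day of cycle j − admin day of cycle 1) / 91,

with the 91-day normalizer equal to the intended Reg-DI treatment span.

The achieved dose intensity (aRDI) of a patient is the point
(tau_J, delta_J) at the last completed cycle; the regulated dose intensity
(rRDI) is the whole trajectory ((tau_1, delta_1), ..., (tau_J, delta_J)),
one point per completed cycle, whose per-segment slope is the treatment
intensity achieved in that cycle. By construction the trajectory is
monotone in both coordinates and its last point equals the aRDI point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import Cohort, TreatmentCourse
from .regimen import TEMPLATES, TIME_NORMALIZER_DAYS, RegimenTemplate


@dataclass(frozen=True)
class RDIPoint:
    """A point in the tau-delta plane (standardised time, cumulative dose)."""

    tau: float
    delta: float


@dataclass
class RDITrajectory:
    """Per-cycle (tau, delta) points of one patient: the regulated RDI."""

    patient_id: str
    points: list[RDIPoint]

    @property
    def final(self) -> RDIPoint:
        return self.points[-1]

    def __len__(self) -> int:
        return len(self.points)


def _check_through_cycle(course: TreatmentCourse, through_cycle: int) -> None:
    if not 1 <= through_cycle <= len(course.cycles):
        raise ValueError(
            f"through_cycle {through_cycle} outside completed cycles "
            f"1..{len(course.cycles)} for patient {course.patient_id}"
        )


def cumulative_dose_fraction(
    course: TreatmentCourse, template: RegimenTemplate, through_cycle: int
) -> float:
    """Standardised cumulative dose delta through a completed cycle."""
    _check_through_cycle(course, through_cycle)
    dox = sum(c.dox_dose for c in course.cycles[:through_cycle])
    cddp = sum(c.cddp_dose for c in course.cycles[:through_cycle])
    return 0.5 * (dox / template.total_dox + cddp / template.total_cddp)


def time_fraction(
    course: TreatmentCourse,
    through_cycle: int,
    time_normalizer_days: int = TIME_NORMALIZER_DAYS,
) -> float:
    """Standardised time on treatment tau through a completed cycle.

    The origin is the first administration, so tau is 0 at cycle 1.
    """
    _check_through_cycle(course, through_cycle)
    span = course.cycles[through_cycle - 1].admin_day - course.cycles[0].admin_day
    return span / time_normalizer_days


def achieved_rdi(course: TreatmentCourse, template: RegimenTemplate) -> RDIPoint:
    """The aRDI point: (tau, delta) at the last completed cycle."""
    if not course.cycles:
        raise ValueError(
            f"patient {course.patient_id} has no completed cycles; "
            "should have been excluded upstream"
        )
    j = len(course.cycles)
    return RDIPoint(
        tau=time_fraction(course, j, template.time_normalizer_days),
        delta=cumulative_dose_fraction(course, template, j),
    )


def regulated_rdi(course: TreatmentCourse, template: RegimenTemplate) -> RDITrajectory:
    """The rRDI trajectory: one (tau, delta) point per completed cycle."""
    if not course.cycles:
        raise ValueError(
            f"patient {course.patient_id} has no completed cycles; "
            "should have been excluded upstream"
        )
    points = [
        RDIPoint(
            tau=time_fraction(course, j, template.time_normalizer_days),
            delta=cumulative_dose_fraction(course, template, j),
        )
        for j in range(1, len(course.cycles) + 1)
    ]
    return RDITrajectory(patient_id=course.patient_id, points=points)


def tau_to_days(tau: float, time_normalizer_days: int = TIME_NORMALIZER_DAYS) -> int:
    """Convert standardised time tau back to whole days.

    Rounds half away from zero, e.g. tau = 1.56 gives 142 days and
    tau = 0.78 gives 71 days.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    return int(math.floor(tau * time_normalizer_days + 0.5))


def compute_trajectories(
    cohort: Cohort, templates: dict | None = None
) -> dict[str, RDITrajectory]:
    """Regulated-RDI trajectories for every patient in a cohort."""
    templates = templates or TEMPLATES
    return {
        course.patient_id: regulated_rdi(course, templates[course.arm])
        for course in cohort
    }


def metrics_frame(cohort: Cohort, trajectories: dict[str, RDITrajectory]):
    """Per-patient metric table: arm, cycles completed, final tau and delta."""
    import pandas as pd

    rows = []
    for course in cohort:
        traj = trajectories[course.patient_id]
        rows.append(
            {
                "patient_id": course.patient_id,
                "arm": course.arm.value,
                "n_cycles_completed": len(traj),
                "tau_final": traj.final.tau,
                "delta_final": traj.final.delta,
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "arm", "n_cycles_completed", "tau_final", "delta_final"])


def trajectory_frame(trajectories: dict[str, RDITrajectory]):
    """Long-format trajectory table: patient_id, cycle_index, tau, delta."""
    import pandas as pd

    rows = [
        {"patient_id": pid, "cycle_index": j + 1, "tau": p.tau, "delta": p.delta}
        for pid, traj in trajectories.items()
        for j, p in enumerate(traj.points)
    ]
    return pd.DataFrame(rows, columns=["patient_id", "cycle_index", "tau", "delta"])
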