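"""Sample-selection rules and the 180-day landmark.

Two filter stages produce the analysis set:

1. Pre-filters: remove patients who never started chemotherapy (zero
   administered cycles) and patients with an abnormal dosage — any single
   administered agent dose strictly exceeding 1.25 × the per-cycle
   prescribed dose (DOX > 93.75 or CDDP > 125 mg/m²).
2. Landmark: remove patients with an event on or before the landmark day
   (180 days since randomization) and patients who had not completed
   therapy by the landmark. Survival is then measured from the landmark,
   avoiding immortal-time (guarantee-time) bias.

Exclusion precedence is fixed (never-started, abnormal dose, event before
landmark, not completed by landmark) so audit reports are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import Cohort, TreatmentCourse
from .regimen import TEMPLATES, RegimenTemplate

DEFAULT_LANDMARK_DAY = 180
DOSE_RATIO_LIMIT = 1.25


@dataclass
class SelectionReport:
    """Audit counts for the selection stages; exclusions list (id, reason)."""

    n_input: int = 0
    n_never_started: int = 0
    n_abnormal_dose: int = 0
    n_event_before_landmark: int = 0
    n_not_completed_by_landmark: int = 0
    n_analysis_set: int = 0
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def reconciles(self) -> bool:
        return (
            self.n_analysis_set
            == self.n_input
            - self.n_never_started
            - self.n_abnormal_dose
            - self.n_event_before_landmark
            - self.n_not_completed_by_landmark
        )

    def merged_with(self, other: "SelectionReport") -> "SelectionReport":
        """Combine a pre-filter report with a downstream landmark report."""
        return SelectionReport(
            n_input=self.n_input,
            n_never_started=self.n_never_started + other.n_never_started,
            n_abnormal_dose=self.n_abnormal_dose + other.n_abnormal_dose,
            n_event_before_landmark=self.n_event_before_landmark
            + other.n_event_before_landmark,
            n_not_completed_by_landmark=self.n_not_completed_by_landmark
            + other.n_not_completed_by_landmark,
            n_analysis_set=other.n_analysis_set,
            excluded=self.excluded + other.excluded,
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_never_started": self.n_never_started,
            "n_abnormal_dose": self.n_abnormal_dose,
            "n_event_before_landmark": self.n_event_before_landmark,
            "n_not_completed_by_landmark": self.n_not_completed_by_landmark,
            "n_analysis_set": self.n_analysis_set,
            "excluded": [{"patient_id": pid, "reason": r} for pid, r in self.excluded],
        }


def _abnormal_dose(course: TreatmentCourse, template: RegimenTemplate) -> bool:
    # Strict inequality: a ratio of exactly 1.25 is retained.
    for cyc in course.cycles:
        if cyc.dox_dose > DOSE_RATIO_LIMIT * template.dox_per_cycle:
            return True
        if cyc.cddp_dose > DOSE_RATIO_LIMIT * template.cddp_per_cycle:
            return True
    return False


def apply_pre_filters(
    cohort: Cohort, templates: dict | None = None
) -> tuple[Cohort, SelectionReport]:
    """Remove never-started and abnormal-dose patients.

    Never-started takes precedence over abnormal dose in the audit counts.
    """
    templates = templates or TEMPLATES
    report = SelectionReport(n_input=len(cohort))
    kept: list[TreatmentCourse] = []
    for course in cohort:
        if not course.cycles:
            report.n_never_started += 1
            report.excluded.append((course.patient_id, "never_started"))
        elif _abnormal_dose(course, templates[course.arm]):
            report.n_abnormal_dose += 1
            report.excluded.append((course.patient_id, "abnormal_dose"))
        else:
            kept.append(course)
    report.n_analysis_set = len(kept)
    return Cohort(courses=kept, provenance=dict(cohort.provenance)), report


def apply_landmark(
    cohort: Cohort, landmark_day: int = DEFAULT_LANDMARK_DAY
) -> tuple[Cohort, SelectionReport]:
    """Remove patients with an event by the landmark or therapy still
    ongoing at the landmark. An event exactly on the landmark day is
    excluded; event-free patients whose therapy ended by the landmark are
    retained.
    """
    if landmark_day <= 0:
        raise ValueError(f"landmark_day must be positive, got {landmark_day}")
    report = SelectionReport(n_input=len(cohort))
    kept: list[TreatmentCourse] = []
    for course in cohort:
        if course.event_day is not None and course.event_day <= landmark_day:
            report.n_event_before_landmark += 1
            report.excluded.append((course.patient_id, "event_before_landmark"))
        elif course.end_of_therapy_day > landmark_day:
            report.n_not_completed_by_landmark += 1
            report.excluded.append((course.patient_id, "not_completed_by_landmark"))
        else:
            kept.append(course)
    report.n_analysis_set = len(kept)
    return Cohort(courses=kept, provenance=dict(cohort.provenance)), report


def apply_selection(
    cohort: Cohort,
    landmark_day: int = DEFAULT_LANDMARK_DAY,
    templates: dict | None = None,
) -> tuple[Cohort, SelectionReport]:
    """Run both stages and return the analysis set with a merged report."""
    filtered, pre_report = apply_pre_filters(cohort, templates)
    analysis, lm_report = apply_landmark(filtered, landmark_day)
    return analysis, pre_report.merged_with(lm_report)
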