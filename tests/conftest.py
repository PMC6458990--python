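import pytest
from hypothesis import strategies as st

from rdistrat import (
    AdaptationCause,
    Arm,
    Cohort,
    CycleRecord,
    TEMPLATES,
    TreatmentCourse,
    intended_schedule,
)

ADAPTED_CAUSES = [
    AdaptationCause.MYELOTOXICITY,
    AdaptationCause.OTHER_TOXICITY,
    AdaptationCause.NON_TOXICITY,
    AdaptationCause.UNKNOWN,
]


def make_intended_course(arm: Arm, patient_id: str = "P1", n_cycles: int = 6,
                         first_admin: int = 0) -> TreatmentCourse:
    """A course that follows its arm's intended schedule at full dose."""
    template = TEMPLATES[arm]
    schedule = intended_schedule(template)
    cycles = [
        CycleRecord(
            cycle_index=j + 1,
            admin_day=first_admin + schedule[j],
            dox_dose=template.dox_per_cycle,
            cddp_dose=template.cddp_per_cycle,
        )
        for j in range(n_cycles)
    ]
    return TreatmentCourse(
        patient_id=patient_id,
        arm=arm,
        cycles=cycles,
        surgery_day=first_admin + template.surgery_day,
        end_of_therapy_day=cycles[-1].admin_day + template.interval_days,
        event_day=None,
        event_observed=False,
        censor_day=2555,
    )


@pytest.fixture
def intended_di_course():
    return make_intended_course(Arm.REG_DI)


@pytest.fixture
def intended_c_course():
    return make_intended_course(Arm.REG_C)


@st.composite
def cycle_lists(draw):
    n = draw(st.integers(min_value=0, max_value=6))
    days = sorted(
        draw(st.lists(st.integers(0, 400), min_size=n, max_size=n, unique=True))
    )
    cycles = []
    for j, day in enumerate(days):
        delayed = draw(st.booleans())
        reduced = draw(st.booleans())
        cause = (
            draw(st.sampled_from(ADAPTED_CAUSES))
            if (delayed or reduced)
            else AdaptationCause.NONE
        )
        cycles.append(
            CycleRecord(
                cycle_index=j + 1,
                admin_day=day,
                dox_dose=draw(st.floats(0, 93.75, allow_nan=False, allow_infinity=False)),
                cddp_dose=draw(st.floats(0, 125.0, allow_nan=False, allow_infinity=False)),
                delayed=delayed,
                reduced=reduced,
                adaptation_cause=cause,
            )
        )
    return cycles


@st.composite
def cohorts(draw):
    n = draw(st.integers(min_value=0, max_value=5))
    courses = []
    for i in range(n):
        cycles = draw(cycle_lists())
        last_day = cycles[-1].admin_day if cycles else 0
        observed = draw(st.booleans())
        courses.append(
            TreatmentCourse(
                patient_id=f"P{i + 1}",
                arm=draw(st.sampled_from([Arm.REG_C, Arm.REG_DI])),
                cycles=cycles,
                surgery_day=draw(st.one_of(st.none(), st.integers(0, 500))),
                end_of_therapy_day=draw(st.integers(last_day, last_day + 90)),
                event_day=draw(st.integers(1, 3000)) if observed else None,
                event_observed=observed,
                censor_day=draw(st.integers(0, 3000)),
            )
        )
    return Cohort(courses=courses, provenance={"source": "hypothesis"})
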