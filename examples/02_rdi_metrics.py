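"""Compute standardised dose-intensity metrics for individual courses.

Shows the target dose intensity of each arm, the (tau, delta) trajectory
of an on-schedule dose-intense course, and how a mid-course delay plus
dose reduction moves a patient away from the target point.
"""

from rdistrat import (
    Arm,
    REG_C_TEMPLATE,
    REG_DI_TEMPLATE,
    TEMPLATES,
    achieved_rdi,
    intended_schedule,
    regulated_rdi,
    target_rdi,
    tau_to_days,
)
from rdistrat.cohort import AdaptationCause, CycleRecord, TreatmentCourse

for template in (REG_DI_TEMPLATE, REG_C_TEMPLATE):
    tau, delta = target_rdi(template)
    print(
        f"{template.arm.value}: intended admin days {intended_schedule(template)}, "
        f"target (tau, delta) = ({tau:.3f}, {delta:.1f}) -> {tau_to_days(tau)} days"
    )

# An on-schedule dose-intense course, except cycle 4 is delayed 14 days
# (myelotoxicity) and cycles 5-6 are reduced by 25%.
days = [0, 14, 28, 77, 91, 105]
cycles = []
for j, day in enumerate(days):
    reduced = j >= 4
    cycles.append(
        CycleRecord(
            cycle_index=j + 1,
            admin_day=day,
            dox_dose=75.0 * (0.75 if reduced else 1.0),
            cddp_dose=100.0 * (0.75 if reduced else 1.0),
            delayed=j == 3,
            reduced=reduced,
            adaptation_cause=AdaptationCause.MYELOTOXICITY if (j == 3 or reduced) else AdaptationCause.NONE,
        )
    )
course = TreatmentCourse(
    patient_id="EX", arm=Arm.REG_DI, cycles=cycles, end_of_therapy_day=119, censor_day=2555
)

traj = regulated_rdi(course, TEMPLATES[Arm.REG_DI])
print("\nregulated RDI trajectory (tau, delta) per completed cycle:")
for p in traj.points:
    print(f"  ({p.tau:.3f}, {p.delta:.3f})")
point = achieved_rdi(course, TEMPLATES[Arm.REG_DI])
print(
    f"achieved RDI: tau={point.tau:.3f} ({tau_to_days(point.tau)} days), "
    f"delta={point.delta:.3f} ({100 * point.delta:.0f}% of the target dose)"
)
# The delay stretches tau past 1 while the reductions leave delta short of
# 1: the endpoint quantifies how far this course fell from its target.
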