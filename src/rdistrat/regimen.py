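"""Intended treatment protocols and standardization constants.

Both arms deliver six combination cycles of doxorubicin 75 mg/m² plus
cisplatin 100 mg/m². The control arm (Reg-C) administers them 3-weekly with
surgery after the second cycle; the dose-intense arm (Reg-DI) administers
the same cycles 2-weekly with G-CSF support and surgery after the third
cycle. Surgery is scheduled at week 6 from the start of treatment in both
arms, with postoperative chemotherapy resuming 3 weeks after surgery.

Standardised time on treatment tau divides elapsed treatment time by 91
days — the intended first-to-last administration span of the dose-intense
arm — so an on-schedule Reg-DI course has tau = 1 exactly. The same
normalizer is used for both arms so that tau values are comparable across
arms.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import Arm

#: Protocol-level time normalizer in days (intended Reg-DI treatment span).
TIME_NORMALIZER_DAYS = 91


@dataclass(frozen=True)
class RegimenTemplate:
    """An intended arm protocol and its standardization constants."""

    arm: Arm
    n_cycles: int = 6
    interval_days: int = 21
    dox_per_cycle: float = 75.0
    cddp_per_cycle: float = 100.0
    preop_cycles: int = 2
    surgery_day: int = 42
    postop_gap_days: int = 21
    time_normalizer_days: int = TIME_NORMALIZER_DAYS

    @property
    def total_dox(self) -> float:
        """Total intended doxorubicin over the full protocol (450 mg/m²)."""
        return self.n_cycles * self.dox_per_cycle

    @property
    def total_cddp(self) -> float:
        """Total intended cisplatin over the full protocol (600 mg/m²)."""
        return self.n_cycles * self.cddp_per_cycle


REG_C_TEMPLATE = RegimenTemplate(arm=Arm.REG_C, interval_days=21, preop_cycles=2)
REG_DI_TEMPLATE = RegimenTemplate(arm=Arm.REG_DI, interval_days=14, preop_cycles=3)

TEMPLATES: dict[Arm, RegimenTemplate] = {
    Arm.REG_C: REG_C_TEMPLATE,
    Arm.REG_DI: REG_DI_TEMPLATE,
}


def intended_schedule(template: RegimenTemplate) -> list[int]:
    """Intended administration days (days since first administration).

    Preoperative cycles run at the arm's interval from day 0; surgery sits
    at day 42 (week 6); the first postoperative cycle follows 3 weeks after
    surgery and the remaining cycles resume the arm's interval.

    >>> intended_schedule(REG_DI_TEMPLATE)
    [0, 14, 28, 63, 77, 91]
    >>> intended_schedule(REG_C_TEMPLATE)
    [0, 21, 63, 84, 105, 126]
    """
    days = [i * template.interval_days for i in range(template.preop_cycles)]
    postop_start = template.surgery_day + template.postop_gap_days
    n_postop = template.n_cycles - template.preop_cycles
    days += [postop_start + i * template.interval_days for i in range(n_postop)]
    return days


def target_rdi(template: RegimenTemplate) -> tuple[float, float]:
    """Target (tau, delta) of an arm: full dose over the intended span.

    delta is 1 by construction (the full protocol dose); tau is the
    intended first-to-last administration span divided by the 91-day
    normalizer, hence exactly 1 for Reg-DI and 126/91 ≈ 1.385 for Reg-C.
    """
    schedule = intended_schedule(template)
    return schedule[-1] / template.time_normalizer_days, 1.0
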