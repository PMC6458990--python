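"""Per-stratum, per-cycle treatment-adaptation summaries.

For each stratum and cycle number, the proportion of patients who required
an adaptation (a delay or a dose reduction) is computed with the recorded
cause. The denominator at cycle j counts only patients in the stratum who
completed cycle j — discontinued cycles do not contribute. A cycle that is
both delayed and reduced counts once, under its recorded cause.
"""

from __future__ import annotations

import pandas as pd

from .cohort import ADAPTATION_CAUSES, AdaptationCause, Cohort
from .regimen import TEMPLATES
from .stratify import StratumAssignment

TABLE_COLUMNS = ["stratum", "cycle_index", "cause", "n_adapted", "n_at_cycle", "proportion"]


def adaptation_table(cohort: Cohort, assignment: StratumAssignment) -> pd.DataFrame:
    """Long-format adaptation table over stratum × cycle × cause."""
    rows = []
    for stratum in assignment.strata():
        courses = [c for c in cohort if assignment.labels[c.patient_id] == stratum]
        for cycle_index in range(1, 7):
            at_cycle = [
                cyc
                for course in courses
                for cyc in course.cycles
                if cyc.cycle_index == cycle_index
            ]
            n_at_cycle = len(at_cycle)
            for cause in ADAPTATION_CAUSES:
                n_adapted = sum(
                    1
                    for cyc in at_cycle
                    if (cyc.delayed or cyc.reduced) and cyc.adaptation_cause is cause
                )
                rows.append(
                    {
                        "stratum": stratum,
                        "cycle_index": cycle_index,
                        "cause": cause.value,
                        "n_adapted": n_adapted,
                        "n_at_cycle": n_at_cycle,
                        "proportion": n_adapted / n_at_cycle if n_at_cycle else 0.0,
                    }
                )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def preop_postop_split(
    cohort: Cohort,
    assignment: StratumAssignment,
    templates: dict | None = None,
    cause: AdaptationCause = AdaptationCause.MYELOTOXICITY,
) -> pd.DataFrame:
    """Preoperative versus postoperative adaptation burden per stratum.

    The preoperative window is arm-dependent (cycles 1–2 on the 3-weekly
    arm, 1–3 on the 2-weekly arm), so the split is computed patient-wise.
    Returns, per stratum and period, the proportion of completed patient
    cycles adapted with the given cause (myelotoxicity by default).
    """
    templates = templates or TEMPLATES
    rows = []
    for stratum in assignment.strata():
        courses = [c for c in cohort if assignment.labels[c.patient_id] == stratum]
        counts = {"preop": [0, 0], "postop": [0, 0]}  # [n_adapted, n_cycles]
        for course in courses:
            preop_cycles = templates[course.arm].preop_cycles
            for cyc in course.cycles:
                period = "preop" if cyc.cycle_index <= preop_cycles else "postop"
                counts[period][1] += 1
                if (cyc.delayed or cyc.reduced) and cyc.adaptation_cause is cause:
                    counts[period][0] += 1
        for period in ("preop", "postop"):
            n_adapted, n_cycles = counts[period]
            rows.append(
                {
                    "stratum": stratum,
                    "period": period,
                    "cause": cause.value,
                    "n_adapted": n_adapted,
                    "n_cycles": n_cycles,
                    "proportion": n_adapted / n_cycles if n_cycles else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["stratum", "period", "cause", "n_adapted", "n_cycles", "proportion"])
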