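"""Per-stratum, per-cycle adaptation tables and the pre/postoperative split."""

import numpy as np
import pytest

from rdistrat import (
    AdaptationCause,
    Archetype,
    Arm,
    Cohort,
    SimulationConfig,
    adaptation_table,
    arm_partition,
    compute_trajectories,
    generate_archetype_cohort,
    generate_cohort,
    kmeans_partition,
    preop_postop_split,
    rrdi_features,
)

from conftest import make_intended_course
from test_simulate import zero_toxicity_config


def _adapted(course, cycle_index, cause=AdaptationCause.MYELOTOXICITY):
    cyc = course.cycles[cycle_index - 1]
    cyc.delayed = True
    cyc.adaptation_cause = cause
    return course


class TestAdaptationTable:
    def test_hand_counted_proportion(self):
        courses = [make_intended_course(Arm.REG_C, patient_id=f"P{i}") for i in range(4)]
        _adapted(courses[0], 2)
        _adapted(courses[1], 2)
        cohort = Cohort(courses=courses)
        table = adaptation_table(cohort, arm_partition(cohort))
        row = table[
            (table.cycle_index == 2) & (table.cause == "myelotoxicity")
        ].iloc[0]
        assert row.n_adapted == 2 and row.n_at_cycle == 4 and row.proportion == 0.5

    def test_discontinued_cycles_not_in_denominator(self):
        full = make_intended_course(Arm.REG_C, patient_id="FULL")
        short = make_intended_course(Arm.REG_C, patient_id="SHORT", n_cycles=4)
        cohort = Cohort(courses=[full, short])
        table = adaptation_table(cohort, arm_partition(cohort))
        assert (table[table.cycle_index == 4].n_at_cycle == 2).all()
        assert (table[table.cycle_index == 5].n_at_cycle == 1).all()

    def test_zero_toxicity_all_proportions_zero(self):
        cohort = generate_cohort(zero_toxicity_config(n=30, seed=1))
        table = adaptation_table(cohort, arm_partition(cohort))
        assert (table.proportion == 0).all()

    def test_proportions_bounded_and_counts_additive(self):
        cohort = generate_cohort(SimulationConfig(n_patients=150, seed=14))
        table = adaptation_table(cohort, arm_partition(cohort))
        assert table.proportion.between(0, 1).all()
        # cause-specific counts sum to total adapted per (stratum, cycle)
        totals = table.groupby(["stratum", "cycle_index"]).n_adapted.sum()
        for (stratum, cycle), total in totals.items():
            adapted = sum(
                1
                for course in cohort
                if (1 if course.arm is Arm.REG_DI else 2) == stratum
                for cyc in course.cycles
                if cyc.cycle_index == cycle and (cyc.delayed or cyc.reduced)
            )
            assert total == adapted

    def test_invariant_to_patient_order(self):
        cohort = generate_cohort(SimulationConfig(n_patients=60, seed=15))
        table = adaptation_table(cohort, arm_partition(cohort))
        reversed_cohort = Cohort(courses=list(cohort)[::-1])
        table_rev = adaptation_table(reversed_cohort, arm_partition(reversed_cohort))
        assert table.equals(table_rev)

    def test_dual_adaptation_counts_once(self):
        course = make_intended_course(Arm.REG_C)
        cyc = course.cycles[1]
        cyc.delayed = cyc.reduced = True
        cyc.adaptation_cause = AdaptationCause.OTHER_TOXICITY
        cohort = Cohort(courses=[course])
        table = adaptation_table(cohort, arm_partition(cohort))
        at_cycle2 = table[table.cycle_index == 2]
        assert at_cycle2.n_adapted.sum() == 1
        assert at_cycle2[at_cycle2.cause == "other_toxicity"].n_adapted.iloc[0] == 1


class TestPreopPostopSplit:
    def test_planted_preop_myelotoxicity_maximal_in_its_stratum(self):
        # one archetype with delays confined to the preoperative cycles
        archetypes = [
            Archetype(name="early", arm=Arm.REG_DI, extra_delay_days=(0, 14, 14, 0, 0, 0)),
            Archetype(name="late", arm=Arm.REG_DI, extra_delay_days=(0, 0, 0, 14, 14, 0)),
            Archetype(name="clean", arm=Arm.REG_C),
        ]
        cfg = SimulationConfig(n_patients=300, seed=16)
        cohort, labels = generate_archetype_cohort(cfg, archetypes)
        traj = compute_trajectories(cohort)
        assignment = kmeans_partition(rrdi_features(cohort, traj), k=3, seed=16)
        split = preop_postop_split(cohort, assignment)

        # stratum holding the majority of the 'early' archetype
        from collections import Counter

        per = {s: Counter() for s in assignment.strata()}
        for pid, label in labels.items():
            per[assignment.labels[pid]][label] += 1
        early_stratum = max(per, key=lambda s: per[s]["early"])

        preop = split[split.period == "preop"].set_index("stratum").proportion
        assert preop.idxmax() == early_stratum

    def test_uniform_rates_give_similar_preop_postop_burden(self):
        # dose reductions apply uniformly to every cycle, so with delays
        # switched off the pre- and postoperative myelotoxicity burden
        # should agree within simulation error
        cfg = SimulationConfig(
            n_patients=1500,
            seed=18,
            base_delay_prob=0.0,
            base_reduction_prob=0.15,
            frailty_sd=0.0,
            cause_mix={
                AdaptationCause.MYELOTOXICITY: 1.0,
                AdaptationCause.OTHER_TOXICITY: 0.0,
                AdaptationCause.NON_TOXICITY: 0.0,
                AdaptationCause.UNKNOWN: 0.0,
            },
            discontinuation_prob_per_cycle=0.0,
        )
        cohort = generate_cohort(cfg)
        assignment = arm_partition(cohort)
        split = preop_postop_split(cohort, assignment)
        for stratum in assignment.strata():
            rows = split[split.stratum == stratum].set_index("period")
            diff = abs(rows.loc["preop"].proportion - rows.loc["postop"].proportion)
            assert diff < 0.03

    def test_empty_cohort_gives_empty_summary(self):
        cohort = Cohort()
        from rdistrat.stratify import StratumAssignment
        import numpy as np

        assignment = StratumAssignment(labels={}, centroids=np.empty((0, 2)), k=0, kind="ardi")
        split = preop_postop_split(cohort, assignment)
        assert split.empty
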