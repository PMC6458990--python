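"""Synthetic cohort generators: determinism, degenerate limits, planted
structure."""

import dataclasses

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from rdistrat import (
    Archetype,
    Arm,
    ConfigError,
    SimulationConfig,
    TEMPLATES,
    achieved_rdi,
    compute_trajectories,
    default_archetypes,
    generate_archetype_cohort,
    generate_cohort,
    intended_schedule,
    kmeans_partition,
    rrdi_features,
    target_rdi,
)


def zero_toxicity_config(n=50, seed=0):
    return SimulationConfig(
        n_patients=n,
        seed=seed,
        frailty_sd=0.0,
        base_delay_prob=0.0,
        base_reduction_prob=0.0,
        discontinuation_prob_per_cycle=0.0,
    )


class TestGenerateCohort:
    def test_same_seed_identical_cohorts(self):
        cfg = SimulationConfig(n_patients=60, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(SimulationConfig(n_patients=60, seed=42))
        assert [dataclasses.asdict(x) for x in a] == [dataclasses.asdict(y) for y in b]

    def test_different_seed_differs(self):
        a = generate_cohort(SimulationConfig(n_patients=60, seed=1))
        b = generate_cohort(SimulationConfig(n_patients=60, seed=2))
        assert [dataclasses.asdict(x) for x in a] != [dataclasses.asdict(y) for y in b]

    def test_zero_toxicity_matches_intended_schedule(self):
        cohort = generate_cohort(zero_toxicity_config())
        for course in cohort:
            template = TEMPLATES[course.arm]
            schedule = intended_schedule(template)
            first = course.cycles[0].admin_day
            assert [c.admin_day - first for c in course.cycles] == schedule
            point = achieved_rdi(course, template)
            assert (point.tau, point.delta) == target_rdi(template)

    def test_arm_allocation_binomially_balanced(self):
        cohort = generate_cohort(SimulationConfig(n_patients=2000, seed=9))
        n_di = sum(1 for c in cohort if c.arm is Arm.REG_DI)
        lo, hi = stats.binom.interval(0.99, 2000, 0.5)
        assert lo <= n_di <= hi

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generated_cohorts_pass_validation(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SimulationConfig(
            n_patients=40,
            seed=seed,
            frailty_sd=float(rng.uniform(0, 1.2)),
            base_delay_prob=float(rng.uniform(0, 0.6)),
            base_reduction_prob=float(rng.uniform(0, 0.4)),
            discontinuation_prob_per_cycle=float(rng.uniform(0, 0.1)),
        )
        generate_cohort(cfg).validate()  # raises on any invariant violation

    def test_first_administration_within_a_week_of_randomization(self):
        cohort = generate_cohort(SimulationConfig(n_patients=200, seed=3))
        lags = [c.cycles[0].admin_day for c in cohort]
        assert min(lags) >= 0 and max(lags) <= 7

    def test_frailty_increases_tau_and_decreases_delta(self):
        # discontinuation truncates courses (lowering final tau), so it is
        # switched off to isolate the delay/reduction channel of frailty
        low = generate_cohort(
            SimulationConfig(
                n_patients=800, seed=21, frailty_sd=0.1, discontinuation_prob_per_cycle=0.0
            )
        )
        high = generate_cohort(
            SimulationConfig(
                n_patients=800, seed=21, frailty_sd=1.0, discontinuation_prob_per_cycle=0.0
            )
        )

        def means(cohort):
            traj = compute_trajectories(cohort)
            return (
                np.mean([t.final.tau for t in traj.values()]),
                np.mean([t.final.delta for t in traj.values()]),
            )

        tau_low, delta_low = means(low)
        tau_high, delta_high = means(high)
        assert tau_high > tau_low
        assert delta_high < delta_low

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_patients=0).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(p_allocation_di=1.5).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(delay_days_probs=(0.5, 0.5, 0.5, 0.5)).validate()


class TestArchetypeCohort:
    def test_zero_jitter_recovers_labels_exactly(self):
        cfg = SimulationConfig(n_patients=200, seed=4)
        cohort, labels = generate_archetype_cohort(
            cfg, default_archetypes(), delay_jitter_days=0.0, dose_jitter_sd=0.0
        )
        traj = compute_trajectories(cohort)
        assignment = kmeans_partition(rrdi_features(cohort, traj), seed=4)
        ids = cohort.patient_ids()
        ari = adjusted_rand_score(
            [labels[p] for p in ids], [assignment.labels[p] for p in ids]
        )
        assert ari == 1.0

    def test_single_archetype_collapses_to_one_stratum(self):
        cfg = SimulationConfig(n_patients=30, seed=4)
        cohort, _ = generate_archetype_cohort(
            cfg,
            [Archetype(name="only", arm=Arm.REG_DI)],
            delay_jitter_days=0.0,
            dose_jitter_sd=0.0,
        )
        traj = compute_trajectories(cohort)
        with pytest.warns(UserWarning, match="distinct"):
            assignment = kmeans_partition(rrdi_features(cohort, traj), k=4, seed=4)
        assert assignment.k == 1
        assert set(assignment.labels.values()) == {1}

    def test_infeasible_archetype_rejected(self):
        bad = Archetype(name="bad", arm=Arm.REG_C, dose_fraction=(1, 1, -0.5, 1, 1, 1))
        with pytest.raises(ConfigError, match="decrease"):
            bad.validate()

    def test_latent_labels_cover_cohort(self):
        cfg = SimulationConfig(n_patients=100, seed=8)
        cohort, labels = generate_archetype_cohort(cfg, default_archetypes())
        assert set(labels) == set(cohort.patient_ids())
        assert set(labels.values()) <= {a.name for a in default_archetypes()}
        cohort.validate()
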