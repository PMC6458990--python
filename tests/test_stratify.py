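"""Feature construction and k-means stratification."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from rdistrat import (
    Arm,
    Cohort,
    FeatureKind,
    FeatureMatrix,
    SimulationConfig,
    arm_partition,
    ardi_features,
    compute_trajectories,
    generate_cohort,
    kmeans_partition,
    rrdi_features,
    stratum_summary,
)

from conftest import make_intended_course
from test_simulate import zero_toxicity_config


@pytest.fixture(scope="module")
def analysis_cohort():
    from rdistrat import apply_selection

    cohort = generate_cohort(SimulationConfig(n_patients=200, seed=12))
    analysis, _ = apply_selection(cohort)
    return analysis


@pytest.fixture(scope="module")
def trajectories(analysis_cohort):
    return compute_trajectories(analysis_cohort)


class TestFeatures:
    def test_ardi_shape_and_intended_row(self):
        cohort = Cohort(courses=[make_intended_course(Arm.REG_DI)])
        fm = ardi_features(cohort, compute_trajectories(cohort))
        assert fm.values.shape == (1, 2)
        assert fm.values[0].tolist() == [1.0, 1.0]

    def test_rrdi_intended_row(self):
        cohort = Cohort(courses=[make_intended_course(Arm.REG_DI)])
        fm = rrdi_features(cohort, compute_trajectories(cohort))
        np.testing.assert_allclose(
            fm.values[0, :6], np.array([0, 14, 28, 63, 77, 91]) / 91
        )
        np.testing.assert_allclose(fm.values[0, 6:], np.arange(1, 7) / 6)

    def test_rrdi_locf_padding(self):
        cohort = Cohort(courses=[make_intended_course(Arm.REG_DI, n_cycles=4)])
        fm = rrdi_features(cohort, compute_trajectories(cohort))
        row = fm.values[0]
        assert row[3] == row[4] == row[5]  # tau carried forward
        assert row[9] == row[10] == row[11]  # delta carried forward

    def test_rrdi_endpoint_matches_ardi_row(self, analysis_cohort, trajectories):
        a = ardi_features(analysis_cohort, trajectories)
        r = rrdi_features(analysis_cohort, trajectories)
        np.testing.assert_array_equal(r.values[:, 5], a.values[:, 0])
        np.testing.assert_array_equal(r.values[:, 11], a.values[:, 1])

    def test_identical_courses_identical_rows(self):
        cohort = Cohort(
            courses=[
                make_intended_course(Arm.REG_C, patient_id="A"),
                make_intended_course(Arm.REG_C, patient_id="B"),
            ]
        )
        fm = rrdi_features(cohort, compute_trajectories(cohort))
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_missing_metrics_errors(self, analysis_cohort):
        with pytest.raises(ValueError, match="missing metrics"):
            ardi_features(analysis_cohort, {})


class TestKMeans:
    def _clouds(self, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
        rows, truth = [], []
        for label, c in enumerate(centers):
            rows.append(c + rng.normal(0, 0.1, size=(25, 2)))
            truth += [label] * 25
        X = np.vstack(rows)
        ids = [f"P{i}" for i in range(len(X))]
        return FeatureMatrix(patient_ids=ids, values=X, kind=FeatureKind.ARDI), truth

    def test_separated_clouds_recovered_exactly(self):
        fm, truth = self._clouds()
        assignment = kmeans_partition(fm, k=4, seed=0)
        labels = [assignment.labels[p] for p in fm.patient_ids]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_row_permutation_invariance(self):
        fm, _ = self._clouds(seed=3)
        assignment = kmeans_partition(fm, k=4, seed=5)
        rng = np.random.default_rng(7)
        perm = rng.permutation(fm.n)
        fm_perm = FeatureMatrix(
            patient_ids=[fm.patient_ids[i] for i in perm],
            values=fm.values[perm],
            kind=fm.kind,
        )
        assert kmeans_partition(fm_perm, k=4, seed=5).labels == assignment.labels

    def test_k_one_gives_feature_mean_centroid(self):
        fm, _ = self._clouds()
        assignment = kmeans_partition(fm, k=1, seed=0)
        assert set(assignment.labels.values()) == {1}
        np.testing.assert_allclose(assignment.centroids[0], fm.values.mean(axis=0))

    def test_fewer_patients_than_k_errors(self):
        fm = FeatureMatrix(
            patient_ids=["A", "B"], values=np.eye(2), kind=FeatureKind.ARDI
        )
        with pytest.raises(ValueError, match="strata"):
            kmeans_partition(fm, k=4)

    def test_relabeling_orders_by_descending_delta(self, analysis_cohort, trajectories):
        fm = rrdi_features(analysis_cohort, trajectories)
        assignment = kmeans_partition(fm, k=4, seed=1)
        d = fm.values.shape[1] // 2
        delta_means = assignment.centroids[:, d:].mean(axis=1)
        assert list(delta_means) == sorted(delta_means, reverse=True)

    def test_labels_contiguous_from_one(self, analysis_cohort, trajectories):
        assignment = kmeans_partition(rrdi_features(analysis_cohort, trajectories), k=4, seed=2)
        assert assignment.strata() == list(range(1, assignment.k + 1))
        assert set(assignment.labels) == set(analysis_cohort.patient_ids())


class TestArmPartition:
    def test_two_strata_dose_intense_first(self, analysis_cohort):
        assignment = arm_partition(analysis_cohort)
        assert assignment.k == 2
        for course in analysis_cohort:
            expected = 1 if course.arm is Arm.REG_DI else 2
            assert assignment.labels[course.patient_id] == expected


class TestSummary:
    def test_zero_toxicity_cohort_summary(self):
        cohort = generate_cohort(zero_toxicity_config(n=40, seed=2))
        traj = compute_trajectories(cohort)
        summary = stratum_summary(cohort, arm_partition(cohort), traj)
        assert (summary["median_delta_pct"] == 100.0).all()
        assert (summary["median_cycles"] == 6).all()

    def test_counts_and_percentages_reconcile(self, analysis_cohort, trajectories):
        assignment = kmeans_partition(rrdi_features(analysis_cohort, trajectories), k=4, seed=3)
        summary = stratum_summary(analysis_cohort, assignment, trajectories)
        assert summary["n"].sum() == len(analysis_cohort)
        np.testing.assert_allclose(summary["pct_reg_c"] + summary["pct_reg_di"], 100.0)
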