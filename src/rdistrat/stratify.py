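"""Post hoc patient stratification in dose-intensity feature space.

Three progressively more individualised stratifications are supported:

* target (tRDI): the randomized-arm split itself — no clustering, every
  patient in an arm shares the arm's intended dose intensity;
* achieved (aRDI): k-means on the endpoint features (tau_final,
  delta_final);
* regulated (rRDI): k-means on the full trajectory vectorized into fixed
  per-cycle slots (tau_1..tau_6, delta_1..delta_6) with
  last-observation-carried-forward padding for courses of fewer than six
  cycles, so discontinuations group together naturally.

No feature scaling is applied: tau and delta are already standardized to
comparable unit scales. k defaults to 4 strata. Cluster labels are made
deterministic and permutation-invariant by fitting on canonically sorted
rows and relabeling clusters by descending mean standardised dose (ties
broken by ascending mean standardised time), so stratum 1 is always the
highest-dose/fastest stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cohort import Arm, Cohort
from .metrics import RDITrajectory
from .regimen import TEMPLATES, target_rdi

RELABEL_RULE = "descending mean delta slots, then ascending mean tau slots"


class FeatureKind(str, Enum):
    TRDI = "trdi"
    ARDI = "ardi"
    RRDI = "rrdi"


@dataclass
class FeatureMatrix:
    """Patient-aligned feature rows for clustering."""

    patient_ids: list[str]
    values: np.ndarray
    kind: FeatureKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.patient_ids):
            raise ValueError("feature matrix shape does not match patient_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class StratumAssignment:
    """Cluster labels (1..k), ordered centroids and the relabel rule."""

    labels: dict[str, int]
    centroids: np.ndarray
    k: int
    kind: FeatureKind
    relabel_rule: str = RELABEL_RULE

    def label_array(self, patient_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[pid] for pid in patient_ids], dtype=int)

    def strata(self) -> list[int]:
        return sorted(set(self.labels.values()))


def _require_metrics(cohort: Cohort, trajectories: dict[str, RDITrajectory]) -> None:
    missing = [c.patient_id for c in cohort if c.patient_id not in trajectories]
    if missing:
        raise ValueError(f"missing metrics for patients: {missing[:5]}")


def ardi_features(cohort: Cohort, trajectories: dict[str, RDITrajectory]) -> FeatureMatrix:
    """Endpoint features: one row (tau_final, delta_final) per patient."""
    _require_metrics(cohort, trajectories)
    ids = cohort.patient_ids()
    rows = [[trajectories[pid].final.tau, trajectories[pid].final.delta] for pid in ids]
    return FeatureMatrix(patient_ids=ids, values=np.array(rows, dtype=float), kind=FeatureKind.ARDI)


def rrdi_features(cohort: Cohort, trajectories: dict[str, RDITrajectory]) -> FeatureMatrix:
    """Trajectory features: (tau_1..6, delta_1..6) with LOCF padding."""
    _require_metrics(cohort, trajectories)
    ids = cohort.patient_ids()
    rows = []
    for pid in ids:
        pts = trajectories[pid].points
        taus = [p.tau for p in pts]
        deltas = [p.delta for p in pts]
        pad = 6 - len(pts)
        rows.append(taus + [taus[-1]] * pad + deltas + [deltas[-1]] * pad)
    return FeatureMatrix(patient_ids=ids, values=np.array(rows, dtype=float), kind=FeatureKind.RRDI)


def _delta_tau_means(centroids: np.ndarray, kind: FeatureKind) -> tuple[np.ndarray, np.ndarray]:
    if kind is FeatureKind.ARDI:
        return centroids[:, 1], centroids[:, 0]
    d = centroids.shape[1] // 2
    return centroids[:, d:].mean(axis=1), centroids[:, :d].mean(axis=1)


def kmeans_partition(
    features: FeatureMatrix,
    k: int = 4,
    n_restarts: int = 50,
    seed: int = 0,
) -> StratumAssignment:
    """Partition patients by Lloyd-style k-means, best of *n_restarts*.

    Deterministic given the seed and invariant to input row order: the
    model is fitted on lexicographically sorted rows and original rows are
    then assigned to the fitted centroids. If the data hold fewer distinct
    rows than k (degenerate input), k is reduced to that number with a
    warning, so all-identical inputs yield a single stratum.
    """
    X = features.values
    n = X.shape[0]
    if n < k:
        raise ValueError(f"cannot form {k} strata from {n} patients")
    n_distinct = len(np.unique(X, axis=0))
    k_eff = min(k, n_distinct)
    if k_eff < k:
        warnings.warn(
            f"only {n_distinct} distinct feature rows; reducing k from {k} to {k_eff}",
            stacklevel=2,
        )

    order = np.lexsort(X.T[::-1])
    km = KMeans(n_clusters=k_eff, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    km.fit(X[order])
    raw_labels = km.predict(X)
    centroids = km.cluster_centers_

    delta_means, tau_means = _delta_tau_means(centroids, features.kind)
    rank = np.lexsort((tau_means, -delta_means))  # primary: delta desc; tie: tau asc

    # Contiguous 1-based labels in rank order, dropping any empty cluster.
    occupied = [c for c in rank if np.any(raw_labels == c)]
    remap = {c: i + 1 for i, c in enumerate(occupied)}
    labels = {
        pid: remap[raw]
        for pid, raw in zip(features.patient_ids, raw_labels)
    }
    ordered_centroids = centroids[occupied]
    return StratumAssignment(
        labels=labels,
        centroids=ordered_centroids,
        k=len(occupied),
        kind=features.kind,
    )


def arm_partition(cohort: Cohort) -> StratumAssignment:
    """The target-RDI stratification: the two randomized arms.

    Labels follow the same ordering convention as the clustered strata
    (both arms share delta = 1; the dose-intense arm has the smaller target
    tau and gets label 1).
    """
    centroids = []
    labels: dict[str, int] = {}
    arm_label = {Arm.REG_DI: 1, Arm.REG_C: 2}
    for course in cohort:
        labels[course.patient_id] = arm_label[course.arm]
    for arm in (Arm.REG_DI, Arm.REG_C):
        tau, delta = target_rdi(TEMPLATES[arm])
        centroids.append([tau, delta])
    present = sorted(set(labels.values()))
    remap = {old: i + 1 for i, old in enumerate(present)}
    labels = {pid: remap[v] for pid, v in labels.items()}
    centroids = np.array([centroids[old - 1] for old in present], dtype=float)
    return StratumAssignment(
        labels=labels,
        centroids=centroids,
        k=len(present),
        kind=FeatureKind.TRDI,
        relabel_rule="dose-intense arm first (ascending target tau)",
    )


def stratum_summary(
    cohort: Cohort,
    assignment: StratumAssignment,
    trajectories: dict[str, RDITrajectory],
) -> pd.DataFrame:
    """Per-stratum summary: n, arm composition, medians of delta (as % of
    the target dose), tau, and cycles completed."""
    _require_metrics(cohort, trajectories)
    rows = []
    for stratum in assignment.strata():
        courses = [c for c in cohort if assignment.labels[c.patient_id] == stratum]
        n = len(courses)
        n_c = sum(1 for c in courses if c.arm is Arm.REG_C)
        deltas = [trajectories[c.patient_id].final.delta for c in courses]
        taus = [trajectories[c.patient_id].final.tau for c in courses]
        cycles = [len(trajectories[c.patient_id]) for c in courses]
        rows.append(
            {
                "stratum": stratum,
                "n": n,
                "pct_reg_c": 100.0 * n_c / n,
                "pct_reg_di": 100.0 * (n - n_c) / n,
                "median_delta_pct": 100.0 * float(np.median(deltas)),
                "median_tau": float(np.median(taus)),
                "median_cycles": float(np.median(cycles)),
            }
        )
    return pd.DataFrame(rows)


def assignment_frame(assignment: StratumAssignment) -> pd.DataFrame:
    """Long-format assignment table: patient_id, stratum_label, feature_kind."""
    return pd.DataFrame(
        [
            {"patient_id": pid, "stratum_label": label, "feature_kind": assignment.kind.value}
            for pid, label in sorted(assignment.labels.items())
        ]
    )
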