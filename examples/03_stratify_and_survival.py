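"""Stratify a cohort by trajectory similarity and compare survival.

Generates a cohort, applies the selection rules and the 180-day landmark,
clusters the regulated-RDI trajectories into four strata, and prints each
stratum's composition and 3-year event-free survival from the landmark.
"""

from rdistrat import (
    SimulationConfig,
    apply_selection,
    compute_trajectories,
    generate_cohort,
    km_by_stratum,
    kmeans_partition,
    rrdi_features,
    stratum_summary,
    survival_at,
)

cohort = generate_cohort(SimulationConfig(n_patients=500, seed=7))
analysis, report = apply_selection(cohort)
print(
    f"analysis set {report.n_analysis_set}/{report.n_input} "
    f"(events by landmark: {report.n_event_before_landmark}, "
    f"therapy ongoing: {report.n_not_completed_by_landmark})"
)

trajectories = compute_trajectories(analysis)
assignment = kmeans_partition(rrdi_features(analysis, trajectories), k=4, seed=7)
summary = stratum_summary(analysis, assignment, trajectories)
print("\nstratum summary (delta as % of target dose):")
print(summary.round(2).to_string(index=False))

curves = km_by_stratum(analysis, assignment)
print("\n3-year event-free survival from the landmark:")
for stratum, curve in sorted(curves.items()):
    print(f"  stratum {stratum}: {100 * survival_at(curve, 1095):.1f}% (n={curve.n_subjects})")
# Stratum 1 is by construction the highest-dose/fastest group; under the
# default conditions outcomes do not depend on tolerability, so the EFS
# values should agree within sampling noise.
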