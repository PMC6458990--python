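"""Per-stratum adaptation profiles: which cycles, which causes.

Plants a subgroup with strongly inflated preoperative myelotoxicity,
recovers trajectory strata, and prints each stratum's preoperative versus
postoperative myelotoxicity burden.
"""

from rdistrat import (
    SimulationConfig,
    adaptation_table,
    apply_selection,
    compute_trajectories,
    generate_cohort,
    kmeans_partition,
    preop_postop_split,
    rrdi_features,
)

cfg = SimulationConfig(
    n_patients=500,
    seed=9,
    preop_myelotox_multiplier=3.0,
    preop_subgroup_fraction=0.25,
)
analysis, _ = apply_selection(generate_cohort(cfg))
trajectories = compute_trajectories(analysis)
assignment = kmeans_partition(rrdi_features(analysis, trajectories), k=4, seed=9)

table = adaptation_table(analysis, assignment)
myelo = table[table.cause == "myelotoxicity"]
print("myelotoxicity adaptation proportion by stratum and cycle:")
print(
    myelo.pivot(index="stratum", columns="cycle_index", values="proportion")
    .round(2)
    .to_string()
)

split = preop_postop_split(analysis, assignment)
print("\npreoperative vs postoperative myelotoxicity proportion:")
print(split.pivot(index="stratum", columns="period", values="proportion").round(3).to_string())
# The stratum absorbing the planted subgroup shows a clearly higher
# preoperative than postoperative myelotoxicity proportion; discontinued
# cycles never enter the denominators.
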