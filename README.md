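# rdistrat

Individualised received-dose-intensity (RDI) analysis for cycle-level
chemotherapy delivery data.

Arm-wide intensification trials in osteosarcoma — escalating the intended
dose or compressing the schedule for a whole randomized arm — have
repeatedly failed to show a survival benefit. One reason is that the
intended regimen says little about what each patient actually received:
toxicity forces per-cycle delays, dose reductions and discontinuations
that differ widely between patients randomized to the same arm. This
package implements a patient-level alternative: it represents each course
of treatment as a trajectory of cumulative dose over time, stratifies
patients by the similarity of those trajectories, and compares event-free
survival (EFS) and adverse-event profiles across the resulting strata. It
is aimed at biostatisticians and trialists working with per-cycle delivery
records.

## The measures

The emulated protocol gives six cycles of doxorubicin (DOX, 75 mg/m²)
plus cisplatin (CDDP, 100 mg/m²), either 3-weekly (control, Reg-C) or
2-weekly with G-CSF support (dose-intense, Reg-DI), with surgery at week 6
and postoperative resumption 3 weeks later. For a patient with completed
cycles 1..J,

- standardised cumulative dose through cycle *j*:
  δⱼ = ½ (Σᵢ≤ⱼ DOXᵢ / 450 + Σᵢ≤ⱼ CDDPᵢ / 600),
  the mean of the two agents' cumulative-dose fractions of the full
  intended protocol (450 and 600 mg/m²);
- standardised time on treatment:
  τⱼ = (admin day of cycle *j* − admin day of cycle 1) / 91,
  where 91 days is the intended first-to-last administration span of the
  dose-intense arm (so its target τ is exactly 1; the control arm's is
  126/91 ≈ 1.385).

Three progressively more individualised representations follow:

- **tRDI** (target): the arm's intended (τ, δ) — identical for everyone
  randomized to the same arm;
- **aRDI** (achieved): the patient's endpoint (τ_J, δ_J);
- **rRDI** (regulated): the whole trajectory ((τ₁, δ₁), …, (τ_J, δ_J)),
  one point per completed cycle; each segment's slope is the treatment
  intensity achieved in that cycle.

The analysis set applies a dose-plausibility rule (any single agent dose
> 1.25 × prescribed excludes the patient) and a landmark at day 180 since
randomization (patients with an earlier event, or therapy still ongoing,
are excluded; survival is measured from the landmark). Strata are formed
by k-means (k = 4) on the aRDI endpoint or on the rRDI trajectory
vectorized into per-cycle slots with last-observation-carried-forward
padding; EFS per stratum is estimated with the Kaplan–Meier product-limit
estimator. Because the trial-scale data this design emulates are not
publicly deposited, the package ships a synthetic cohort generator (a
per-patient frailty mechanism, plus a planted-archetype variant for
recovery testing) so that every stage is testable end to end.

## Worked example

```python
from rdistrat import (SimulationConfig, generate_cohort, apply_selection,
                      compute_trajectories, rrdi_features, kmeans_partition,
                      stratum_summary, km_by_stratum, survival_at)

cohort = generate_cohort(SimulationConfig(n_patients=500, seed=7))
analysis, report = apply_selection(cohort)
traj = compute_trajectories(analysis)
assignment = kmeans_partition(rrdi_features(analysis, traj), k=4, seed=7)
print(stratum_summary(analysis, assignment, traj))
```

This prints (see `examples/03_stratify_and_survival.py`):

```
analysis set 436/500 (events by landmark: 39, therapy ongoing: 25)

 stratum   n  pct_reg_c  pct_reg_di  median_delta_pct  median_tau  median_cycles
       1 210      87.62       12.38             95.83        1.46            6.0
       2 188       1.60       98.40             95.83        1.08            6.0
       3  14      35.71       64.29             45.83        0.50            3.0
       4  24      54.17       45.83             27.08        0.15            2.0
```

Stratum 1 is dominated by control-arm patients who completed near-full
dose over a long span (median τ 1.46 ≈ 133 days); stratum 2 by
dose-intense patients who completed the same dose faster (τ 1.08 ≈ 98
days); strata 3–4 capture discontinuations (median 3 and 2 cycles). The
per-stratum 3-year EFS from `km_by_stratum`/`survival_at` is 50.0%,
52.7%, 71.4% and 54.2% — under the default generator, outcomes are
independent of tolerability, so these differ only by sampling noise.

`examples/` holds one short script per capability (simulation, metrics,
stratification + survival, trajectory-vs-endpoint clustering, adverse
events, full pipeline). A thin CLI wraps the pipeline:

```bash
rdistrat run-all --seed 5 --outdir run   # or: simulate / select / metrics /
                                         # stratify / survival / adverse-events
```

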