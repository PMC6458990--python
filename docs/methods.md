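# Methods

## Data model and standardization

A cohort is a set of treatment courses, one per patient: ordered per-cycle
records (administration day, per-agent dose in mg/m², delay/reduction
flags with a recorded cause) plus patient-level surgery, end-of-therapy
and outcome fields. All days are integers since randomization (day 0);
absent values are serialized as empty CSV fields, never sentinels.

The emulated protocol is six DOX (75 mg/m²) + CDDP (100 mg/m²) cycles,
3-weekly on the control arm (surgery after cycle 2) or 2-weekly with
G-CSF on the dose-intense arm (surgery after cycle 3); surgery sits at
day 42 (week 6 of treatment) and postoperative cycles resume 21 days
later. The intended administration days are therefore
[0, 21, 63, 84, 105, 126] (control) and [0, 14, 28, 63, 77, 91]
(dose-intense), days since first administration.

Standardised cumulative dose through completed cycle *j* is
δⱼ = ½ (Σ DOX/450 + Σ CDDP/600): the two agents, always given as a
combination cycle, are weighted equally as fractions of their full
intended totals. Standardised time is τⱼ = (admin day of cycle *j* −
admin day of cycle 1)/91. Choices worth stating explicitly:

- **The 91-day normalizer is shared by both arms** (it equals the
  dose-intense arm's intended span, making that arm's target τ exactly 1
  and the control arm's 126/91 ≈ 1.385). A per-arm normalizer would make
  τ values incomparable across arms.
- **τ's origin is the first administration, not randomization.** Surgery
  and cycle spacing are defined relative to the start of treatment; the
  randomization-to-first-administration lag (days, occasionally a week)
  is enrolment logistics, not treatment intensity.
- **Dose is credited at administration.** Each cycle contributes its dose
  at its administration day; only completed cycles generate trajectory
  points, but any administered dose counts toward δ.
- **τ→days conversion** rounds half away from zero
  (`round(τ × 91)`), e.g. τ = 1.56 → 142 days, τ = 0.78 → 71 days.
- δ is bounded by 1.25 because the selection stage has already removed
  any course with a single agent dose above 1.25 × prescribed.

The achieved RDI is the endpoint (τ_J, δ_J); the regulated RDI is the
full per-cycle trajectory, monotone in both coordinates by construction,
whose last point equals the achieved point identically.

## Selection and the landmark

Pre-filters remove patients with zero administered cycles and patients
with any single agent dose strictly above 1.25 × prescribed
(DOX > 93.75, CDDP > 125 mg/m²; a ratio of exactly 1.25 is retained).
The landmark at day 180 since randomization removes patients with an
event on or before day 180 and patients whose therapy was still ongoing
(end of therapy after day 180); discontinuation ends therapy, so
discontinued patients are retained. Survival is then measured from the
landmark, which removes immortal-time (guarantee-time) bias: membership
in a dose-intensity stratum is only knowable once treatment is over.
Exclusion precedence is fixed — never-started, abnormal dose, event,
not-completed — so audit reports are deterministic. "Registration" and
"randomization" are treated as the same day-0 origin.

EFS from each patient's own end of therapy is retained as an option
(`efs_origin_rule="end_of_therapy"`); the default common landmark origin
makes curves directly comparable across strata.

## Stratification

Endpoint (aRDI) features are (τ_final, δ_final); trajectory (rRDI)
features are the twelve per-cycle slots (τ₁..τ₆, δ₁..δ₆) with
last-observation-carried-forward padding for courses of fewer than six
cycles. LOCF was chosen over zero-padding or interpolation because it
places discontinued courses on a plateau that k-means naturally groups,
yielding the discontinuation-dominated stratum such analyses expect. No
feature scaling is applied — τ and δ are already standardized to
comparable unit scales, and rescaling would silently reweight time
against dose.

Clustering is Euclidean k-means, k = 4 (two strata would only reproduce
the arm split; four resolves the fast/slow completers and the
discontinuers), best of 50 restarts. Determinism and permutation
invariance: the model is fitted on lexicographically sorted rows with a
fixed random state, then every original row is assigned to the fitted
centroids. Labels are relabelled 1..k by descending mean of the δ slots
(ties: ascending mean τ), so stratum 1 is always the
highest-dose/fastest group regardless of restart order. Degenerate
inputs with fewer distinct rows than k reduce k to that number with a
warning (all-identical inputs yield a single stratum). The target-RDI
scenario performs no clustering: it is the randomized-arm split, labelled
with the same convention (dose-intense arm first).

## Survival estimation

The product-limit estimator S(t) = Π_{tᵢ≤t} (1 − dᵢ/nᵢ) is computed as a
literal sequential product over distinct event times, with subjects
censored at an event time kept at risk at that time (events before
censorings). The sequential form is deliberate: it agrees bit-for-bit
with an explicit risk-set recomputation, which the test suite exploits;
the suite also cross-checks against lifelines at 1e-12. Greenwood
standard errors are carried on the curve as an optional output.
Evaluation beyond the last observed time returns the last value with an
extrapolation flag. "3-year EFS" means S(1095 days) on the curve's own
time axis (days since the landmark by default).

## Synthetic cohorts

The generator emulates the trial structure the analysis was designed
for; the source trial reports no delivery-level distributions, so all of
the following are stand-ins chosen once for plausibility:

- 1:1 allocation; first administration uniform 0–7 days after
  randomization; n defaults to 500 (the scale of the emulated trial).
- One per-patient log-normal frailty exp(g), g ~ N(0, 0.5²), multiplies
  the per-cycle delay (base 0.30, cycles 2+), reduction (base 0.12) and
  discontinuation (base 0.025) probabilities — a single latent
  tolerability scalar is the minimal mechanism by which one patient's
  whole course is systematically harder than another's. Delays shift all
  subsequent cycles by 3/7/14/21 days (probabilities .35/.35/.20/.10);
  reductions remove 25% of both agents jointly (the combination is given
  as a unit). Recorded causes are drawn from a fixed mix
  (myelotoxicity .6, other toxicity .2, non-toxicity .1, unknown .1); an
  optional designated subgroup gets its preoperative delay/reduction
  odds multiplied and causes forced toward myelotoxicity, so early-vs-late
  toxicity contrasts can be planted and detected.
- Event times are exponential with hazard 5.5 × 10⁻⁴/day (≈55% 3-year
  EFS, the range such cohorts report), scaled by exp(coef × g); the
  frailty–hazard coupling defaults to 0 so the null is the default.
  Administrative censoring at 7 years.

The archetype generator draws each patient near one of a few fixed
delay/dose templates (integer-day jitter, SD 2 days; dose-fraction
jitter, SD 0.02) and returns the latent labels, giving ground truth for
cluster-recovery tests. Two canned sets are provided: four
well-separated archetypes (on-schedule control, discontinuer,
on-schedule dose-intense, adapted dose-intense — optionally with a
hazard ratio of 0.45 planted on one of them), and an endpoint-matched
pair whose members share (τ_final, δ_final) but place their delays
preoperatively versus postoperatively — separable by trajectory features,
provably not by endpoint features.

What the generator does **not** model: body-surface-area dosing (doses
are already per m²), pharmacokinetics/pharmacogenetics, competing risks,
CTC toxicity grades, per-agent asymmetric reductions, or
enrolment-period effects. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that planted structure of the stated
kinds is recoverable — not that real cohorts contain such structure.

## Problem sizes and numerics

Simulation-based checks use cohorts of 800 patients (recovery,
planted-survival and null-calibration runs), 1000 courses for trajectory
identities, and 2000 for allocation balance and exponential calibration;
k-means uses 50 restarts throughout. The null survival calibration
compares pairwise 3-year EFS differences against ±2.807 ×
√(SE₁² + SE₂²) Greenwood bands (two-sided ≈99.5% per pair). Ties in the
lexicographic sort used for permutation invariance are harmless
(identical rows are interchangeable). The pipeline writes a manifest
with SHA-256 digests of every CSV; reruns with an identical config are
byte-identical.

## Known limitations

- The rRDI vectorization (fixed per-cycle slots + LOCF) is one
  reasonable choice among several; trajectory representations with
  explicit time-warping or spline coefficients could behave differently
  for heavily delayed courses.
- The landmark origin for EFS and the end-of-therapy definition of the
  outcome are in tension (they differ per patient); both are offered,
  and the default favours cross-stratum comparability.
- k-means with Euclidean distance treats all twelve trajectory slots
  exchangeably; it cannot express that early cycles might matter more
  than late ones.
- No inferential comparison between strata is performed (no log-rank
  tests, no Cox models); the stratifications are descriptive.
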