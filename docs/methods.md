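# Methods

## Model overview

`crcscreen` is a continuous-time, event-driven Monte Carlo
microsimulation of the adenoma–carcinoma sequence and of stool-based and
colonoscopic screening for colorectal cancer.  Each simulated person
carries a latent disease history (adenomas, their growth, malignant
transformation, preclinical dwell, clinical presentation, stage and
survival) that is generated once and then replayed under a no-screening
counterfactual and under each screening strategy × sensitivity scenario,
with all randomness paired at the individual level.

## Scenario construction

Scenario cells are built by a symmetric logit split of the base
per-lesion colonoscopy sensitivities (75/85/95% for small/medium/large
adenomas): given a log odds ratio λ between the follow-up/surveillance
and screening arms, the arms are `expit(logit(base) ∓ λ/2)`.  The split
rule is identified by the published grid itself: on a 10⁻⁴ lattice of
candidate pairs constrained to each cell's λ, the pairs that reproduce
the printed percentages are exactly those whose logit midpoint is the
base value (see `test_lattice_oracle_selects_symmetric_split`).  λ for
large adenomas is the scenario anchor (0, 1 or 2); medium and small add
one and two slope increments (0.15, 0.30 or 0.60).  Percentages are
compared to printed values with half-up rounding to one decimal.

## Population

A single birth cohort (default 1975).  Other-cause death ages are
sampled by inverting one uniform against the cumulative survival of an
annual-probability (`qx`) cohort life table; within-year timing is
uniform.  The packaged table (`data/life_table_1975.csv`) is *synthetic*
— a Gompertz–Makeham-style curve with an infant bump, chosen once to
give a cohort life expectancy near 78 years — standing in for an
all-cause-minus-CRC cohort table, which is not distributed here.  Any
real table loads from CSV.

Between-person adenoma risk heterogeneity is a lognormal frailty
multiplier with mean 1 (default σ = 1.1, a typical dispersion for
adenoma-risk heterogeneity in this model family); σ = 0 collapses to a
homogeneous cohort.  Sex is recorded and plumbed through the survival
interface but the default parameters are sex-neutral; a sex-stratified
configuration can be dropped in without interface changes.

## Natural history

All components are set by `NaturalHistoryParams` (YAML/JSON-serialisable,
schema-versioned).  **The shipped defaults are this package's own
placeholder calibration**: the exact parameter values of established CRC
microsimulation models are maintained in external repositories and are
not reproduced here; the default configuration was chosen once to
produce an epidemiologically plausible unscreened cohort and then
frozen.  Replicating a specific published model is a config swap plus
the calibration hook below.

* **Onset**: non-homogeneous Poisson process, piecewise-constant
  baseline intensity by age (default: 0 before age 20 rising in steps to
  0.040/yr at 80+) × frailty × a global scale.  Sampling is exact
  (per-segment Poisson counts + uniform placement).
* **Growth**: diameter 1 mm at onset growing exponentially, reaching
  10 mm after a lognormal time (default median 25 y, σ = 0.8), capped at
  30 mm.  Size classes at an exam use the continuous diameter at the
  exam date (1–5, 6–9, ≥10 mm).
* **Transformation**: hazard k·(d/10 mm)^p along the growth curve
  (default k = 0.003/yr at 10 mm, p = 2), integrated in closed form and
  inverted, flat once the diameter caps.  With p = 0 this degenerates to
  a constant hazard (used by the exponential test oracle).
* **Sojourn**: lognormal preclinical dwell (default μ = 1.25, σ = 0.55;
  mean ≈ 4 y).  The first cancer to surface clinically before death is
  the diagnosed CRC; lesion accrual is irrelevant after diagnosis (one
  diagnosed CRC per person).
* **Stage and survival**: stage I–IV categorical distributions, with the
  screen-detected distribution shifted toward early stage
  (0.48/0.30/0.15/0.07 vs 0.18/0.30/0.28/0.24 symptomatic); survival is
  cure fraction + exponential residual, both stage-monotone (cure
  0.92/0.78/0.55/0.08, mean 10/7/4.5/1.6 y).  The stage draw and the
  survival draws reuse the same uniforms across detection modes and
  stages, so screen detection is pathwise never worse than symptomatic
  presentation of the same lesion.

Under the frozen defaults the unscreened cohort shows ≈ 64 CRC cases and
≈ 23 CRC deaths per 1000 people alive and CRC-free at 40 (lifetime risk
≈ 6.4%), mean ≈ 1.1 adenomas per person — plausible for an average-risk
Western cohort, but not fitted to any registry.  Consequently absolute
outcome levels (e.g. LYG per 1000) are smaller than published
model-family values, while rate-type outcomes (AMR, ADR, reductions)
and all trend directions are directly comparable.

## Screening

Exams fall on integer ages, birthday-aligned, from 50 to 75 at the
strategy interval (colonoscopy 10 y, FIT 1 y, mt-sDNA 3 y), 100%
adherence.  Stool tests are one Bernoulli per person per exam using the
most advanced lesion present: preclinical CRC (FIT 73.8%, mt-sDNA
92.3%), else any adenoma ≥10 mm (23.8% / 42.4%), else any adenoma
(7.6% / 17.2%), else a false positive at 1 − specificity (96.4% /
89.8%).  A positive stool test always triggers a follow-up colonoscopy
at the same decision epoch.

Colonoscopy detects each adenoma independently at the indication arm's
size-class sensitivity; preclinical cancers are found with probability
0.95.  Full cecal reach occurs 95% of the time; partial reach triggers
an immediate completed repeat — both exams count toward colonoscopy
totals, and detection is evaluated once at full reach.  Under this
resolution every lesion is effectively within reach at a completed exam,
so the AMR's within-reach restriction is vacuous at the default profile.
With probability 1 − 0.86 a non-adenomatous polypectomy occurs
(complication exposure only).  Complication risk per exam is a
config-driven age curve (default 0.25% at 50 rising ≈ 3%/yr of age) —
a placeholder shape, not an estimate.

Findings map to surveillance intervals: ≥1 large adenoma or ≥3 adenomas
→ 3 y; 1–2 non-large adenomas → 5 y; none → exit surveillance, stool
testing resuming 10 years later (within the 50–75 window); surveillance
runs to age 85.  For the colonoscopy strategy, routine exams use the
screening arm and all post-finding exams the follow-up/surveillance arm;
stool-triggered colonoscopies always use the follow-up arm in the
primary analysis.  Sensitivity analysis 1 flips a per-modality switch so
FIT-triggered exams use the screening arm; sensitivity analysis 2
accepts alternate test-performance inputs (size/segment-specific stool
sensitivity, age-banded specificity) and forces the large-adenoma arms
equal — the schema is implemented and tested on identity/degenerate
inputs; no alternative numeric input set ships with the package.

## Outcomes

All outcomes are per 1000 individuals alive and CRC-free at exact age
40, undiscounted, against the paired no-screening counterfactual.  The
weighted AMR uses single-year-of-age cross-sections — missed/present
adenomas among all colonoscopies at that age, all indications pooled
(a screening-only mode exists) — weighted by exam count at that age.
ADR is the fraction of each person's *first* follow-up colonoscopy with
≥1 detected adenoma.  Comparable effectiveness is LYG ≥ 90% of the
colonoscopy strategy's LYG within the same scenario.

## Randomness and reproducibility

Every stochastic decision draws `u = f(individual key, purpose tag,
context labels)` from a splitmix64 mixing function; the individual key
derives from the run seed and the person's index.  This makes (a) runs
bit-reproducible for a fixed seed on any platform, (b) the same person's
natural history identical in every cell, (c) single decisions (a given
lesion at a given exam) pathwise monotone in the probability applied to
them, which is why raising any sensitivity cannot reduce detections at
that exam.  Aggregate monotonicity across the grid holds statistically
(event schedules may diverge after a changed detection) and is asserted
at n = 2×10⁵ in the test suite.  Results are independent of cohort size
partitioning: person i sees the same numbers in a cohort of 10 or 10⁶.

## Problem sizes

The test suite runs closed-form stochastic oracles at 10⁵ draws (3
standard-error tolerance) and the grid-direction checks at n = 2×10⁵
with scenarios 1 and 10 (the grid endpoints).  The analysis drivers
default to n = 5×10⁴ for a full 10-scenario × 3-strategy grid;
published-model scale (4×10⁶) is reachable by passing a larger n — the
simulation is O(n) at roughly 40–80 µs per person-strategy pass.

## Known limitations

* The natural-history defaults are placeholders; absolute LYG and
  case counts are calibration-dependent.  The calibration hook
  (`calibration.fit_onset_scale`) recovers the onset-rate scale from
  simulated lifetime adenoma counts via the linear moment estimator
  `scale = Σ counts / Σ frailty·Λ(death age)`; CRC incidence would
  identify it too but far more noisily.
* No serrated-polyp pathway, no adenoma regression, no calendar-period
  effects, no imperfect adherence, no costs.
* Stage at screen detection ignores the lesion's dwell time in the
  preclinical phase (a single shifted distribution, not a
  time-in-phase model).
* The complication age curve and the surveillance policy table are
  config-replaceable conventions, not fitted quantities.
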