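# Methods

## Data model

A cohort is a table of primary-care patients with an acute respiratory
tract infection. Each record carries binary symptom/sign indicators
(runny nose absent, feels ill, current smoker, new-onset confusion),
vital signs (age, respiratory rate, systolic/diastolic blood pressure,
oxygen saturation), biomarkers (CRP in mg/l, procalcitonin in the units
supplied — PCT units are not standardised here — and MR-proADM in nmol/l),
the binary outcome (consolidation on chest X ray, i.e. pneumonia), and
optional follow-up fields. Missingness is explicit: an empty CSV cell maps
to a missing value and survives a round trip. Indicator direction matters
and is stored exactly as the prediction equations use it (1 = runny nose
**absent**, 1 = feels ill), preventing sign errors.

Analyses are complete-case: a record enters an analysis only if every
field that analysis needs is present, and the number excluded per field is
reported. No imputation is performed.

## Prediction models

`LogisticEquation` is an intercept plus named term coefficients under the
logistic link; `predict` returns 1/(1 + exp(−(β₀ + Σ βᵢxᵢ))). Two published
equations ship as constants (see README). The CRP term is the indicator
CRP > 30 mg/l with a **strict** inequality: a value exactly at a cutoff
scores 0. The same strictness applies to the MR-proADM cutoffs 0.646 and
1.00 nmol/l. No PCT cutoff is provided by default because no defensible
value is available; callers supply their own.

Fitting (`CohortLogit.fit`) maximises the binomial log-likelihood via
Newton iterations (statsmodels' `Logit`), equivalent to iteratively
reweighted least squares. Odds ratios are exp(coefficient) with Wald 95%
intervals exp(β ± 1.96·se); p-values are two-sided Wald tests. Perfect or
quasi-separation raises `SeparationError` rather than returning divergent
estimates; the quasi-separation guard fires when any coefficient exceeds
15 on the logit scale, far beyond any plausible clinical odds ratio.

CRB-65 sums four indicator points: new-onset confusion; respiratory rate
≥ 30/min; blood pressure systolic < 90 mmHg **or** diastolic ≤ 60 mmHg
(one point even if both); age ≥ 65. Missing inputs raise — a partial
severity score would be misleading.

## Risk stratification and reclassification

Thresholds 0.025 and 0.20 bound the intermediate group on both sides:
low is p < 0.025, high is p > 0.20, and the boundaries themselves are
intermediate. With the published coefficients no covariate pattern lands
exactly on a boundary, so this convention is observationally irrelevant
for the shipped equations; it is documented for user-supplied models.

The reclassification table cross-tabulates old-model stratum (rows) by
new-model stratum (columns), separately for events and non-events, on the
patients complete for the **union** of both models' covariates, so both
margins describe the same analysed population.

ORI counts *every* upward move as correct for an event and every downward
move as correct for a non-event (including single-step moves through the
intermediate stratum), subtracts the incorrect moves and divides by all
analysed patients. NRI is the standard sum of the two per-group net
fractions. ORI weights each patient equally; NRI inflates the influence of
the rarer outcome class — with 30 events against 212 non-events the two
can disagree in sign, which is precisely why both are reported.

Percentages in reports are rounded half away from zero, one decimal for
prevalences and reclassification fractions, whole percents for shares;
underlying JSON always carries the unrounded fractions so no rounding
accumulates.

## Model evaluation

ROC curves come from a full threshold sweep (no vertex pruning) with
trapezoidal area; this equals the Mann–Whitney concordance probability
with half credit for ties, and the test suite asserts that equivalence
against a brute-force all-pairs count. Each biomarker is evaluated on its
own complete-case subset with its n reported, so biomarkers with different
missingness patterns are compared transparently.

The Hosmer–Lemeshow statistic groups patients into deciles of predicted
risk (tied probabilities stay together, so fewer groups can result),
sums (observed − expected)²/expected over both outcome classes and all
groups, and refers the result to χ² with (groups − 2) degrees of freedom —
the reference distribution appropriate for in-sample fitted probabilities.
For probabilities supplied from outside the fitting sample that reference
is anticonservative (the statistic is closer to χ² with g degrees of
freedom); calibration of externally derived scores should be judged
accordingly. Groups with a vanishing expected count are merged into a
neighbour with a warning.

Nagelkerke's R² = (1 − exp(2(ll₀ − ll₁)/n)) / (1 − exp(2·ll₀/n)) rescales
the Cox–Snell ratio to the [0, 1] range; it is exposed both standalone and
on fit results.

## Synthetic cohorts

**Fixture.** The deterministic 249-record cohort reconstructs a published
reclassification table: 242 complete records (30 events, 212 non-events)
plus one record missing a clinical variable and six missing CRP, all seven
non-events (forced: the table's 30 events already exhaust the cohort's
event count). Covariate patterns are assigned per stratum — e.g. the
8 events moving intermediate→high are (runny nose present, feels ill,
CRP > 30), the only pattern that makes that move. Where the table
under-determines the data (which of three patterns the intermediate
"stayers" occupy; the CRP indicator of high-stratum patients, which cannot
change their stratum; the observed fields of the excluded records) the
fixture uses one documented deterministic choice. Continuous CRP values
are constants on the correct side of 30 mg/l (10 and 80), vitals are
round typical values (age 56, RR 18, BP 120/80, saturation 97%), and
PCT/MR-proADM are left missing — only the CRP indicator enters any shipped
equation. `randomized_consistent_fixture(seed)` instead resolves every
under-determined choice uniformly at random; the test suite verifies over
many seeds that the reclassification table, ORI and stratum prevalences
are invariant, i.e. the reproduced results do not depend on unidentifiable
patient-level detail.

**Stochastic generator.** `simulate_cohort` draws independent Bernoulli
symptom indicators (defaults 0.69 runny-nose-absent, 0.28 feels-ill — the
fixture margins), a CRP>30 indicator (default 0.25, or pattern-conditional),
and the outcome from a configurable logistic equation (default: the
published CRP equation). Continuous CRP is log-normal truncated to the
side of 30 mg/l its indicator dictates (inverse-CDF sampling, exact);
PCT and MR-proADM are log-normal with outcome-conditional location shifts.
The standardized shifts default to CRP 1.2 > PCT 0.7 > MR-proADM 0.35
log-SD units — *conventions chosen to give the generator a known
discrimination ordering for tests, not estimates from any real cohort.*
Vitals are drawn from plausible primary-care distributions. All draws flow
from one seed; equal seeds give bit-identical cohorts.

What the generator does **not** emulate: correlated symptoms, age- or
season-dependent risk, measurement error in vitals, informative
missingness, microbiology, or treatment effects. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
generative model, not performance of the equations on real patients.

## Problem sizes and numerical choices

Parameter-recovery checks use 50,000 simulated patients (asymptotic
standard errors there make ±0.1 a comfortable bound for every
coefficient); bias-decay checks use 500 and 5,000; null-coverage and
calibration checks use 20 seeded replicates. The headline reclassification
results are exact integer arithmetic on 242 patients and run in
milliseconds. Logistic fits converge at statsmodels' default tolerance
within 100 iterations; fits are flagged `converged` from the optimizer
state. Probabilities at risk-group boundaries are resolved as documented
above; ROC ties receive half credit; report rounding is half-away-from-zero.

## Known limitations

* Multivariable odds-ratio tables from the original cohort, its
  Hosmer–Lemeshow and Nagelkerke values, and biomarker AUCs on real
  patients require the raw study data and are not reproduction targets;
  the statistics themselves are implemented and tested on synthetic data.
* No variable-selection routine is provided: the published equations are
  taken as printed, and `fit_logistic` exposes the building block a
  screening workflow would use.
* No continuous NRI, IDI, reclassification confidence intervals,
  penalized regression or internal-validation (bootstrap) machinery.
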