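# Methods

## The estimand and the models

The package studies associations between the number of rare diseases an
inpatient carries (0, 1, >1 — the exposure) and five outcomes: in-hospital
mortality, ICU admission, length of stay (LOS), ICU LOS, and 30-day
readmission.  The analysis unit is the patient, represented by one hospital
stay selected uniformly at random from the patient's stays; analyzing all
stays would over-weight frequently admitted patients, who are also more
likely to carry rare diseases.

Binary outcomes are fitted by maximum-likelihood logistic regression;
durations by ordinary least squares on the natural logarithm, whose
exponentiated coefficients are multiplicative effects (1.28 ⇒ +28%).  Every
model adjusts for age group (18–34 reference, 35–49, 50–64, 65–79, 80+),
sex (F reference), calendar year of discharge (continuous, centered at the
earliest year in the data — centering affects only the intercept), and the
count of distinct non-rare diagnosis codes (disease burden).  The
readmission model additionally adjusts for the previous-stay category
(0 / 1 / 2 / 3+ admissions in the prior 730 days) and LOS in days.
Confidence intervals are Wald-type with z = 1.96 throughout, which exactly
reproduces the unadjusted 2×2 intervals; no multiple-testing adjustment is
applied (per-model CIs only).

Degenerate designs are refused loudly: rank-deficient matrices, perfect
separation (detected via non-convergence or exploding standard errors,
after a deterministic L-BFGS retry of an oscillating Newton fit), and
non-positive durations reaching a log fit all raise.  Factor levels absent
from a cohort are dropped from the design rather than emitted as zero
columns.

## Matching semantics

Catalogue codes act as wildcards: catalogue code c matches patient code p
iff c is a prefix of p; the longest matching c wins; c is never truncated
to meet a shorter p.  Matching operates on canonical strings (uppercase,
dots stripped).  Consolidation replaces a complete set of child codes by
their parent; this intentionally *widens* matching for the bare parent code
itself (that is what the replacement is for) while leaving the match status
of all deeper codes unchanged — the invariant tests cover exactly that.
Within a stay, codes are deduplicated after normalization and counted as
distinct *matched entries*, so two codes for the same disease (D57.1,
D57.3 → D57) contribute one rare disease; distinct unmatched codes form the
non-rare burden covariate.

## The synthetic population

The generator emulates the structure of a large adult tertiary-care
inpatient cohort and draws outcomes from the very model families the
pipeline fits, so recovery of the configured effects by the full pipeline
(matching → selection → cohorts → fits) is a well-posed end-to-end check.

Defaults (all configurable through `SyntheticConfig`):

- 165,908 patients; a third multi-stay, with 1 + Geometric(p = 2/3) stays
  (support ≥ 2, mean 2.5).
- Rare-disease prevalence 0.115; among exposed patients, 2053/19104 carry
  more than one (the >1 group carries 2 + Poisson(0.4) distinct entries).
- Synthetic catalogue of 100 prefix-free 3–4-character codes on stems
  disjoint from the 2,000-stem non-rare code pool, so no pool code can ever
  match.  Half of all emitted rare diagnoses are child codes (one extra
  digit), and half of all longer codes are displayed with a dot, so the
  truncation and normalization paths are exercised by every dataset.
- Per-stay distinct diagnosis counts are 1 + NegativeBinomial(r = 3) with
  group means (4.65, 5.75, 8.9), giving group medians ≈ 4 / 5 / 8.
- Demographics by group follow the emulated study's margins (age-band
  weights and male fractions per exposure group); the joint age × sex
  distribution within groups is independent, a modelling choice since only
  the margins are published.
- True effects default to the emulated study's adjusted estimates —
  mortality ORs 1.80/2.78, ICU 1.64/2.23, readmission 1.57/1.64 for the
  1 / >1 groups, LOS factors 1.28/1.49, ICU-LOS 1.14/1.40 — together with
  its age, sex, year, burden, previous-stay and LOS-per-day effects.
  Baseline rates (mortality 0.022, ICU 0.110, readmission 0.048) are
  enforced by calibrating each model's intercept once, on the first-stay
  population of the unexposed group, so each generated outcome follows a
  single-intercept model of exactly the fitted form.  LOS is log-normal
  (reference median 5 days, σ = 0.70); ICU LOS conditional on admission is
  log-normal (reference median 1.2 days, σ = 0.60), and a stay is extended
  when a drawn ICU LOS would exceed it (rare; keeps ICU days ≤ LOS without
  touching the ICU model).
- Timelines: deaths truncate a patient's remaining stays (dead patients
  cannot be readmitted or return).  Each stay's 30-day readmission event is
  drawn from the logistic model and realized on the calendar: the gap to
  the next admission is ≤ 30 days after discharge for events, 31–365
  otherwise, and the cohort module's date-based derivation is asserted to
  reproduce the drawn events and previous-stay counts exactly.  When an
  event falls on a patient's last stay, a follow-up admission *without
  coded diagnoses* is appended: it marks the readmission date but is
  removed by the ≥ 1-diagnosis eligibility filter, so realizing an event
  never changes the patient's selection weights.  (Without this, appended
  stays dilute the selection probability of event stays and deaths interact
  with stay counts; simulation QA measured −2 to −7% bias on readmission
  odds ratios and +2 to +4% on mortality before the change, and no
  detectable bias after — residual death-truncation coupling is below 1.5%
  across 200 replicates, well within the recovery tolerance, and mirrors
  real timelines, where deaths genuinely end them.)
- About 1.2% of stays have their readmission information flagged unknown,
  missing at random; they are excluded from the readmission cohort.

What the generator does *not* emulate: realistic ICD-10 code frequencies,
within-patient outcome correlation beyond shared covariates, seasonal or
nonlinear calendar trends, transfers between units within a stay, and
out-of-hospital deaths.  Passing recovery tests therefore demonstrate that
the pipeline estimates what it claims under the stated model, not that the
model captures every feature of real hospital data.

## Simulation studies and their sizes

- **Parameter recovery**: 150 replicates of 60,000 patients, full pipeline
  per replicate.  Across replicates the median estimate of each of the ten
  rare-group effects must lie within ±5% of its configured value
  (equivalently |median log-ratio| ≤ log 1.05 ≈ 0.049; the Monte-Carlo
  standard error of each median is ≤ 0.011 at this size, so the check is
  sharp), and the Wald 95% CIs must cover truth at a pooled rate ≥ 93%.
  Coverage is pooled over the ten effects because a per-effect ≥ 93% bound
  at 150 replicates would fail by pure binomial chance ≈ 10% of the time
  per effect even at exact nominal coverage.
- **Null calibration**: 60 replicates of 40,000 patients with every effect
  set to 1 and identical demographics across exposure groups (otherwise
  group differences in age and sex make descriptive p-values legitimately
  non-uniform).  The size ensures ≥ ~11 expected events in the sparsest
  cell (deaths in the >1 group) so every model is estimable.  Checks: each
  effect's mean log-estimate within 4 standard errors of 0, and
  Kolmogorov–Smirnov uniformity of the baseline table's chi-squared
  p-values for the mortality and ICU rows.
- **Selection uniformity**: 10,000 reseeded draws of the one-stay-per-
  patient selection for a two-stay patient, chi-squared goodness of fit at
  α = 0.01.

## Numerical choices and edge cases

- Logistic fits: Newton with tolerance 1e-8, max 100 iterations; on
  non-convergence one deterministic L-BFGS retry (500 iterations); standard
  errors above 1e3 are treated as separation.
- 2×2 odds ratios require all cells positive; zero cells raise a named
  error rather than applying a silent continuity correction.
- Percentages of empty groups are reported as missing, never 0; the
  Kruskal–Wallis test is skipped (p = NaN) when all values are tied.
- Ages below 18 are rejected wherever an age group is derived; the 80+
  band is unbounded above.
- The 30-day readmission window is inclusive on both ends (admission on
  the discharge day through 30 days after); the previous-stay window is
  the 730 days strictly before admission.
- Chapter assignment uses the standard ICD-10 chapter ranges; codes in
  inter-chapter gaps (e.g. D49) report "unclassified".
- Every run derives per-stage seeds from a single top-level seed via
  `numpy.random.SeedSequence` with stable CRC-based stage tags; identical
  configuration and seed reproduce every output file byte for byte.

## Known limitations

- The 30-day readmission flag is computed from the stay table alone;
  admissions to other institutions are invisible, as are deaths after
  discharge.
- The catalogue shipped with the synthetic generator is a syntactic toy;
  real analyses must supply a curated catalogue table
  (`icd10_code,label[,source]`).
- Adjusted effect estimates from synthetic data characterize estimator
  behaviour, not real-world effect sizes.
- LOS values are generated strictly positive; real data with zero-day
  stays must be excluded or recoded upstream of the log-linear models, and
  the package refuses them loudly rather than guessing.
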