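# Methods

## Episode reconstruction

Dose records are calendar-day events (patient, date, medication, dose in
mg); time of day is not modelled because the gap rule is phrased in whole
days. Duplicate (patient, date, medication) rows are collapsed keeping the
maximum dose. For one patient sorted by date, the dose-free span between
consecutive dose dates is `next − last − 1` whole days; an episode ends
when that span reaches the disqualifying gap — 5 days for methadone, 6 for
buprenorphine/naloxone, both configurable via `GapRule`. "N days without a
dose" is read literally: a split requires `next − last ≥ N + 1`.

The gap that applies after any dose is that of *that dose's* medication:
the clinically relevant clock is days since the last dose of whatever the
patient was last on. When both medications are dosed on the same day the
larger gap applies (a tie the day-level model cannot otherwise resolve).
An episode's medication is the medication of its first dose; switches
within an episode neither split it nor are tracked further. `duration_days`
counts both endpoints, so a single dose is an episode of duration 1 —
retention is days *in* treatment and zero-length episodes cannot occur.
Episodes are right-truncated at `study_end` (later doses dropped with a
warning); an optional `study_start` truncation exists for cohorts whose
extract begins mid-treatment. Administrative loss to follow-up means the
last episode ends strictly before `study_end`.

The implementation is vectorized (numpy on day ordinals); its reference in
the test suite is a deliberately naive day-by-day scan, and the two must
agree exactly on randomized histories.

## Cascade stages

Longest retention (the maximum single-episode duration, not the sum across
episodes) maps to `[0,90) / [90,365] / (365,730] / (730,∞)` days. The
verbal stage labels overlap at 90 and 365 days; the half-open/closed
placement above is the simplest exhaustive, mutually exclusive convention
consistent with "less than 90 days" and "more than 2 years". One year is
365 days and two years 730; leap days are ignored. Yearly cascade tables
key on the year of *first* initiation. Display rounding is half-up: whole
percent in yearly cascade summaries, one decimal in characteristics
tables, two decimals for odds ratios.

## Covariates

* **UDS quadrants.** Per drug class (amphetamine-type stimulant, fentanyl,
  cocaine, cannabis, other opioid), positivity = positive / total tests
  over the whole study window (patient-level, not per episode). Bins are
  right-closed quarters: `p ≤ .25`, `(.25,.5]`, `(.5,.75]`, `(.75,1]`, so
  26% lands in the second bin as labelled. Patients with zero tests of a
  class sit at proportion 0 (first quadrant) with `n_tests = 0` kept as a
  flag — there is no separate "never tested" category.
* **Average monthly UDS** = distinct test dates ÷ (total days in treatment
  across all episodes / 30.4375). The fixed days-per-month constant makes
  the measure insensitive to calendar alignment.
* **Geography.** Rural ⇔ Rurality Index (RIO) score ≥ 40; Northern ⇔
  health-region code 13 or 14; four strata from the cross. Missing RIO or
  region code gives a missing label: such patients are excluded from (and
  counted against) the regional analysis only. Real postal-code geocoding
  is out of scope; a small synthetic postal-prefix lookup exists purely
  for interface tests.
* **Age groups** `<25 / 25–45 / 46–65 / 65+`, computed at first initiation
  from birth year; exactly-65-year-olds are placed in 46–65 (the labels
  alone leave 65 ambiguous).
* **Dose indicators.** Start dose = first dose of episode 1; peak = max
  dose over the patient's episodes of the starting medication. Medians of
  the *peak* dose are taken per medication over the cohort, and both
  `start_above_median` and `peak_above_median` compare strictly against
  that median peak (reading "start dose above-median peak dose" literally).

## Models

Stage membership is modelled as a baseline-category multinomial logit with
reference stage `< 90 days`. "Crude" means one single-covariate model per
covariate (standard epidemiological usage); "adjusted" enters all declared
covariates at once — by default sex, age group, region, starting
medication, attempts (continuous), average monthly UDS (continuous), five
UDS quadrant factors and the two dose indicators; initiation year is not
included. Estimation is Newton maximum likelihood (statsmodels MNLogit,
relative log-likelihood tolerance 1e-10, max 200 iterations); intervals
are Wald at level 1−α (default α = 0.05), OR = exp(β̂). Rows missing any
modelled covariate are dropped complete-case and counted; sex "missing" is
a bookkeeping category, not a modelled level.

For a single categorical covariate the model is saturated, so fitted crude
ORs must equal the contingency cross-product
`(n_ls · n_ref,0) / (n_l0 · n_ref,s)`; `crude_or_from_counts` implements
that closed form with the Wald interval
`exp(log OR ± z·√(Σ 1/cell))` and serves as the independent oracle (tests
require 1e-6 relative agreement). A zero cell makes the OR undefined and
the row is flagged, never continuity-corrected. Separation or a singular
Hessian is surfaced explicitly: flagged rows (`converged = False`, OR NaN)
by default, an exception in strict mode — never clipped estimates. The
characteristics report uses chi-square tests of independence for
categorical covariates and one-way ANOVA for continuous ones.

A known reconciliation note: published crude ORs for some covariates
(starting medication in particular) cannot be reproduced from the same
publication's printed contingency counts in either direction. The package
trusts the closed form; the sex-by-stage worked example, which does
reconcile, is the reference check.

## Synthetic cohort generator

The generator emulates the observed-dosing EMR structure: per patient, a
number of episodes (1 + Poisson(1.17), matching a mean of ~2.2 attempts),
lognormal episode lengths (median 400 days, σ = 1.5 — spreading patients
across all four stages with the long-retention mode dominant), daily
dosing with a per-day miss probability (default 0.10, standing in for
take-home doses since no dosing-frequency distribution is published), and
inter-episode gaps uniform on 7–90 days. Two structural constraints make
ground truth exactly recoverable: gaps are clamped to at least the
episode medication's disqualifying gap, and within-episode missed-dose
runs are capped at gap − 1 days (endpoints always dosed). Doses ramp
linearly from a start to a peak level (defaults 30→80 mg methadone,
8→24 mg buprenorphine, patient-level lognormal scatter) — deliberately not
a pharmacological titration model. UDS visits fall on dosed days at ~6 per
treatment-month with all five classes screened per visit at configured
positivity. Demographics: 77.6% methadone starts, 61.4/38.5/0.1% M/F/
missing sex, age ~ N(35.6, 10.7) clipped to [18, 85], region mix
4.3/17.9/3.4/74.4% with 14.5% missing geography. All randomness flows from
one `numpy` generator per call; identical (config, seed) is byte-identical.

`generate_stage_odds_cohort` is a separate harness for the regression:
independent Bernoulli(½) covariates, stages drawn from a specified
baseline-category logit, generating coefficients returned for recovery and
CI-coverage tests.

What the generator does *not* emulate — dose titration pharmacology,
medication switches, clinic-level clustering, seasonal initiation trends,
covariate-dependent retention (unless planted via the stage-odds harness)
and real geocoding — bounds what passing tests show: they validate the
pipeline's correctness (segmentation, staging, counting, estimation), not
the epidemiology of any real cohort.

## Problem sizes and numerical notes

Routine tests run at 30–300 patients; the cohort-scale exact-recovery
check uses 2,000 patients (~1.5M dose rows), the oracle suite 1,000
randomized histories, parameter recovery n = 50,000, and CI coverage 200
replicates of n = 5,000 — sizes chosen to give tight statistical checks at
interactive runtimes. Proportions use exact integer counts; half-up
decimal rounding is applied only at display. Degenerate inputs are
explicit: empty dose tables give empty episode lists, a patient with no
doses is outside the cohort, zero-test UDS classes are flagged rather than
NaN, and a single-patient cohort's dose indicators are False by the strict
median comparison.

## Limitations

Prescription vs dispensation is not distinguished; cumulative (rather than
longest-episode) retention is not offered; left-truncation at the study
start is available but off by default since the original design's choice
is unknown; adjusted-model results on synthetic data depend on planted
effects and carry no clinical meaning.
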