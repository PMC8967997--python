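# Methods

This note records the modelling choices, conventions and limitations of the
package, in the order the pipeline applies them.

## Cohort construction

A patient enters the cohort through an index emergency-department (ED) visit
in the target calendar year.  Heart failure is recognised by ICPC-2 code K77
in the ED record, or by ICD-10-CM codes with prefixes I11.0, I13.0, I13.2,
I50 in the diagnoses of the hospitalization linked to that visit; hospital
codes count only when flagged present on admission (POA).  Codes are
uppercased and dot-stripped before prefix matching, so both ICD-10-CM
dialects (`I50.9` / `I509`) match.

*Classification.* HF at position 1 → primary HF (pHF); HF only at a later
position → secondary HF (sHF).  A hospitalization whose only HF codes lack
POA is new-onset HF and excluded; an ED K77 without a defined position makes
the patient unclassifiable and excluded.  When a patient is admitted and both
the ED and the hospital record would classify, the hospital record wins
(hospital discharge coding is the richer source); ED-only patients are
classified from the ED record.  This precedence is our interpretation — the
source registries do not state one.

*Anchoring and linkage.* The first qualifying ED visit of the year is the
index; an ED visit with disposition ADMITTED links to a hospitalization
starting on, or one calendar day after, the ED end date (midnight-crossing
admissions).  Both rules are interpretations where the registry conventions
are unstated.  Patients who die in the ED are kept as a separate arm with no
follow-up.

## Daily clinical states

Day 0 is the index ED arrival and the window is a fixed 30 or 365 days per
patient, so total patient-days equal n × horizon exactly.  Event-rate
cut-offs, by contrast, are anchored at the index *discharge* (hospital
discharge if admitted, ED discharge otherwise) — the window and the cut-off
anchors intentionally differ.

Each day takes the highest state in the hierarchy `DEAD >
IN_HOSPITAL_INDEX > IN_HOSPITAL_READMISSION > IN_ED_INDEX > IN_ED_REVISIT >
DAY_HOSPITAL > OUTPATIENT_VISIT > AT_HOME` among the episodes covering it.
Conventions:

- A hospitalization occupies days `start .. end−1` (half-open, minimum one
  day), which makes occupied days equal length of stay = discharge −
  admission.  ED, day-hospital and outpatient episodes occupy every calendar
  date they touch; a same-day ED visit is one ED day.  The dates-touched ED
  convention is chosen because a zero-based difference cannot produce mean ED
  stays above one day, which real ED data show.
- DEAD persists to the horizon; days after death count as days dead, never as
  utilization.
- The share of time alive out of hospital spent at home is
  `days_home / (horizon − days_dead − days_in_hospital)`, defined as 1 when
  the denominator is 0.  Whether ED/day-hospital days should also leave the
  denominator is ambiguous; they do not here (flagged as an interpretation).

Occupancy matrices are validated to be row-stochastic (each day sums to 1
within 1e-9) with a non-decreasing DEAD fraction.

## Outcome statistics

Event rates are crude cumulative incidences — patients with ≥1 qualifying
event divided by all patients of the stratum, with deaths retained in the
denominator and no competing-risk adjustment.  Utilization events count
episode starts in the half-open window `(discharge, discharge + cutoff]`;
mortality counts any death on or before `discharge + cutoff`, so in-hospital
deaths are inside every mortality cut-off (the 1-year figure is day-365
status, not a KM estimate).  In-hospital mortality is additionally computed
from the index hospitalization's disposition.

Survival uses the Kaplan–Meier product-limit estimator and the two-sample
log-rank test (lifelines); in-hospital deaths enter at duration 0 and
survivors are censored at the horizon.  Baseline comparisons dispatch to
Student's t (equal variances), Mann–Whitney U, or chi-square without
continuity correction; the measurement scale is declared by the caller, no
normality test is run.  Significance is two-sided at 0.05 with no
multiplicity correction.

## Costing

Full-cost scheme per episode: directly imputable items (DIRECT), unit-priced
service-catalog items (CATALOG, with `amount = quantity × unit_cost`), and a
share of non-imputable hospital costs (RESIDUAL).  The residual imputation
weight is per-diem (occupied days); the real accounting criteria are
proprietary, so per-diem is an explicit, configurable stand-in.  Monetary
arithmetic runs at cent precision with largest-remainder reconciliation, so
conservation — Σ items = Σ episode totals = Σ status totals = group total —
is exact, and `mean_cost_per_patient_day × horizon = mean_cost_per_journey`
holds identically under the fixed-horizon convention.

Journey aggregation attributes each costed in-window episode to one clinical
status (ED, index hospitalization, readmission, day-hospital); an episode
with at least one in-window day is charged in full.  Outpatient visits carry
no ledger cost, matching cost tables that split totals over ED, hospital and
day-hospital only.  Mean days at ED / in hospital are computed over **all**
patients of the group, not only users of that resource (the alternative
reading is noted as ambiguous).  Daily cost curves spread an episode's total
uniformly over its occupied in-window days — no intra-episode cost profile is
modelled.

## Synthetic generator

The generator emulates one calendar year of ED-anchored HF activity and is
the package's test bed; its defaults are the published rates of a
single-centre 2018 cohort (group sizes 1029/1257 hospitalized and 434/363
discharged home, 15 ED deaths; mortality, readmission, re-ED, LOS,
outpatient and cost parameters as listed in `coherent/params/defaults.yaml`).

- **Death**: two-piece constant hazard on (0, 30] and (30, 365] days after
  index discharge, solved in closed form from the 30-day and 1-year
  cumulative mortalities; hospitalized patients first face a Bernoulli
  in-hospital death.  This reproduces an "early divergence, then parallel"
  survival contrast between groups without inventing a parametric family.
- **Readmission / re-ED**: time to first event has its own two-piece hazard,
  calibrated by root finding so that the *crude* incidence in the presence of
  the competing death hazard matches the target 30-day and 1-year
  probabilities (targets conditioned on surviving the index stay).
  Subsequent events recur at the late-piece hazard, and readmissions never
  overlap.  Bias checks at n = 20,000 show all recovered rates within Monte
  Carlo error of their targets.
- **LOS**: log-normal matched to median 8 and IQR 6–12 on the log scale,
  rounded to whole days (min 1).  The same law is used in both groups.
- **Costs**: log-normal per episode class, moment-matched to the printed
  mean/SD; split into direct (45%), catalog and residual items at cent
  precision.
- **Outpatient visits**: negative-binomial yearly count (moment-matched),
  spread uniformly over post-discharge days alive outside hospital;
  day-hospital visits are Poisson with the per-patient-year episode rate.
- **Streams**: every patient draws from
  `SeedSequence(seed, spawn_key=(cell, i))`, so enlarging one group never
  perturbs other patients and a fixed seed is byte-reproducible.

What the generator does **not** emulate — and therefore what passing tests do
not show about real data: correlation between comorbidity, LOS, cost and
death (independence given the group is assumed); diagnostic-code diversity
beyond what classification needs; seasonal admission patterns; recurrence
*counts* beyond the first event (only first-event probabilities are
calibrated, so total episode volumes per journey — and hence per-journey cost
totals — undershoot the real cohort's, even though per-episode cost means
match); and coding errors or missing data.  Group sizes for the ED-death arm
(8/7) and several ED-home-arm parameters (outpatient and day-hospital
intensity) are unreported in the source material and set to plausible values
once.

## Numerical choices

- Dates are ISO-8601 calendar dates; all interval logic is whole days.
  Episode intervals are closed on dates at the I/O layer; the half-open
  hospital-day convention is applied by the state engine only.
- Tie-breaks are the fixed state hierarchy; a same-day ED visit + admission
  renders as hospital.
- The log-rank test is undefined without events and raises; identical groups
  give statistic 0, p = 1.
- Residual allocation with all-zero weights raises rather than splitting
  evenly.
- Occupancy of an empty cohort, event rates on an empty stratum and cost
  summaries of a zero-cost group are contract errors, not NaNs.

## Problem sizes in the test suite

Property suites run on generated cohorts of 1,000 journeys; calibration
recovery uses n = 5,000 per hospitalized group at a fixed seed with 3
binomial-SE bands; the acceptance script regenerates the full published-size
cohort (3,098 patients).  These sizes make sampling error small relative to
the tested tolerances while keeping the default run fast.
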