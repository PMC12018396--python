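# Methods

## Study design implemented

The package implements a new-user ("incident user") cohort design on
pharmacy-claims data. The data extraction window is December 2019 –
November 2022; cohort entry is the first fill of the drug under analysis
(the *index drug*) between December 2020 and November 2021, so that every
patient has a full 180-day look-back and a full 365-day follow-up inside
the extraction window. Internally every date is an integer day offset from
the extraction start (diagnoses are kept at calendar-month granularity, as
claims carry them), and all interval logic is exact integer arithmetic on
half-open `[start, end)` intervals.

Inclusion requires, in order: a PD diagnosis (ICD-10 G20) in the same
calendar month as entry; oral levodopa filled on the entry date and at
least once in the 180-day look-back; no index-drug fill in the washout
window (the look-back by default); and age ≥ 40 at entry. Exclusions:
enrollment not covering `[entry − 180, entry + 365]`, and any diagnosis of
a differential condition (secondary/atypical parkinsonism, normal pressure
hydrocephalus, schizophrenia). Each criterion's exclusions are recorded in
an attrition table whose counts telescope.

Patients qualifying in several drug cohorts enter the all-drugs cohort at
their earliest entry only; several index drugs newly filled on that same
day form a *combination index drug*, whose covered period is the
intersection of the constituents' covered periods.

### Conventions the data do not dictate

Decisions the source definitions leave open, fixed here once and exposed in
`StudyConfig` where configurable:

* **Gap semantics.** Gap = next period start − previous period end on
  half-open intervals, so a refill on the exact day supply runs out has gap
  0, and a 1-day supply never refilled yields a persistent-period length of
  1. A gap exactly equal to the threshold counts as discontinuation
  ("persistent" requires the gap to be *strictly less than* 30 days). The
  discontinuation day is the end of the last covered period before the
  qualifying gap; under these interval conventions "last covered day" and
  "gap start" coincide.
* **"Last day of filling".** The gap rule is anchored at supply end, not
  the fill date: a fill-date reading would make any supply of ≥ 30 days
  self-discontinuing.
* **No stockpiling.** A fill's coverage is truncated at the next fill of
  the same drug. Early refills therefore never bank supply; this is what
  lets MPR (which sums raw dispensed days) exceed 1 while PDC cannot.
* **Discharge imputation.** A fill flagged as dispensed at hospital
  discharge with a recorded 1-day supply is imputed to the days until the
  next fill of the same drug, capped at 30; with no later fill the cap is
  used (the only bounded choice). Imputations are counted in a per-patient
  audit column.
* **PDC windows and eligibility.** PDC is computed only for patients with
  ≥ 2 fills of the index drug (same-day duplicate fills are collapsed
  first). The numerator counts covered days strictly before the start of
  the last covered period in the window, matching the denominator's "day
  before the start" endpoint, so PDC ≤ 1 always. An undefined PDC (< 2
  in-window fills, or all fills on one day) is reported as missing, never
  as 0 or 1. For combination indexes the anchors are the intersected
  covered-period starts and "fills" are days on which every constituent was
  filled.
* **Exclusion-diagnosis window.** Differential diagnoses are checked over
  the whole extraction window (conservative for diagnostic certainty), not
  only the look-back; configurable.
* **Quartiles.** Linear interpolation between order statistics (the shared
  default of numpy/pandas and R's type-7 quantile), so five-number
  summaries are reproducible across ecosystems.
* **Age** is entry year − birth year: claims rarely carry full birth
  dates.
* **Doses.** Fills carry no strength, so daily dose enters through the
  catalog: each drug's `led_factor` is its levodopa-equivalent dose in
  mg/day at typical maintenance dosing, and strength-specific levodopa
  products (150–600 mg/day) encode the dose distribution. The shipped
  factors are plausible defaults for synthetic data, not a validated
  conversion table; a real analysis must supply its own.
* **Concomitant drug count**: distinct non-N04 ATC second-level classes
  filled at entry or in the look-back, dropping classes with < 14 total
  days supplied. The anti-PD drug count is the number of distinct
  non-levodopa N04 drugs filled on the entry date (the index drug
  included, the levodopa backbone not).

## Statistical estimators

* **Kaplan–Meier** curves for time to discontinuation use the
  product-limit estimator via `lifelines`, with discontinuation as the
  event and patients persisting through follow-up censored at 365 days.
* **Modified Poisson regression** fits a Poisson GLM with log link to the
  binary outcome (persistent yes/no; good adherence yes/no) via
  `statsmodels`, with HC0 sandwich standard errors — the robust-variance
  correction that makes the misspecified Poisson likelihood yield valid
  risk-ratio inference. 95 % CIs use `exp(β ± 1.96·SE)`. Rows with missing
  covariates are dropped and counted; fitted risks above 1 (a known
  pathology of the method) are reported in diagnostics, never clipped.
  Dose covariates enter per 100 mg so their risk ratios are legible;
  counts and age enter per unit.
* **Sensitivity variants** each change exactly one element of the primary
  analysis (asserted on the resolved configuration): 15-day gap threshold;
  washout extended back to the extraction start; PDC denominator anchored
  in the follow-up window; MPR in place of PDC.

## The synthetic claims process

The generator emulates the study population — elderly patients on a
levodopa backbone newly adding one adjunct — with known ground truth. Per
patient: age ~ Normal(77.2, 7.0) truncated at 40; male with probability
0.436; entry uniform over the entry year; G20 in the entry month plus an
earlier month; comorbidities as independent Bernoulli flags (depression
14.3 %, dementia 19.4 %, liver failure 15.6 %, renal failure 5.6 %)
emitting ICD-10 records; ~5 concomitant ATC classes refilled monthly;
0–3 additional *ongoing* anti-PD adjuncts whose fills start a year before
entry (so they are never new users of those drugs); and one index drug
drawn from a 17-drug menu whose weights and hazards span the observed
adjunct landscape (pooled 1-year persistence ≈ 45 %, per-drug ≈ 29–60 %).

The refill process is the part with a closed form. Fills recur at supply
exhaustion (30-day cycles by default) plus integer jitter
`round(N(μ, 3))`, where μ = 0 for most patients and 4–12 days for a "late
refiller" minority (8 %) — the generator's model of heterogeneous
adherence. At each refill decision the patient stops for good with
probability *h* (per-cycle hazard, multiplied by 1.15 per extra anti-PD
drug and 1.10 under depression). With 30-day cycles, zero jitter and no
hospitalizations, the 30-day-gap rule over 365 days is failed exactly when
one of the first 11 refill decisions fails, so 1-year persistence is
`(1 − h)¹¹`; `persistence_probability()` computes the general cycle-mix
form by recursion, and the consistency tests verify the pipeline
reproduces the realized truth patient by patient under those conditions.
Hospitalization (15 %/year, stays of 5–21 days) displaces the in-stay
refill to the discharge day and registers it as a 1-day supply with
probability 0.7, exercising the imputation rule; the true supply is kept
in the ground truth.

What the generator does **not** model — and hence what passing tests do
not establish about real claims: correlated comorbidity structure, dose
titration, switching between adjuncts, seasonal prescribing, enrollment
churn, miscoded diagnoses, or any causal link between covariates and
adherence behavior beyond the two hazard multipliers. Results on synthetic
data validate the *estimators*, not the substantive findings of any real
population.

## Problem sizes and determinism

The shipped analyses and the acceptance script use 2,000-patient cohorts,
where the binomial SE of a persistence rate is ~1.1 points and a full
pipeline run takes well under a minute; the estimator-validation tests use
up to 2,000 patients per hazard and a 500-replicate coverage simulation at
n = 5,000. One integer seed drives a single PCG64 stream for the
generator, so equal seeds give byte-identical claims files and reports.

## Known limitations

* Claims measure dispensing, not ingestion; "adherence" here is adherence
  to refilling.
* The per-drug hazards are constant per refill cycle (geometric dropout);
  real discontinuation hazards fall with time on drug.
* Combination-index adherence uses the intersected covered periods; other
  defensible readings (e.g. union, or per-constituent PDC averaged) are
  not offered.
* Charlson comorbidity scoring and levodopa-equivalent conversion are
  accepted as user-supplied inputs, not computed.
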