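# Methods

## Scope and data model

The package operates on five person-level tables (persons, hospital diagnosis
contacts, prescription redemptions, procedure events, healthcare contacts)
that mirror the joint structure of national health registers used in
pharmacoepidemiology. Dates are ISO 8601 and all interval arithmetic is in
whole days. Costs are carried in EUR; a `cost_dkk` input column is converted
at 7.47 DKK/EUR on load. ICD matching is prefix-based after dot-stripping
("F322" matches the configured "F32.2"), with a leading `D` stripped when
followed by a letter (the Danish register dialect, e.g. "DF32.1"); legacy
ICD-8 exclusion entries are matched on their printed numeric strings, with
single-character `x` wildcards and ranges in steps of .10. Validation is
total: any malformed row produces an error naming the table and row.
Diagnosis dates are bounded to [1969-01-01, study end + 730 d] rather than the
study years themselves, since prior exclusion diagnoses legitimately predate
the study period and injected post-index diagnoses can fall shortly after it.

## Cohort definition

The incident cohort is each person's earliest hospital MDD contact
(severity-coded ICD-10 lists: mild F32.0/F32.8/F32.9/F33.0/F33.4/F33.8/F33.9,
moderate F32.1/F33.1, severe F32.2/F32.3/F33.2/F33.3) during 1996–2015, at
age ≥ 18 (completed years at diagnosis). Only the 13 severity-listed codes
qualify; other F32/F33 subcodes (F32.4–F32.7, F33.5–F33.7) are not
severity-classifiable and do not enter the cohort. Same-day ties between MDD
codes are broken by severity rank (severe > moderate > mild), then
lexicographically — the paper-silent case needed a deterministic rule, and
ranking by severity is conservative for severity stratification. Persons with
a bipolar, other/persistent affective, schizophrenia-spectrum or dementia
diagnosis on/before the MDD date are excluded ("prior" includes same-day
codes, since within-day events cannot be ordered), as are persons with
prevalent TRD (second shift on/before diagnosis). Anxiety (F40–F48) and
substance-abuse (F10–F19) flags over the 5 years before the index date are
computed for descriptive tables only.

## Treatment shifts and TRD

Within [MDD − 365 d, MDD + 365 d], the first new-treatment event (first
in-window redemption of each distinct antidepressant substance at full ATC
level 5, or first in-window ECT) is treatment initiation; each subsequent
distinct new-treatment event is one shift. TRD is defined at the second
shift; the index date is that event's date. Design choices where the
operational definition is genuinely open:

- **Re-initiation.** Default counts only first-time substances (A→B→A is one
  shift); `re_initiation_counts` switches to change-from-previous semantics
  (two shifts). Returning to a previously failed substance is clinically
  ambiguous; new-treatment semantics follows prior registry cohort work.
- **ECT as first treatment** is initiation, not a shift (`ect_always_shift`
  overrides): a shift presupposes existing therapy.
- **No duration or dose adequacy** is enforced; `min_days_between_shifts`
  (default 0) optionally suppresses shifts closer than a given gap to the
  previous counted event, reproducing ≥4-week sensitivity analyses.
- **Pre-window history is ignored**: only in-window events define initiation
  and shifts.
- Shift *kind* labelling (switch vs add-on) uses a 90-day activity window —
  a substance counts as ongoing therapy if redeemed within the preceding 90
  days. The label does not affect TRD status.
- Same-day distinct new treatments each count once, ordered lexicographically.

`shift_oracle` re-derives the shift sequence by explicit day-by-day replay and
is kept deliberately independent of `detect_shifts`; the test suite proves
equality on an exhaustive grid (all sequences of ≤ 4 events over 3 substances
plus ECT on a 5-date grid, both semantics — 10,626 sequences each).

## Matching and follow-up

Cases are matched 1:2 to non-TRD controls exactly on age group, sex,
diagnosis-year group and severity. Non-TRD means never algorithmically TRD
within the person's own window, not merely non-TRD at the case's index date.
Cases are processed in seeded random order; controls are drawn uniformly
without replacement from the unused stratum pool; a single remaining control
forms a 1:1 set by default (`allow_partial_match`). Cases and pools are
sorted by person id before seeded shuffling, so a fixed seed yields a
byte-identical matched cohort regardless of input row order. Each control's
index date is its own MDD date plus the case's diagnosis-to-index offset.

Conditioning follows matching (match, then restrict): any member with death,
emigration, or an exclusion diagnosis on/before index + 365 d is removed; sets
losing their case or all controls dissolve. A separate pre-index-year
completeness flag would be vacuous in this data model — death/emigration
on/before index + 365 d already subsumes all earlier events and there is no
immigration/late-entry process — so none is provided.

## Outcome windows and aggregation

Pre-index window [index − 365 d, index − 1 d]; post-index window
[index + 1 d, index + 365 d]. The index day belongs to neither window because
the TRD-defining redemption is itself a cost event and would mechanically
inflate the post year (`include_index_day_in_post` overrides). Visits and
hospitalizations count at their start date; bed days are in-window nights,
clipped at both window edges, with a floor of one bed day for completed
same-day inpatient stays (admission/discharge-day conventions differ across
registries; nights + floor 1 is the stated convention here). Costs use the
recorded per-event EUR amounts by default, or a fixed price per
sector × contact type × admission mode (`cost_mode: fixed`); the shipped
price table is synthetic but plausible. The psychiatric cost category
includes hospital psychiatric services, private psychiatrist and psychologist
services, and psychiatric home visits; medicine costs are total transaction
prices split by ATC prefix (N06A antidepressants; N05A/N05B other
psychiatric; remainder other). Additivity (acute + elective = overall;
category sums = totals) holds per patient by construction and is tested.

## Two-part model

Part 1 fits a log-link Poisson GLM to the binary any-use indicator with HC0
sandwich variance (optionally cluster-robust on matched set,
`cluster_by_set`), reported as (RR − 1) × 100 with a Wald 95% CI formed on
the log scale. The default part-1 design is group-only (unadjusted); the
exact-matched design makes covariate adjustment largely redundant, and
`adjust_part1` adds the four matching covariates when wanted. With a
group-only design the fit equals the crude risk ratio, and its sandwich SE
equals √((1−p₁)/(n₁p₁) + (1−p₀)/(n₀p₀)); both identities are asserted to
float precision against closed forms. If the GLM fails to converge, the
unadjusted path falls back to that closed form with a logged notice. Zero
users in an arm yields a flagged (NaN) estimate, never a crash.

Part 2 restricts to users (outcome > 0, so no log offset is needed) and fits
OLS of ln(outcome) on group plus the matching covariates as categoricals,
back-transformed to (GMR − 1) × 100. Covariates with a single observed level
among users are dropped to keep the design full rank. No multiplicity
correction is applied across the outcome grid; per-outcome p-values are
reported as-is.

Stratified analyses (severity, diagnosis-year group) report per-stratum user
fractions and crude RRs with robust CIs; strata with an empty arm or zero
users are omitted with a log entry. The baseline table reports counts
(percent, one decimal) per group with Pearson Chi² p-values (no continuity
correction); expected cells < 5 flag the variable as small-sample.

## Synthetic registry

A latent per-person resistance flag (default prevalence 0.158) drives both
switching and HRU intensity. Realistic-mode defaults: 62% women; age
distribution (0.12, 0.33, 0.28, 0.22, 0.05) over the five matching bands;
severity (0.55, 0.32, 0.13); ~12 redemptions at a mean 30-day interval with
per-redemption switch hazard 0.35 (resistant) vs 0.06 (non-resistant); ECT in
20% of resistant severe patients; contact counts gamma-Poisson
(negative-binomial, dispersion α = 1) with annual non-resistant rates near
published non-TRD utilization means (e.g. GP 7.5/yr, psychiatric outpatient
4/yr, psychiatric acute hospitalization 0.10/yr) and resistance multipliers of
roughly 2 for psychiatric categories, 1.0 for somatic, 1.2 for GP; geometric
hospitalization durations (mean 7 nights); costs = fixed price × optional
lognormal noise; annual death/emigration/exclusion-diagnosis hazards
0.02/0.01/0.01 injected after the index period to exercise conditioning.
Events are generated over [MDD − 365 d, MDD + 730 d] with uniform dates, so
any 365-day window has the configured annual mean. One RNG substream per
table (`SeedSequence.spawn`) makes output byte-identical for a fixed seed.

Calibration mode is the regime used for parameter-recovery and type-I
experiments: resistant persons redeem three distinct substances at days
0/60/120 after diagnosis (exactly two shifts; index = MDD + 120 d),
non-resistant persons redeem one substance twice, and competing events are
off, so algorithmic TRD equals the latent flag exactly and the
diagnosis-to-index offset is constant. Per-category rates are a lean 0.25/yr
(GP 1.0/yr) with Poisson counts. `any_use_probs` replaces a category's count
generation with a Bernoulli any-use draw in the post-index year — the
binomial oracle for the any-use part.

What the generator does *not* emulate: correlated comorbidity beyond the
single latent flag, calendar trends, realistic national incidence, seasonal
prescription refill behaviour, or DRG-style costing. Passing tests therefore
certify the algorithmic pipeline and estimator calibration under the stated
generative assumptions, not real-world effect sizes.

## Verification experiment sizes

Chosen as the package's own experiment design: parameter recovery uses
~2,000 cases matched 1:2 (6,000 simulated persons, resistance prevalence 1/3,
any-use 0.2 vs 0.4) over 200 replicates in the test suite (60 in the
acceptance script), asserting the mean recovered change within [85%, 115%]
and ≥ 90% CI coverage; a single replicate's robust SE is ≈ 8 percentage
points at this design, so the band is checked on the replicate mean. Type-I
error uses ~500 cases per replicate over 400 replicates (200 in the script),
asserting rejection at p < 0.05 within [0.03, 0.08].

## Known limitations

- The shift algorithm treats the full ATC level-5 code as substance identity;
  combination products or the same substance at different strengths under
  different codes count as distinct.
- Bed-day and index-day conventions are stated choices; registries differ.
- The fixed-price table is synthetic; recorded-cost mode is the default.
- Unmatched cases are logged but not re-matched with relaxed criteria.
- The amount part assumes approximate log-normality among users; with heavy
  point masses just above zero the GMR interpretation weakens.
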