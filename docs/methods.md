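# Methods

This note documents the data model, the synthetic-claims generator, the cohort
and matching procedures, the outcome conventions, and the numerical and design
choices behind them. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

A claims extract is seven delimited tables (UTF-8, comma-separated, ISO-8601
dates): persons, enrollment intervals, diagnoses, procedures, drug
dispensings, itemized costs and sick-leave days. German outpatient care is
billed per calendar quarter; the tables nevertheless carry day-resolution
dates throughout, and quarter identity is derived only where a rule needs it
(the two-quarter confirmation rule; the one-billed-contact-per-physician-per-
quarter visit convention). Outpatient diagnoses carry a confirmation qualifier
with the German G/V/A/Z semantics, named abstractly
(`confirmed`/`suspected`/`excluded`/`status_post`); only `confirmed` counts
toward any rule. Inpatient diagnoses carry no qualifier. Costs are recorded
EUR amounts; no re-pricing, deflation or DRG re-grouping is attempted.
Sick-leave days are a separate attribute stream (`sick_leave.csv`) rather than
a cost category. Aid and remedy cost items carry a product-group code because
they double as hdPS dimensions.

Code lists (bone-metastasis code C79.5, solid-tumor range C00–C76, per-type
SRE diagnosis/procedure codes, BTA ATC codes, named tumor subgroups) live in
an editable `CodeListConfig` (YAML round-trip). The SRE defaults
(M49.5\*/M84.4\* pathological fracture, G95.2\* cord compression, OPS-like
5-78\*/5-79\* surgery and 8-52\* radiation prefixes, ATC M05BA\*) are
documented placeholders in the shape of German coding practice and must be
reviewed against the local catalogue before any real-data use.

## Study windows and eligibility

Data cover 2010-01-01..2018-06-30; incident diagnoses are accepted in
2011-01-01..2017-06-30, leaving a full washout year before and at least twelve
months of potential follow-up after every index date. The eligibility chain
(each stage is an attrition row):

1. **Incident BM** — one inpatient C79.5, or two confirmed outpatient C79.5
   in two *different calendar quarters* (no maximum gap). The incident date is
   the inpatient date or the first of the confirming pair, whichever is
   earlier; first-contact dating maximizes washout integrity. Any BM-coded
   evidence before the inclusion window start disqualifies (prevalent case).
2. **Solid tumor** — at least one inpatient or confirmed outpatient C00–C76
   diagnosis within 12 months before to 3 months after the BM date (calendar
   months via date offsets, not 365/4-day approximations).
3. **Age ≥ 18** at the BM date (age in completed years, days/365.25). Age at
   the index date is what baseline tables report.
4. **Continuous enrollment** — after merging abutting intervals (gap
   tolerance 0 days), a single interval must cover BM − 12 months through the
   person's data end (death or 2018-06-30).
5. **Group and index** — SREs are detected between the BM date and the
   inclusion end from configured diagnosis codes (inpatient any, outpatient
   confirmed) and procedure codes, prefix-matched dotless. The first SRE is
   the SRE-group index; several SRE types on that day classify as `multiple`.
   Non-SRE patients draw `BM + offset`, the offset resampled with replacement
   from the SRE group's BM-to-index offsets (offsets, not calendar dates, so
   the index can never precede BM); up to 100 redraws until the date falls
   inside [BM, person's data end], else the person is excluded and counted in
   attrition. Random index assignment happens before matching.
6. **BTA naivety** — a BTA dispensing strictly before BM, or on/after BM but
   strictly before the index date, excludes; a BTA on/after index is kept and
   later censors follow-up.

Tumor subgroup = named 3-character group (C34 lung, C61 prostate, C50 breast,
C64 kidney, C67 bladder) of the latest solid-tumor code dated on/before index;
two different named groups on that latest date, or only unnamed codes, give
`other`.

## Comorbidity and baseline covariates

All baseline covariates use the strict half-open window
[index − 365 d, index). The Charlson Comorbidity Index uses the Quan ICD-10
condition mapping with the original weights, hierarchies (metastatic disease
supersedes malignancy, severe liver supersedes mild, complicated diabetes
supersedes uncomplicated) and age points (one per decade from age 50, capped
at 4). This variant is a deliberate choice: with every cohort member carrying
the metastatic weight of 6 plus age points, mean scores land near 11, the
plausible range for this population; the mapping is an editable table and the
variant is therefore configurable, and absolute CCI levels are not asserted
anywhere. Hospitalizations count by admission date in-window; GP visits as
distinct billed (physician, quarter) contacts; sick-leave days are summed.

## hdPS matching

Within each of seven dimensions (inpatient dx, outpatient dx, dispensings,
outpatient treatments, inpatient treatments, aids, remedies), codes occurring
in ≥ 1% and < 100% of cohort persons during baseline become candidates. Each
candidate expands into up to three binary recurrence covariates: occurred at
least once; at least the median of nonzero per-person counts; at least their
75th percentile (linear-interpolation percentiles; duplicate thresholds
collapse onto the lowest level). Covariates are ranked by
`|log((p₁+c)/(p₀+c))|` — prevalence in exposed vs unexposed with a 0.5-count
continuity correction — and the top 100 per dimension are kept (≤ 700 total;
a pooled top-700 and a Bross bias ranking with death-within-follow-up as
proxy outcome exist behind flags; the exposure-association default was chosen
because the study's outcomes are rates and costs, not a single binary event).

The propensity model is logistic regression of SRE status on the selected
covariates plus forced covariates, all standardized, with a small ridge
penalty (λ = 10⁻⁴) that keeps coefficients finite under separation; scores
are strictly inside (0, 1). The forced set is age, sex, sick-leave days and
the CCI, **plus** the two baseline utilization counts (hospitalizations, GP
visits) that the matched baseline table balances — raw counts carry intensity
information that binary recurrence indicators coarsen away, and forcing them
measurably improves confounder control in the simulator's world.

Matching is 1:1 greedy nearest neighbor without replacement on the
probability scale with a hard caliper of 0.01 (a logit-scale caliper is a
config alternative). Treated persons are processed in a seeded random order,
making order-dependence measurable across seeds; for a fixed order the greedy
result is exactly the lexicographic minimizer of the per-step distance
sequence, which is what the exhaustive small-instance oracle in the test
suite verifies. Balance is reported before and after matching as percent
standardized differences (binary covariates use p(1−p) variances; two
zero-variance samples report 0 when means agree and signed infinity
otherwise) with chi-squared / Welch-t / Mann-Whitney p-values chosen by
variable type.

## Outcomes

Follow-up runs from index to the earliest of death, first BTA dispensing
on/after index, first SRE strictly after index (non-SRE group only), or
2018-06-30; ties resolve death > BTA > later SRE > end of data; the minimum
follow-up is one day and person-years are days/365.25. Events dated inside
[start, end] count. Hospitalization days are discharge − admission (night
count) truncated to the follow-up interval; admissions count by admission
date; SRE-related admissions are those whose stay covers an inpatient
SRE-coded diagnosis. Outpatient visits deduplicate to one billed contact per
(person, physician, quarter) — the quarterly accounting makes repeat visits
to the same physician unobservable. Cost categories are hospitalization,
outpatient visits, rehabilitation, prescriptions, and aids and remedies
(combined); the total is their exact sum, an identity asserted in the tests.

All rates are pooled group totals over pooled person-years. Rate-ratio
p-values come from a seeded patient-level bootstrap (default 2,000 resamples;
500 in the pipeline default): persons are resampled within each group, the
log rate ratio recomputed, and the two-sided p-value read off by
CI inversion with a +1 continuity term. A bootstrap avoids the Poisson
assumption that pooled cost totals grossly violate; its null calibration is
checked at the 5% level over 200 replicates in the acceptance suite (group
size 150, compound Poisson–log-normal costs — a regime where the bootstrap is
expected to be near-nominal; much smaller groups with extreme skew would
reject somewhat above nominal). Zero denominators leave the ratio undefined
and flagged rather than imputed. Reported rates and ratios round to two
decimals; raw values persist unrounded.

The monthly cost series uses 365.25/12-day months from the index date and
reports, for month m, cumulative cost over the first m months divided by
cumulative person-months at risk (fractional months for censored persons);
a per-month (non-cumulative) variant sits behind a flag. The cumulative
reading was chosen as the primary one because it is stable at late months
where few persons remain at risk; months with zero persons at risk are
flagged, never imputed.

## The synthetic generator

The generator emulates the *structure* of sickness-fund claims, not any real
cost distribution. Its causal skeleton:

* latent frailty `z ~ N(0, 0.4²)` per person;
* competing post-BM exponential waiting times — first SRE (base hazard
  0.75/yr, log-hazard +1.2·z), death (0.70/yr, +0.3·z), BTA initiation
  (0.75/yr, independent of z) — with SREs observable until the inclusion end
  for grouping and until the data end for censoring;
* per-category cost events: Poisson intensities (log-intensity +0.6·z; rates
  per year: admissions 3.3, GP contacts 5.6, specialist contacts 13.5,
  rehabilitation 0.25, prescriptions 42.9, aids 4, remedies 3) with
  log-normal amounts sized so the non-SRE per-patient-year category costs
  land near 10.8 k€ hospitalization, 1.5 k€ visits, 38 € rehabilitation,
  6.8 k€ prescriptions and 1.3 k€ aids/remedies; hospital stays have
  geometric length (mean 9.3 nights) and per-diem amounts;
* entering the SRE state multiplies category intensities/amounts by the
  configured effects (defaults echo the published category rate ratios:
  hospitalization ≈ 1.31 in cost and 1.16 in days, specialist visits 1.05,
  rehabilitation 5.5, prescriptions 0.90, aids/remedies 1.22; implied total
  ≈ 1.16). A uniform-effect variant (`with_uniform_cost_multiplier`) sets
  every category's cost ratio to one number exactly — the configuration the
  recovery tests use;
* background codes in all seven dimensions are Poisson with log-rate +1.0·z
  over 20-code vocabularies with geometric prevalence decay 0.95, so the
  claims carry genuine proxy information about the confounder (measured
  R² of z given the covariates ≈ 0.88 at default settings) — without which an
  hdPS would have nothing to find;
* the last 30 days before death carry a 1.5× intensity boost; 12% of
  SRE-state admissions are tagged with an inpatient SRE code so SRE-related
  hospitalization outcomes are a genuine subset of all-cause ones without
  distorting the configured totals; lung-cancer patients carry a 1.5× cost
  factor so the tumor-type subgroup ordering has a configured truth.

Determinism: one `numpy` Generator drives everything; identical config + seed
give byte-identical tables. Claims are emitted only from one washout year
before BM to the person's data end — no downstream window reads anything
earlier — and persons without BM contribute person/enrollment rows only.

Deliberate departures from real claims, and what they imply: mortality is
only weakly tied to the latent frailty and the terminal-phase cost spike is
mild. Real end-of-life cost concentration is stronger, and because random
non-SRE index dates land closer to death than first-SRE dates, a strong spike
makes the measured cost ratio systematically understate the SRE effect — a
bias the original comparative analyses of this design acknowledge in their
own data. The defaults keep that mechanism present but small so that the
configured effect is identifiable and the matching property tests are
meaningful; configs with a 3×/60-day spike are used where the
deceased-vs-survivor contrast itself is under test. BTA initiation is
memoryless, which overstates late BTA censoring relative to the reported mix
(where BTA starts cluster soon after BM); the censoring-reason composition is
therefore only qualitatively matched. There is no provider or regional
structure, no seasonality, and no calibration to real German cost
distributions. Passing tests demonstrate that the pipeline recovers known
effects under this structure; they do not certify performance on real claims.

## Problem sizes

The default simulated population is 20,000 persons, yielding roughly 10,000
eligible patients and ≈ 3,500 matched pairs — the scale at which the full
pipeline (simulation through outcome tables) runs in well under a minute on
one CPU. The effect-recovery suite runs ten seeded replicates of 5,000
persons each with the uniform 1.16 effect; the null-calibration check uses
200 replicates of 150-person groups with 1,000 bootstrap resamples. These
sizes keep the whole test suite at a few minutes while leaving the
Monte-Carlo error of each asserted quantity comfortably inside its asserted
tolerance.

## Known limitations

* Code lists are placeholders; real analyses must substitute validated lists.
* The censoring-reason mix is qualitative, not calibrated (see above).
* CCI variant ambiguity: only relative balance, never absolute levels, is
  asserted.
* The bootstrap p-value is a calibration-checked convention, not the (never
  specified) test used in the emulated analyses.
* Greedy caliper matching is order-dependent by construction; the seeded
  random order makes this measurable but not removable.
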