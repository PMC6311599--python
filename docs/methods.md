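# Methods

This note documents the models, rules and numerical conventions the package
implements, the design choices made where the design was genuinely open, and
what the synthetic data generator does and does not emulate.

## The selection cascade

Cohort selection is a deterministic phenotyping cascade over event-level
hospital episode histories.  A patient enters the cascade if any diagnosis
field of any event carries a pulmonary-hypertension ICD-10 code (I27.0,
I27.2, I27.9).  Codes are compared on a normalized form (upper-case,
dot-free), because episode extracts store undotted codes while published
code lists are dotted; code lists accept either and normalize on load.
Whether PH identification should search the primary diagnosis field only or
all positions is configurable (`SelectionConfig.ph_code_scope`); the default
searches all positions, since restricting to the primary field is only ever
stated for the first-symptom rule.

Rules are evaluated in a fixed order — research-opt-out removal, PH-code
presence, then: no RHC; no RHC at an adult specialist center; non-iPAH
code; pediatric; insufficient lookback; non-England residence; utilization
cap — and the recorded exclusion reason is the *first* failing rule, so the
attrition table reproduces a single patient-flow diagram.  Conventions:

* **Diagnosis date** is the *earliest* RHC at an adult specialist center.
  Incidence counts *new* diagnoses, so the first confirmatory catheterization
  is the natural event when several exist.
* **Pediatric** is the union of age < 18 at diagnosis and any attendance at
  the pediatric specialist center.  Age is computed from birth month/year
  using the 15th of the month (episode data carries no birth day; mid-month
  halves the maximum dating error).
* **Insufficient lookback** fails when the diagnosis is less than
  `min_lookback_days` (default 3 × 365) after the first recorded event, or
  earlier than a configurable calendar cutoff (in a dataset starting April
  2009 with a 3-year requirement, the cutoff is April 2012).
* **Utilization cap**: ≥ 250 events — inclusive at 250 — counted over the
  full record across all settings.  No observation window is attached to the
  cap because its purpose is to remove atypically heavy utilizers whose
  histories would dominate cohort means; the broadest window serves that
  best.
* **Non-iPAH codes** are matched at any time relative to diagnosis
  (configurable in principle; any-time is the conservative phenotype).
* The non-iPAH exclusion list, the RHC OPCS codes, the specialist-center
  provider codes and the symptom code list are site-governed inputs; the
  package ships documented synthetic stand-ins in `ipahes.defaults`.

**Incidence staging.**  Annual incidence per million is reported either for
the fully selected analysis cohort (`stage="analysis"`) or for the
*probable-iPAH* cohort — survivors of the diagnostic rules only, before the
lookback/residence/utilization restrictions (`stage="probable"`).  The
probable stage exists because the lookback rule removes every diagnosis in
the first three calendar years of any extract by construction, which would
zero out early-year incidence; epidemiological comparison against registry
literature belongs to the probable cohort.

**Age bands.**  In the demographic profile, "> 50 years" is strict: an exact
age of 50.0 falls in the lower band.  In the age-stratified utilization
summary the bands are < 50 / ≥ 50, matching how the stratified comparison is
conventionally phrased.

## Registry merge and linkage

The three clinical sources are merged to one record per patient identifier.
On conflict the final diagnosis follows source precedence (diagnostic
registry > operational clinical database > biobank), with one refinement:
an UNASSIGNED diagnosis never overrides an assigned one — the diagnosis
comes from the highest-precedence source that assigned one.  Without this,
a biobank-confirmed diagnosis would be erased by a registry row that merely
lacks an adjudication, and the "no assigned final diagnosis" category would
be inflated.  First-visit dates take the minimum across sources; records
whose sources disagree on gender or birth fields are flagged
(`demographic_conflict`), never silently merged.

Linkage is deterministic: exact identifier join, with demographics used
only as a consistency check.  Gender and birth month/year must match
exactly; GP postcodes are compared after whitespace/case normalization.
The default **strict** policy demotes any mismatch; a **lenient** policy
tolerates postcode-only mismatches (postcodes churn when patients change
GP).  The linkage rate is 100 × linked / total registry records, rounded
half-up to one decimal (Python's built-in `round` is half-even, which would
mis-report boundary cases).

## Temporal anchors

* **Index date** — the latest cardiology/respiratory/neurology event
  *strictly before* the first specialist-unit visit.  "Before" is read as
  strict: the index is descriptively about 76 days before the first visit,
  so the two are non-coincident; an event on the visit day belongs to the
  specialist work-up, not the pre-referral record.
* **Lookback date** — max(first recorded event, index − 5 × 365 days).
* **First symptom** — the earliest event in [lookback, index] whose
  *primary* diagnosis matches the ICD-10 symptom list, or whose procedures
  match the OPCS symptom list (procedures have no primary field, so any
  position counts).  Same-day ties break by setting (A&E < inpatient <
  outpatient), then file order — an arbitrary but deterministic rule.
* **Eligibility** for the validation cohort removes, in order: linkage
  failures; ≥ 250 total events; no derivable index event; and < 3 × 365 days
  of data before the index.  The 3-year rule is measured against the
  earliest recorded event (data availability), not the lookback date — the
  lookback date is capped at 5 years and testing against it would make the
  rule one-sided.

## HCRU windows

Year windows count back from the per-patient anchor (diagnosis date in the
pilot arm, index date in the validation arm): Yk = [anchor − k·365 d,
anchor − (k−1)·365 d), half-open, with the anchor day itself in no window —
the anchor day's activity is part of the diagnostic episode, not
pre-diagnosis behavior, and half-open intervals guarantee the three windows
are disjoint and exhaustive over the 3-year span.  A "year" is 365 days;
leap days are not special-cased.

Cohort means are arithmetic over all anchored patients (zero counts
contribute zeros).  Because a patient's lookback may start inside the
3-year span, each window also carries a complete-case denominator
(`n_observed`: patients whose observation start precedes the window), so
both all-cohort and complete-case means are available; nothing is imputed.
Distinct-provider and distinct-specialty counts are per patient over all
in-span events across all settings, then averaged.  The cardiology-or-
thoracic share maps to the canonical specialties CARDIOLOGY and RESPIRATORY
via the configurable specialty vocabulary (raw treatment-function codes →
canonical names; unmapped codes fall to OTHER).

## Synthetic data generator

The generator emulates a national episode extract joined to a specialist-
center registry.  Event counts are Poisson per patient × setting ×
pre-anchor year — the minimal count model consistent with reporting means,
and the one that makes recovery tests analytic — with dates uniform within
the year and a stepwise per-year escalation matching the Y3/Y2/Y1 reporting
granularity.  All randomness derives from one seed, split hierarchically by
(subpopulation, patient index), so enlarging a cohort never perturbs
earlier patients' draws.

Deterministic scaffolding gives every derived quantity a known truth:

* a registration event exactly `history_years` (default 5) before the
  anchor guarantees the record span;
* a diagnosis encounter on the diagnosis date carries the PH code and the
  RHC procedure at an adult specialist provider;
* validation-style subpopulations (`gap_days = 76`) additionally plant the
  index encounter — a relevant-specialty event 76 days before the first
  center visit, with no events in the gap — so the derived index date is
  known exactly and window counts equal the Poisson draws;
* the first-symptom event is created by re-labelling an existing pre-anchor
  event (the earliest within two years of the anchor) with a symptom code
  and a specialty drawn from the symptom-specialty mix, rather than by
  inserting an extra event, so calibrated count means are not inflated.

Contrast subpopulations each violate exactly one cascade rule (no PH code,
no RHC, RHC at a non-specialist provider, non-iPAH code, pediatric age,
non-England residence, ≥ 250 events) while passing all earlier rules.
Registry mirrors carry matchable demographics, with discrepancies (missing
identifier, gender flip, birth-year shift, postcode change) injected at a
configurable rate whose default, 1.4%, reflects a 98.6% clean-linkage
environment; a fraction of patients (default 20%) appear in a second source
with an unassigned diagnosis, exercising the merge.

**Calibrated presets.**  `phase1_case_spec` fixes per-year (Y3, Y2, Y1)
means of outpatient (4.9, 5.9, 9.4 — summing to 20.2), inpatient
(0.7, 0.8, 1.8) and A&E (0.3, 0.4, 0.8) events: a 3-year total of 25.0 with
12.0 in Y1, and a specialty mix with half of events under
cardiology/respiratory.  `phase2_case_spec` fixes outpatient
(4.4, 5.3, 8.4 — summing to 18.1), inpatient (0.8, 0.9, 1.7) and A&E
(0.3, 0.4, 0.8): a 3-year total of 23.0, a 32% cardiology/thoracic event
share, and a first-symptom specialty mix of general medicine 36.0%,
respiratory 32.8%, cardiology 13.3%, geriatric medicine 3.1%, A&E 2.9%,
general surgery 1.1% (remainder OTHER).  Demographics default to 60%
female and 64% aged over 50 at diagnosis.  These presets are the study
conditions under which the pipeline is exercised and are not re-tuned.

**What the generator does not emulate.**  Realistic marginal ICD-10
frequencies, comorbidity correlation structure, seasonality,
setting-dependent specialty profiles (specialty is drawn independently of
setting), heavy-tailed utilization beyond the explicit high-utilizer
subpopulation, or partial five-year data coverage (every generated case
spans its full history, whereas real cohorts have ragged starts).  Passing
recovery tests therefore demonstrates that the *pipeline's* windowing,
counting, linkage and cascade logic are correct under known conditions —
not that real episode data behave like the generator.

## Problem sizes and tolerances

Statistical tests run at the cohort sizes stated in each test: label
recovery on 1,000 patients (300 clean + 700 across seven violator
subpopulations); rate recovery at n = 500 with per-target 3-standard-error
bounds (and a joint chi-square(3) check at α = 10⁻³ for the per-setting
unit test); linkage-discrepancy recovery within 3 binomial standard errors
at n = 400.  `scripts/acceptance.py` uses n = 1,000 synthetic cohorts for
the utilization and validation summaries and sizes the incidence cohort at
403 cases (1.9 per million per year against a 53-million denominator over
2010–2013, diagnosed uniformly).  Exact worked examples (linkage rate
98.6% from 852/864; registry partition 864 + 3944 + 1383 + 483 = 6674) are
computed from their published counts as inputs.

## Known limitations

* The cascade records only the first failing rule; multi-reason accounting
  would require a different attrition surface.
* Calendar-year incidence assumes the diagnosis-date distribution is
  meaningful per year; the generator draws diagnosis dates uniformly, so
  per-year synthetic incidence carries Poisson noise of ~10% at ~100 cases
  per year.
* The 365-day year drifts one day against the calendar every leap year;
  over a 5-year lookback the drift is ≤ 2 days.
* No probabilistic linkage: records without a usable identifier are
  unlinkable by design.
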