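# Methods

## The classification model

`fpattach` operationalises "having a family physician" as a hierarchy of
three administrative facts, evaluated over a closed two-year window:

1. **Enrolment.**  Formal enrolment is a signed, registry-recorded
   commitment between patient and physician, and is taken as the strongest
   evidence of attachment.  Two kinds exist: enrolment with a
   family-medicine-group (FMG) physician, open to any patient, and
   vulnerable-patient enrolment, restricted to patients with qualifying
   chronic conditions.  Eligibility for these conditions is consumed as
   the registry's own `kind` field; no diagnosis logic is implemented.
   A physician qualifies when the patient's merged enrolment spells with
   that physician cover at least `min_enrolment_days` of the window
   (default 548 = ceil(1.5 × 365.25); the "18 months" criterion is stated
   in months, so the day count is a package choice, configurable on
   `StudyWindow`).  FMG enrolment takes priority over vulnerable
   enrolment when both qualify.
2. **Complete medical examinations (CME).**  A comprehensive exam billable
   at most once per patient per physician per calendar year in a
   primary-care clinic.  Two CMEs by the same physician (necessarily in
   distinct calendar years) indicate a stable relationship; a single CME
   still indicates some attachment; CMEs spread over different physicians
   indicate none, and such patients are barred from the CME-based types.
3. **Concentration of visits.**  The usual-provider-of-care (UPC) score:
   the fraction of countable clinic visits made to the most frequently
   seen physician, defined only for patients with ≥ 2 countable visits.
   75% or higher is read as attachment to the modal physician.

Countable visits (for both CME detection and UPC) are claims inside the
window with clinic setting — emergency-room and hospital-inpatient rows are
excluded — billed by fee-for-service physicians.  Time-basis physicians
(community health centres, teaching units) generate no usable claims, so
their CME/UPC activity is structurally invisible; their enrolments still
count, which is why type-1/2 shares are unaffected.  This asymmetry slightly
understates CME and UPC prevalence among enrolled patients of such
physicians, exactly as in real fee-for-service data.

The cascade assigns the first type whose rule fires (README table).  CME
claims count as visits in the UPC denominator; the single-visit type 7
explicitly excludes CME visits, which is consistent because a lone CME is
captured earlier by type 5.

### Non-attached subtypes

Type 8 is refined by first-match over five rows: 8a multi-physician
enrolment with no qualifying physician; 8b multi-physician CMEs; 8c UPC
above 50% (the 75% upper bound is enforced by the cascade itself, so the
row is coded as the "> 1/2" dichotomy of its companion row); 8d more than
one visit with UPC ≤ 50%; 8e no countable clinic visit.  Under non-default
configurations a type-8 patient can match no row (e.g. an
enrolment-blocked single visit in strict mode); such patients fold into
8d/8e by visit count with a logged warning rather than gaining an invented
sixth category.

### Configuration points

* `strict_no_enrolment` (default off): reads "without any type of
  enrolment" literally, letting any spell touching the window — even one
  too short to qualify — block rules 3–7.  Off by default because the
  non-attached taxonomy has no row for short-spell patients, so blocking
  would leave them undescribed.
* `multi_cme_to_type8` (default on): patients with multi-physician CMEs
  and no pair go straight to type 8 (they form subtype 8b); turning it off
  lets them compete at the concentration rule instead.  Both routings are
  defensible readings of the cascade; the default keeps the subtype table
  additive.
* `upc_threshold` (default 3/4) and the 51–74% partial band; all
  comparisons use integer cross-multiplication on exact `Fraction`s, never
  floats, so boundary cases (UPC exactly 3/4, exactly 1/2) are
  deterministic.

### Tie-breaks and degenerate inputs

The sources are silent on ties, so the package fixes them
deterministically: qualifying-enrolment ties by most covered days, then
earliest spell start, then smallest physician id; CME-pair ties by more
CMEs, then most recent CME, then smallest id; modal-physician ties by most
recent visit, then smallest id.  Cohort exclusion reasons are tallied in
the fixed order age → non-resident → no activity → long-term care →
deceased, so a patient failing several criteria counts once, under the
first.  Age eligibility ("20 and over") is evaluated at the window start;
death anywhere in the window excludes by default (both choices
configurable, since the original assessment date is unstated).  Duplicate
same-year CME billings are dropped at read time keeping the earliest (or
the read hard-fails, per configuration).

## Synthetic data

The generator emulates two years of fee-for-service claims and enrolment
spells for an urban adult population.  Each patient is drawn from a type
mixture and realised by a recipe that satisfies the target type's
predicate *by construction* (counts and splits chosen so the defining
inequalities hold exactly), so the truth table is exact and planted-truth
recovery is a 100%-accuracy check, not a statistical one.  Defaults:

* `type_mixture` — the study population's observed distribution
  (7.2, 16.2, 5.3, 8.1, 8.0, 12.7, 10.5, 31.9 percent for types 1–8,
  re-normalised from printed one-decimal percentages summing to 99.9), so
  default simulations resemble that population; the non-attached share is
  split 0.4 / 1.0 / 4.6 / 14.4 / 11.5 across 8a–8e the same way.
* `mean_visits = 4` per patient over two years (zero-truncated Poisson,
  clamped up to each recipe's minimum), `n_physicians = 200`,
  `time_basis_fraction = 0.15`, `fmg_fraction = 0.35` — plausible values
  for a large urban primary-care market; none of the classification
  checks are sensitive to them because truth is planted by construction.
* demographics: 55.1% female; age bands 20–44 / 45–59 / 60–74 / 75+ at
  43.8 / 27.5 / 18.1 / 10.6%; diabetes 9.3%; morbidity low/moderate/high
  at 42.5 / 47.3 / 10.2%.  With `covariate_gradients=True` the age,
  diabetes and morbidity draws are tilted by type (vulnerable-enrolled
  patients older and sicker, single-visit and non-attached patients
  younger and healthier), qualitatively reproducing the stratified
  gradients of such populations while leaving the type marginal equal to
  the mixture.

What the generator does **not** emulate: real billing-code vocabularies,
visit seasonality and clustering into episodes, physician panel sizes,
geographic structure, patients who are simultaneously near several type
boundaries, data-entry noise beyond the optional planted duplicate-CME
violations, and ineligible patients (every simulated patient passes the
cohort filter).  Passing tests therefore demonstrate that the rules are
implemented and composed correctly, not that the mixture or the covariate
gradients would be recovered from any particular real registry.

## Reports

Tables are computed on exact counts and rounded only at display,
half-up to one decimal (the convention of published prevalence tables);
machine-readable CSVs carry the denominators.  A percentage column over an
exhaustive partition sums to 100 within ±0.3 after rounding.  Aggregate
rows (attached / non-attached) are recomputed from unrounded counts, so
the displayed aggregate can differ by 0.1 from the sum of displayed rows —
e.g. a population with per-type shares printing as 7.2 … 10.5 prints
attached = 68.1 while the same rows summed after rounding give 68.0.  The
dimension-prevalence table counts every holder of each dimension
independently of the cascade, so its rows dominate the corresponding
cascade shares by construction.  Empty strata are emitted as missing
markers, never as divisions by zero.

## Problem sizes and determinism

The shipped test suite and the acceptance script use a 20,000-patient
population (about 100,000 claim rows) for the statistical checks — large
enough that every type's share is estimated within a fraction of a
percentage point (3 binomial SEs at the smallest planted share, 0.4%, is
±0.13) — and exhaustive 26-fixture sweeps for the boundary checks.  All
randomness flows from a single integer seed through one NumPy generator;
identical seeds give byte-identical CSV outputs.

## Known limitations

* The attached physician is the rule-implied one; without linkage to
  survey or physician-roster data the package cannot validate that this
  is the physician the patient would name.
* A patient can hold a family physician without any claim in the window
  (misclassified non-attached), or see a physician once without any bond
  (type 7 is deliberately the weakest attached type).
* Morbidity bands are consumed as given patient attributes; no case-mix
  grouping is computed.
* The enrolment registry is modelled as clean intervals; real annual
  snapshots may need pre-merging before they satisfy the spell schema.
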