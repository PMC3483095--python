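# Methods

## Study design emulated

`osteoburden` implements a prevalence-based cost-of-illness pipeline for
osteoporosis-related fractures in a population aged 50 and over, of the
kind run on Canadian administrative health data for fiscal year
2007/2008. All cases prevalent in the year are costed, regardless of
onset; costs are expressed in 2010 Canadian dollars from both a payer
and a societal perspective. The real source databases (acute discharge
abstracts, ambulatory care, rehabilitation, continuing care, home care,
drug and physician claims) are access-restricted, so a synthetic
generator reproduces their stratified structure and the published
national tables serve as benchmark inputs.

## Case identification and attribution

A record is a fracture case when (1) its most responsible diagnosis
(MRDx) is an includable fracture code, or (2) a secondary diagnosis is
an includable fracture code and an intervention indicative of fracture
treatment (fixation, immobilization, reduction, partial excision,
repair) is present. Records matching both definitions count once,
tagged MRDx; events, not persons, are counted. Records under age 50 and
records with a severe-trauma external-cause code (transport accidents,
falls from height — configurable) are excluded in the base case, keeping
fragility fractures. Sites classify into hip, vertebral, wrist,
humerus, multiple, other; fractures of the heel, toe, hand, finger,
face, skull, sacrum and coccyx are not osteoporosis-related and never
form cases. Two distinct includable sites on one record classify as
`multiple`. The official diagnostic classification is not
redistributable, so the prefix→site mapping is configuration
(`CodeMap`) with documented defaults.

Hip and vertebral fractures are attributed to osteoporosis in full
(weight 1.0). For the remaining sites a sex-specific rate X solves

    share_hv · 1.0 + (1 − share_hv) · X = overall_target

with overall targets 0.745 (men) and 0.904 (women) — the fractions of
low-trauma fractures occurring at low bone mineral density in the
source cohort. `share_hv` is the hip+vertebral share of the case set
supplied to `apply_attribution`; the pipeline supplies all settings
combined (post-exclusion, pre-attribution), so an admissions-only
denominator is obtained by passing the admission subset. A sensitivity
mode replaces women's other-site rate with age-band rates from a Quebec
cohort (0.757 at 50–59 to 0.918 at 80+; intermediate decades 0.81 and
0.87 are interpolated configuration, since only the endpoints are
published). Weights are deterministic fractional multipliers carried
through counts, days and costs — expected-value accounting, never
Bernoulli sampling — which keeps the pipeline reproducible and makes
attribute-then-extrapolate algebraically identical to the reverse
order (asserted by test).

## Costing

**Acute settings.** Each encounter costs RIW × $5,399.04 plus physician
assessment fees, a diagnostic fee and (admissions, day surgeries) a
procedure fee. Assessments follow length of stay: $79.20 on admission
day; $55.45 on days 2, 3 and the last day (a day qualifying twice bills
once); $29.20 otherwise. Diagnostics and procedures default to the
published cross-site averages ($75, $1,352) with per-site overrides,
since the fee schedules publish only ranges ($33–$117, $76–$2,551).
Whether ER visits attract a procedure fee is unstated in the source
methodology; default is no (`er_procedure_fee` flag). Costs accumulate
as floats and round to the cent at aggregation boundaries, so every
rendered total is the exact sum of its rendered cells.

**Post-acute pathways.** Facility use is proxied by net transfers: per
destination and per sex, discharges from acute care minus entrants from
that facility class, floored at zero (only the excess represents new
osteoporosis-attributable placements). Rehabilitation costs
days × $736/day (primary mode; a per-stay RIW mode at $15,449 remains
behind a flag); days default to net × 23.64 — the ratio of the published
131,944 rehabilitation days to the published 5,581 net transfers, a
calibration, not a published value. Continuing care costs
net × 91 days × mean RIW × $420.12; long-term care net × 194 × $147.77;
home care recipients × weeks × $168.50 with weeks defaulting to 28.7993,
calibrated so the published 50,398 recipients reproduce the published
$244,565,735 component.

**Physician and drugs.** Outpatient physician visits split 81%/19%
between general practice and internal medicine, each half consultation
($56.10 / $132.50) and half repeat ($42.35 / $82.90). Drug spend enters
as observed public spend plus observed private spend scaled by its 65%
claim coverage. These are observed inputs, not record-level
computations; defaults invert the published components.

**Indirect costs (human capital).** Productivity losses value days not
available for work — acute days plus, configurably, rehabilitation,
continuing-care and home-care days (the long-term-care stock is
excluded by default as largely retired) — at participation rates 0.77
(50–59) and 0.45 (60–69) times $24.12/h × 8 h. No participation rate is
given above 69, so older ages contribute zero. Non-acute days are
spread over age bands in proportion to each band's share of national
admissions (the true split is unpublished). Caregiver losses apply
47.2% caregiver use × 37 days × 35.8% caregiver employment × the daily
wage to every attributable admission, at any age.

## Extrapolation

Quantities observed in a subset of provinces (acute data exclude
Quebec; ambulatory and home-care data are Ontario-only) scale to
national totals by direct age–sex standardization: stratum rate =
value / source population, national value = rate × national population.
Zero-count strata contribute zero (no smoothing); events in a stratum
with zero population raise an error naming the cell. The operation is
exact for identity populations, linear, and composes
(A→B→C equals A→C) — all property-tested. Fracture-type mix differences
between provinces are not adjusted for.

## Scenarios

* **base** — full pipeline as above.
* **rocq_attribution** — women's age-specific attribution.
* **add_op_only_admissions** — admissions with osteoporosis alone (no
  fracture code; default N = 2,096) are added to the acute,
  rehabilitation and continuing-care components pro rata at the base
  per-admission intensity. The published column is not exactly
  proportional (its per-case costs are unpublished), so verbatim
  reproduction uses component overrides.
* **ltc_prevalence** — replaces the net-transfer long-term-care
  component with a full-year cost over the stock of long-term-care
  residents over 65 attributable to osteoporosis: per-sex denominator ×
  prevalence (0.17 men, 0.21 women) × $147.77 × 365. The resident
  denominators default to {M: 40,000, F: 112,500}, calibrated to the
  modelled 30,425 attributable residents.
* **all_trauma** — severe-trauma exclusion off, every weight 1.0;
  dominates the base case by construction.

Any of the eight components can be pinned by an override (recorded in
the result and the report footnote); this exists because three
published components — continuing care, base long-term care, and the
$46M productivity figure — cannot be recomputed from published inputs
(their mean RIWs and day splits were never printed).

CPI inflation to 2010 is a plain ratio (`inflate_to_2010`); unit-cost
defaults are already 2010 dollars, and the bundled all-items index
values (2002 = 100) cover 2007–2010.

## Synthetic generator

One integer seed drives deterministic per-record-type substreams;
identical configurations give byte-identical CSVs. Defaults emulate the
published national structure: admission site mix ~50% hip, sex mix 70.6%
female, >70% of cases over 70 with the peak in the 80s, rest-of-Canada
province mix for discharges and Ontario-only ambulatory records,
ER mix wrist 30% / hip 23% / other 30% and a day-surgery mix 80% wrist.
Length of stay is log-normal (mu = ln 6.6, sigma = 1.209) rounded up to
a whole day, giving mean ≈ 14.5 and median ≈ 7 days; RIWs are gamma
around site means calibrated so per-admission costs land near the
published site averages (hip ≈ $20k, wrist ≈ $9k, multiple ≈ $23k); the
published dispersions are unknown. Severe-trauma contamination (5%),
secondary-code-only presentation (10%), under-50 (3%), excluded-site
(3%) and non-fracture (4%) records exist purely to exercise the
filters. The generator does not emulate record linkage, within-year
readmission correlation, provincial case-mix differences, coding error,
or disclosure realism — passing tests show the pipeline arithmetic is
right under the assumed structure, not that real administrative data
would satisfy those assumptions.

## Numerical choices and limitations

Money is floating point, rounded to cents only at aggregation/render
boundaries; percent cells round half away from zero at render only.
Probability vectors must sum to 1 within 1e-9. The attribution solver
raises rather than clips when a target is infeasible (X outside [0,1])
or the hip+vertebral share is 1. Empty inputs yield empty outputs, not
errors. Problem sizes in the test suite (hundreds to tens of thousands
of synthetic records) were chosen as the smallest that make the
statistical checks (binomial interval, chi-square at α = 0.001) stable.
Event counting means a patient admitted twice counts twice, as in the
source methodology, which reports hospitalizations rather than persons.
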