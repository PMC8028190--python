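# Methods

## Model structure

The provider cost model is a deterministic state-transition cohort model
with a yearly cycle. Everyone enters at age 2 (the age chelation starts)
in "TDT without cardiac complications"; each cycle survivors may develop
cardiac disease and/or die, with dead absorbing, up to the horizon at age
58. The cardiac state is split into tunnel strata by year since onset
(year 1 vs year 2+), because complication management costs differ between
the onset year and established disease. The four endocrine complications
(diabetes, hypogonadism, hypoparathyroidism, hypothyroidism) are tracked
the same way but do **not** modify mortality — they enter through costs
only — so their prevalences, conditional on being alive, evolve
independently of survival.

Mortality at age *a* in the non-cardiac state is
`min(1, q(a) * RR)` with `q(a)` the general-population annual death
probability and `RR = 3.9` the TDT relative risk. The cardiac state adds
an annual excess probability of 0.0062, combined as independent competing
risks: `1 - (1 - base)(1 - 0.0062)`. The printed header of the excess-risk
figure is ambiguous about scale ("(%) 0.0062"); it is interpreted as the
probability 0.0062 = 0.62%/yr and is configurable. Within a cycle, onset
is evaluated before death (a patient whose cardiac disease starts this
cycle faces cardiac mortality immediately); the published description does
not fix this ordering, so it is a documented convention. There is no
half-cycle correction: costs accrue on start-of-cycle occupancy, matching
the whole-cycle accounting the published sums imply.

An individual-level microsimulation implements the identical rules and is
used purely as a validation oracle for the recursion, never as the
production path.

## Costs

All computation happens in a single currency (MYR natively; USD is a
single multiplicative reporting conversion at 4.07). Per cycle and age:

- **Chelation (cICT).** Children (ages 2–15) receive DFX; from age 16 the
  cohort splits 50/50 between DFO monotherapy and DFO+DFP (the published
  policy states "DFO or DFO + DFP" without proportions; the split is
  configurable, and the survey's observed regimen mix is available as an
  alternative preset). Annual drug mass per agent is
  dose (mg/kg/day) x weight(age) x dosing days. DFO is dosed five days a
  week (its administration cost is priced "per month for five weekly
  doses"); oral agents daily. Acquisition cost is scaled by compliance
  (DFO 77.3%, DFP 90.3%, DFX 98.1%) by default — the compliance figures
  are listed among the model parameters and would otherwise be inert, and
  only under compliance-scaled, five-weekly DFO dosing does the lifelong-
  DFX scenario reproduce the published "approximately +65%" provider-cost
  increase (unscaled daily dosing yields about +21%). Both choices are
  switches (`compliance_scales_cost`, `dose_days_per_week`).
- **Administration (cAdmin).** MYR 393.98/month, twelve months a year, for
  any regimen containing DFO; not compliance-scaled (consumables are
  dispensed regardless of use).
- **Monitoring.** Monthly schedule by age group, cutoff at 10 years
  (the ">= 10" schedule applies from the cutoff age itself).
- **Transfusion.** 12 transfusions/year of 15 ml/kg at the per-ml blood
  price plus fixed crossmatch and equipment fees per episode.
- **IOL complications.** Prevalence-weighted year-1 / year-2+ annual
  management costs. The printed table leaves the year-2+ cells for cardiac
  disease and diabetes blank; both default to the year-1 value (both
  sources are annual ambulatory-care estimates) and are overridable.

Lifetime components are survival-weighted sums over ages; TC3 multiplies
the survey's mean monthly family expenditure by 12 and by the summed
survival curve (a single population-level mean — age-stratified family
costs are out of scope). TC1 = TC2 + TC3 holds identically in both
currencies.

## Weight model

Body weight enters chelation and transfusion costs at every age. It is
modelled by independent OLS lines on age bands 1–10, 11–18 and 19–60,
mirroring near-normal first-decade growth, slowed pubertal growth, and an
adult plateau. Boundary ages belong to the band whose inclusive lower edge
they match. For the adult band, where age explains almost no weight
variance, a constant-mean fallback is provided. The original fitted
coefficients are not published, so the packaged workflow fits the bands to
synthetic survey data; predictions are validated against the generating
growth curve rather than any published trajectory.

## Survey pipeline

Monthly patient/family expenditure per respondent is
cOOP + cTransportation + cProductivity (MYR). Missing transport costs are
imputed as recorded return-trip distance x government reimbursement rate x
monthly visits; records missing both are flagged and excluded from
transport means but never dropped. Productivity loss is hours at the
facility x average hourly wage. The determinants model is a forward-
stepwise OLS (entry p = 0.05, removal p = 0.10, the SPSS convention) of
ln(total monthly expenditure) on income category (ordinal code), visits
per month, a DFO-regimen indicator and years of transfusion; non-positive
totals are excluded before the log with their count reported (an
epsilon-offset alternative is deliberately not the default).

## Synthetic inputs

Three inputs of the original analysis are not public and are generated
with known ground truth:

- **Life table.** Gompertz-Makeham hazard
  `mu(x) = lambda + alpha e^(beta x)` with lambda = 5e-5/yr and
  beta = 0.11/yr; alpha is solved by bisection so the zero-onset TDT
  cohort (RR 3.9) attains a target life expectancy — default 57.7 years of
  age, the published model output — within 0.05 years. The published
  target is a *life expectancy in years of age*; over a horizon of ages
  2–58 the corresponding person-years (55.7) are what the calibration
  controls. The form only needs to make the cohort model exercisable; it
  is not a demographic estimate for Malaysia.
- **Transition probabilities.** Age-flat (or linearly age-ramped) annual
  onset curves. Defaults — cardiac 0.005; diabetes 0.008, hypogonadism
  0.020, hypoparathyroidism 0.004, hypothyroidism 0.006 — were chosen once
  so that any-complication prevalence near the survey's mean age (~17) is
  about 44%, matching the observed complication frequency (44.6%) in the
  surveyed population. They are user-replaceable, and no claim is made
  that they reproduce the source model's values.
- **Survey.** n = 574; integer ages from a truncated normal whose location
  is solved so the *truncated* mean is 17.3 (SD 10.6); weights from a
  piecewise growth curve (level-calibrated so the cohort mean is 36.8 kg,
  noise SD 6 kg); regions and regimens drawn at the observed frequencies;
  income as an ordinal 1–5 code; visits 1 + Poisson (rate 2.0 in East
  Malaysia, where repeat visits for phenotype-matched blood are reported,
  0.3 elsewhere); years of transfusion = age minus an onset age of
  1 + Poisson(2); hours in hospital normal (22.1/9.3 East Malaysia,
  11.7/7.1 elsewhere, truncated at 0). Monthly totals follow the published
  log-linear model exp(6.654 + 0.272 income + 0.294 visits + 0.262 DFO +
  0.009 years + eps) with the noise SD set from the realized covariate
  variance to target R^2 = 0.492; totals split 33.5/31.1/35.5% into
  OOP/transport/productivity (shares normalized; the printed shares sum to
  100.1%), and 10% zero-expenditure respondents are injected (the true
  zero prevalence is unpublished; 10% is an arbitrary documented default).

**A deliberate inconsistency to be aware of:** the published mean monthly
expenditure (USD 65.56 ≈ MYR 267) and the published log-linear model are
mutually incompatible — the regression constant alone (e^6.654 ≈ MYR 776)
exceeds that mean, and a log-normal mean exceeds its median. The generator
follows the regression model, so its monthly mean (~MYR 3,700) and any TC3
derived from it are much larger than the published survey mean. Lifetime
figures computed on fully synthetic inputs are therefore *structural*
stand-ins: they exercise every code path and satisfy the calibration and
equivalence properties below, but do not reproduce the published TC2/TC3
magnitudes, which depend on the non-public inputs.

## Validation strategy and numerical choices

- The cohort recursion is checked exactly against brute-force enumeration
  of all individual event paths on small (≤ 3-cycle) models, and against a
  100,000-patient microsimulation on the full base case. State occupancies
  are required to agree within 3 binomial SE at every age; the per-
  complication tunnel strata add ~450 further comparisons, for which a 4 SE
  familywise allowance is used (an unbiased simulator exceeds 3 SE
  somewhere among ~740 correlated cells for most seeds).
- Conservation (occupancies sum to 1, tolerance 1e-12), monotone survival,
  monotonicity of life expectancy in the relative risk, and linearity of
  transfusion cost in volume/frequency are asserted as properties.
- Stepwise-regression recovery is validated on 500 replicated synthetic
  surveys of n = 305 (the published regression's effective sample), with
  the mean visits coefficient required within 2 Monte-Carlo SE of the
  generating 0.294. Simulation sizes (1e5 microsimulated patients, 500
  replicates) were chosen so each check resolves its tolerance comfortably
  while the whole suite stays fast.
- Currency cross-checks between the printed USD and MYR unit-cost columns
  pass at 0.5% relative error or half a printed ULP (the per-ml blood
  price, USD 0.16, is exact only to print precision).
- Bisection tolerances: life-table calibration 0.05 years; survey age
  location solved to machine tolerance on a fixed bracket.

## Limitations

- Undiscounted costs only, matching the source analysis; no price-year
  inflation adjustment, no currencies beyond MYR/USD.
- No bone-marrow-transplant, hepatic or infection states; no
  time-varying compliance; endocrine complications carry no mortality.
- The synthetic life table, transition probabilities and survey stand in
  for non-public data: passing tests demonstrate correct mechanics and
  calibration, not Malaysian epidemiology.
- Whether compliance should modify cardiac-onset probabilities (as in the
  source progression model) is unspecified in the base analysis; the
  transition interface accepts arbitrary curves, but the default keeps
  transitions regimen-independent.
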