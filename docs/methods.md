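# Methods

## Model structure and assumptions

The model is an annual expected-value decision tree for one older adult
with type 2 diabetes on glucose-lowering monotherapy. The decision node is
the choice among six medication classes; chance nodes realize hypoglycemic
events, their severity, the care pathway of severe events, and survival of
hospitalization. Because every payoff is linear in event counts, the tree
collapses to closed-form expectations: annual cost and QALYs are rates
times expected per-event quantities. The time horizon is one year with no
discounting; the six classes are assumed approximately equivalent in
glycemic efficacy, so the comparison isolates hypoglycemia-related cost and
quality-of-life differences. Combination therapy, non-hypoglycemia drug
harms and long-term complications are out of scope.

Key structural assumptions:

- **Event counts are Poisson.** The analytic expectations only need means,
  but the simulator and the fatality formula assume independent events;
  Poisson is the minimal such model and yields the thinning identity
  `p_fatal = 1 − exp(−rate_severe · p_hosp · p_death)`.
- **Severity mix is constant.** All events split 95/4/1 into
  mild/moderate/severe regardless of drug and cohort. The risk equation's
  output is interpreted as the *mild* rate; moderate+severe events are
  added at 5/95 of it. This convention reproduces the reported rate table
  for metformin, DPP-4 inhibitors, thiazolidinediones and sulfonylureas
  (80+); the reported basal-insulin and GLP-1 cells follow a different,
  mutually inconsistent convention and are quarantined as expected
  failures in the test suite rather than silently tolerated.
- **Renal-function multiplier.** The adopted reading is
  `22700^(clamp(GFR,15,60)^−0.86655 − 60^−0.86655)`, which equals 1 at the
  65–79 cohort's GFR of 61 and reproduces the 80+ rates. An alternative
  reading that divides the multiplier by 1.2 is implemented behind
  `risk_constants.gfr_legacy_divisor` for auditability; it cannot
  reproduce the rate table and is off by default.
- **Ambulance and EMS glucagon** are charged only on the transported
  severe-event pathways (emergency room, hospitalization), at probability
  1.00 and 0.25 per event respectively; the post-event follow-up (14%
  professional contact with one glucose assay, 3.9 extra self-monitoring
  tests) applies after events of every severity.
- **Fatality enters QALYs as half a year** of base utility lost
  (`fatal_event_year_fraction_lost = 0.5`, configurable), because the
  conversion of in-year death to QALYs is not otherwise pinned down; fatal
  events do not truncate the cost or event streams. The simulator draws
  the death time uniformly over the remaining year, matching the half-year
  expectation.
- **Headline rate totals** are reported as the sum of the two
  independently 2-dp-rounded severity components (e.g. 1.91 + 0.10 =
  2.01), which is how the reported totals were evidently formed; full
  precision is kept internally.

## Parameters

All inputs live in a validated `ParameterBundle` (YAML-serializable; two
packaged bundles, `us_2015` and `canada_2015`). The quantities that matter
most, with defaults:

| parameter | default | units |
|---|---|---|
| base rates (met/SU/DPP-4/TZD/GLP-1/insulin) | 1.0 / 3.0 / 1.0 / 1.0 / 1.3 / 6.3 | events/person-year |
| cohort 65–79 (duration, A1c, BMI, GFR) | 15.6 y, 7.1%, 31.1, 61 | — |
| cohort 80+ | 17.8 y, 7.0%, 28.2, 45 | — |
| severity split | 0.95 / 0.04 / 0.01 | proportion |
| severe-event branch | 0.26 / 0.13 / 0.20 / 0.17 / 0.24 | GP/NP/outpatient/ER/hospital |
| death given hospitalization | 0.20 | probability/year |
| daily SMBG tests | 0.94 (oral), 1.16 (SU), 2.08 (insulin) | tests/day |
| base utility | 0.844 | utility/year |
| daytime share of events | 0.75 mild, 0.60 moderate/severe | proportion |
| WTP threshold | 54,630 US$ / 53,891 CAN$ | per QALY |

Currencies are never converted implicitly; a bundle carries one currency
(2015 US$ or 2015 CAN$) and all outputs inherit it. The only conversion
utility is explicit (`convert_currency`), e.g. 50,271 × 1.0720 → 53,891.

### Synthetic calibrated unit costs and disutilities

The original analysis sources its unit costs and per-event disutilities
from supplementary fee-schedule tables that are not redistributed with
this package. The packaged defaults are therefore **synthetic**: they were
calibrated, once, so that the model reproduces the reported per-person
annual cost column (within ±1 currency unit for the internally consistent
rows) and QALY column (exactly, at 3 decimals, for the
metformin/DPP-4/TZD/sulfonylurea cells). The calibration exploits the
model's linear structure — therapy cost and the per-event cost scale are
separately identified by the two cohorts' rate ratio (1.3914) — but the
solution is not unique, so individual unit costs (notably the implied
severe-event cost, dominated by the hospitalization price) should be read
as effective values, not fee-schedule facts. Any substantive costing work
should override `unit_costs` and `utilities.disutility_per_event` with
payer values; they are plain configuration data.

Consequences worth knowing: the basal-insulin cost cells land within ~1%
(not ±1) and the GLP-1/insulin QALY cells within 0.001–0.008 of the
reported values, because those reported rows are internally inconsistent
with the others (see above); and the population-level dollar figures
reproduce the reported order of magnitude but not the exact digits.

## Incremental analysis

Pairwise ICERs vs a single reference with dominance classification:
dominant (cheaper, at least as effective), dominated (costlier, at most as
effective), equivalent (both deltas at machine zero), otherwise ΔC/ΔE. The
cheaper-but-less-effective quadrant is flagged (`southwest`) rather than
reported as a bare ratio. Ranking is by decreasing cost-effectiveness.
Frontier pruning with extended dominance exists (`efficiency_frontier`)
but is opt-in; the headline comparisons are pairwise.

## Sensitivity analysis

- **One-way (tornado):** each scalar parameter is swung to ±25% of base
  (or an explicit range) with everything else fixed; dominance at an end
  is encoded as a signed infinity and labelled. Sum-constrained probability
  vectors (severity split, severe-event branch) are excluded from the
  default sweep because a one-way swing would break their simplex
  constraint.
- **Probabilistic:** 1,000 iterations by default. Gamma distributions for
  incidence-rate inputs, unit costs, drug costs and disutilities; beta for
  the base utility, truncated to (0, 1]. The ±25% range is interpreted as
  a 95% interval half-width, so every distribution is moment-matched to
  `sd = 0.25·mean/1.96` — the standard convention when only a range is
  stated. Parameters are drawn jointly but independently (no correlation
  structure is specified anywhere). Non-positive bases cannot
  parameterize a gamma and are held fixed with a warning.
- **CEAC:** at each willingness-to-pay value, the probability that a
  strategy maximizes net monetary benefit (QALY·WTP − cost) among all six;
  probabilities sum to 1 by construction. A summary-level variant
  (`psa_from_summary`) runs the same machinery directly over reported
  per-strategy costs and QALYs when a full parameter bundle is not the
  object of interest.

## Microsimulation oracle

`simulate_cohort` draws per-patient annual histories: independent Poisson
counts per severity class (equivalent to a Poisson total thinned 95/4/1),
binomial follow-up contacts and glucagon use, a multinomial severe-event
care-setting split, Bernoulli ambulance/EMS glucagon on transported
pathways, Bernoulli(0.20) death per hospitalization, and Bernoulli
day/night labels for disutilities. It emulates the model's own stochastic
assumptions — it is an internal-consistency oracle, not real-world claims
data: it has no within-year event dependence, no patient heterogeneity
beyond the two cohort profiles, and no seasonal or secular structure, so
agreement demonstrates the correctness of the closed-form expectations,
not external validity. The acceptance suite verifies agreement of
empirical mean cost and QALY with the analytic values within 3 standard
errors at n = 200,000 patient-years for all 24 strategy × cohort × country
cells (a ~7-second vectorized computation), plus convergence of the
severity mix to 95/4/1. The record-keeping mode (`keep_events=True`)
produces explicit per-event histories for small cohorts and derives the
aggregate arrays from the same draws.

## Numerical choices

- Reported rates use half-up rounding (ties away from zero) to 2 decimals;
  all internal arithmetic is double precision.
- Probability-vector validation uses an absolute tolerance of 1e-9 on the
  sum; ICER tie detection uses a relative 1e-12 on the deltas.
- QALYs are floored at zero (active only in pathological configurations).
- Person-count splits round the smaller group and assign the remainder, so
  partitions conserve totals exactly.
- All randomness flows through `numpy.random.Generator` seeded explicitly;
  identical seeds give bitwise-identical PSA and simulation output.

## Problem sizes

Default analysis sizes: 1,000 PSA iterations per cell (the convention of
the original analysis), 200,000 patient-years per microsimulation oracle
cell, 41-point CEAC grids over [0, 2·WTP]. The full test suite, including
the 24-cell oracle sweep, runs in well under a minute on one CPU.

## Known limitations

- The packaged unit costs and disutilities are calibrated stand-ins (see
  above); population dollar figures inherit their approximation.
- The reported source tables contain internal inconsistencies (the
  insulin/GLP-1 severity convention; one headline total that is not the
  sum of its components; a digit transposition in the combined U.S.
  population cost). The package follows the single convention that
  reproduces the majority of cells, reports computed sums, and logs the
  discrepancies at warning level in the CLI.
- No efficacy differences, adherence, combination therapy, long-term
  complications, or time preference (the horizon is one year).
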