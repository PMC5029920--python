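# hypoecon

Decision-analytic costing of drug-induced hypoglycemia in older adults with
type 2 diabetes.

Hypoglycemia is the dominant harm of glucose-lowering therapy in people aged
65 and over, and its costs — ambulance calls, emergency visits,
hospitalizations, lost quality of life — are routinely left out of
value-based prescribing arguments. `hypoecon` implements an annual
decision-tree model that quantifies those costs for six medication classes
(metformin, sulfonylureas, DPP-4 inhibitors, thiazolidinediones, GLP-1
receptor agonists, basal insulin), two age cohorts (65–79 and 80+) and two
payer perspectives (U.S. Medicare, Canadian public), for health economists
and formulary committees who need per-person and population-level numbers.

## The model

The annual rate of mild hypoglycemia for a medication class with base rate
*b* (events/person-year) is a validated multiplicative risk equation over
the cohort's clinical averages:

```
rate_mild = b · 1.037^(min(dur, 20) − 9)
              · 0.82^(A1c − 7)
              · 0.95^(clamp(BMI, 21, 35) − 33)
              · 22700^(clamp(GFR, 15, 60)^−0.86655 − 60^−0.86655)
```

with diabetes duration in years, HbA1c in %, BMI in kg/m², GFR in ml/min.
Moderate and severe events are added so that the severity mix of all events
is 95% mild / 4% moderate / 1% severe. Each severity class carries an
expected per-event cost (follow-up contacts, glucagon, and for severe
events a five-way split over care settings with ambulance transport and a
20% in-hospital fatality risk on the hospitalization branch) and a
day/night-weighted per-event utility decrement. Per-person annual cost is
therapy cost plus rate-weighted event costs; QALYs are the base utility of
uncomplicated diabetes (0.844) minus rate-weighted disutilities and a
fatality adjustment, with fatal hospitalizations treated as thinned Poisson
events (`p_fatal = 1 − exp(−rate_severe · 0.24 · 0.20)`).

Strategies are compared pairwise as incremental cost-effectiveness ratios
ICER = ΔC/ΔE with dominance classification, against a per-capita-GDP
willingness-to-pay threshold (US$54,630; CAN$53,891). One-way deterministic
(tornado) and 1,000-iteration probabilistic sensitivity analyses (gamma
distributions for rates, costs and disutilities, beta for the base utility,
±25% of base value as a 95% interval) feed cost-effectiveness acceptability
curves. Budget impact scales per-person outcomes by national user counts
with three disinvestment scenarios. A patient-level microsimulation
realizes the same tree as Poisson/Bernoulli/categorical draws and serves as
a brute-force oracle for every closed-form expectation.

Unit costs and per-event disutilities in the packaged bundles are
**synthetic, calibration-derived defaults** (see `docs/methods.md`); they
are configuration data, meant to be replaced with payer fee-schedule values.

## Worked example

```python
from hypoecon import HypoglycemiaCostModel

results = HypoglycemiaCostModel.from_country("US").fit()
print(results.summary())
```

```
Drug-induced hypoglycemia decision model — US (2015 US$)
WTP threshold: 54,630 per QALY

cohort   strategy         mild  mod/sev     hypo$  therapy$    total$    QALY
-----------------------------------------------------------------------------
65-79    metformin        1.37     0.07       100       333       433   0.831
65-79    sulfonylurea     4.12     0.22       299       410       709   0.805
65-79    dpp4             1.37     0.07       100      2207      2307   0.831
65-79    tzd              1.37     0.07       100       896       996   0.831
65-79    glp1             1.79     0.09       129      2202      2331   0.827
65-79    basal_insulin    8.65     0.46       627       905      1532   0.761
80plus   metformin        1.91     0.10       139       333       472   0.826
80plus   sulfonylurea     5.73     0.30       416       410       826   0.789
80plus   dpp4             1.91     0.10       139      2207      2346   0.826
80plus   tzd              1.91     0.10       139       896      1035   0.826
80plus   glp1             2.48     0.13       180      2202      2382   0.820
80plus   basal_insulin   12.04     0.63       873       905      1778   0.729
```

Reading the metformin 65–79 row: such a patient is expected to have 1.37
mild and 0.07 moderate/severe hypoglycemic events per year, costing $100 in
event-related care on top of $333 of therapy, and accruing 0.831 QALYs out
of a ceiling of 0.844. Basal insulin users aged 80+ average over 12 events
per year, losing more than a tenth of a QALY relative to metformin users.

Incremental analysis and population scaling:

```python
results.icer_table("sulfonylurea")      # dominance + ICERs per cohort
results.population_costs()              # national annual hypoglycemia cost
results.psa("65-79")                    # 1,000-iteration PSA
results.simulate("metformin", "65-79", n=10_000, seed=1)  # microsim oracle
```

The same analyses are exposed as a CLI: `hypoecon rates`, `hypoecon cea`,
`hypoecon dsa`, `hypoecon psa`, `hypoecon population` (see `--help`; every
command writes CSV outputs plus a JSON run manifest and is byte-reproducible
given the same config, flags and seed).

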