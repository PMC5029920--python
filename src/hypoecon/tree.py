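"""Closed-form evaluation of the annual decision tree.

For one strategy x cohort x country the tree collapses, by linearity of
expectation, to products of annual event rates with expected per-event
costs and disutilities:

* mild event — possible healthcare-professional contact (with a glucose
  assay) plus extra self-monitoring tests;
* moderate event — the mild follow-up plus a possible glucagon injection;
* severe event — one of five care settings (GP, nurse practitioner,
  outpatient practice, emergency room, hospitalization), with ambulance use
  and EMS glucagon on the transported pathways, plus the universal
  follow-up;
* fatality — a fraction of hospitalized severe events is fatal; fatal
  hospitalizations are treated as thinned Poisson events, so the annual
  probability of death is ``1 - exp(-rate)``.

QALYs start from the base utility of uncomplicated diabetes and subtract
day/night-weighted per-event disutilities and, for fatal years, a
configurable fraction of the base utility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import (
    ParameterBundle,
    ResourceUseModel,
    UnitCostTable,
    UtilityModel,
    DrugStrategy,
    CohortProfile,
)
from .risk import RateResult, rates_for

__all__ = [
    "EventCostBreakdown",
    "StrategyOutcome",
    "event_cost_mild",
    "event_cost_moderate",
    "event_cost_severe",
    "annual_hypo_cost",
    "annual_therapy_cost",
    "p_fatal",
    "expected_qaly",
    "evaluate_strategy",
    "evaluate_all",
]


@dataclass(frozen=True)
class EventCostBreakdown:
    """Expected cost per event of each severity, with resource components."""

    mild_cost: float
    moderate_cost: float
    severe_cost: float
    components: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-person annual expectations for one strategy x cohort x country."""

    strategy: str
    cohort: str
    country: str
    currency: str
    rates: RateResult
    annual_hypo_cost: float
    annual_therapy_cost: float
    qaly: float
    p_fatal: float

    @property
    def annual_total_cost(self) -> float:
        return self.annual_hypo_cost + self.annual_therapy_cost


def _followup_cost(resource: ResourceUseModel, costs: UnitCostTable) -> float:
    """Expected post-event follow-up cost, identical for every severity."""
    contact = resource.p_hcp_contact_any_event * (
        costs.gp_visit + resource.p_assay_per_contact * costs.blood_glucose_assay
    )
    smbg = resource.n_extra_smbg_after_event * (costs.smbg_strip + costs.smbg_lancet)
    return contact + smbg


def event_cost_mild(resource: ResourceUseModel, costs: UnitCostTable) -> float:
    """Expected cost of one mild event (follow-up care only)."""
    return _followup_cost(resource, costs)


def event_cost_moderate(resource: ResourceUseModel, costs: UnitCostTable) -> float:
    """Expected cost of one moderate event (follow-up plus possible glucagon)."""
    return _followup_cost(resource, costs) + resource.p_glucagon_moderate * costs.glucagon_kit


def event_cost_severe(resource: ResourceUseModel, costs: UnitCostTable) -> float:
    """Expected cost of one severe event.

    Branch-weighted care-setting cost, plus ambulance and EMS glucagon on
    the transported pathways (emergency room, hospitalization), plus the
    universal follow-up.
    """
    b = resource.severe_branch
    branch = (
        b.gp * costs.gp_visit
        + b.np * costs.np_visit
        + b.outpatient * costs.outpatient_visit
        + b.er_only * costs.er_visit
        + b.hospitalization * costs.hospitalization
    )
    p_transport = b.er_only + b.hospitalization
    ems = p_transport * (
        resource.p_ambulance_severe_transport * costs.ambulance
        + resource.p_glucagon_severe * costs.glucagon_kit
    )
    return branch + ems + _followup_cost(resource, costs)


def event_cost_breakdown(
    resource: ResourceUseModel, costs: UnitCostTable
) -> EventCostBreakdown:
    b = resource.severe_branch
    p_transport = b.er_only + b.hospitalization
    components = {
        "followup": _followup_cost(resource, costs),
        "glucagon_moderate": resource.p_glucagon_moderate * costs.glucagon_kit,
        "severe_gp": b.gp * costs.gp_visit,
        "severe_np": b.np * costs.np_visit,
        "severe_outpatient": b.outpatient * costs.outpatient_visit,
        "severe_er": b.er_only * costs.er_visit,
        "severe_hospitalization": b.hospitalization * costs.hospitalization,
        "severe_ambulance": p_transport
        * resource.p_ambulance_severe_transport
        * costs.ambulance,
        "severe_glucagon": p_transport * resource.p_glucagon_severe * costs.glucagon_kit,
    }
    return EventCostBreakdown(
        mild_cost=event_cost_mild(resource, costs),
        moderate_cost=event_cost_moderate(resource, costs),
        severe_cost=event_cost_severe(resource, costs),
        components=components,
    )


def annual_hypo_cost(
    rates: RateResult, resource: ResourceUseModel, costs: UnitCostTable
) -> float:
    """Expected annual hypoglycemia-attributable cost per person."""
    return (
        rates.mild * event_cost_mild(resource, costs)
        + rates.moderate * event_cost_moderate(resource, costs)
        + rates.severe * event_cost_severe(resource, costs)
    )


def annual_therapy_cost(strategy: DrugStrategy, costs: UnitCostTable) -> float:
    """Annual cost of therapy: drug, routine monitoring, needles, monitor."""
    monitoring = 365.0 * strategy.daily_smbg_tests * (costs.smbg_strip + costs.smbg_lancet)
    injections = 365.0 * strategy.daily_injections * costs.needle
    return strategy.annual_drug_cost + monitoring + injections + costs.home_monitor_annual


def p_fatal(rates: RateResult, resource: ResourceUseModel) -> float:
    """Annual probability of a fatal hypoglycemia hospitalization.

    Fatal hospitalizations are a thinned Poisson stream with rate
    ``severe_rate * p_hospitalization * p_death``, so the probability of at
    least one over the year is ``1 - exp(-rate)``.
    """
    lam = (
        rates.severe
        * resource.severe_branch.hospitalization
        * resource.p_death_given_hospitalization
    )
    return 1.0 - math.exp(-lam)


def expected_qaly(
    rates: RateResult, utilities: UtilityModel, p_fatal_year: float
) -> float:
    """Expected QALYs accrued over the year, floored at zero."""
    loss_mild = rates.mild * utilities.effective_disutility("mild")
    loss_modsev = rates.moderate_severe * utilities.effective_disutility(
        "moderate_severe"
    )
    loss_fatal = (
        p_fatal_year * utilities.fatal_event_year_fraction_lost * utilities.u_base
    )
    return max(utilities.u_base - loss_mild - loss_modsev - loss_fatal, 0.0)


def evaluate_strategy(
    strategy: DrugStrategy | str,
    cohort: CohortProfile | str,
    bundle: ParameterBundle,
) -> StrategyOutcome:
    """Evaluate the full tree for one strategy x cohort under a bundle."""
    if isinstance(strategy, str):
        strategy = bundle.strategies[strategy]
    if isinstance(cohort, str):
        cohort = bundle.cohorts[cohort]
    rates = rates_for(strategy, cohort, bundle.risk_constants, bundle.severity)
    fatal = p_fatal(rates, bundle.resource_use)
    return StrategyOutcome(
        strategy=strategy.name,
        cohort=cohort.label,
        country=bundle.country,
        currency=bundle.currency,
        rates=rates,
        annual_hypo_cost=annual_hypo_cost(
            rates, bundle.resource_use, bundle.unit_costs
        ),
        annual_therapy_cost=annual_therapy_cost(strategy, bundle.unit_costs),
        qaly=expected_qaly(rates, bundle.utilities, fatal),
        p_fatal=fatal,
    )


def evaluate_all(bundle: ParameterBundle) -> list[StrategyOutcome]:
    """Outcomes for every strategy x cohort in the bundle."""
    return [
        evaluate_strategy(strategy, cohort, bundle)
        for cohort in bundle.cohorts.values()
        for strategy in bundle.strategies.values()
    ]
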