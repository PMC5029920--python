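"""Decision-tree expectations: event costs, therapy cost, fatality, QALYs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hypoecon.params import (
    DrugStrategy,
    ResourceUseModel,
    UnitCostTable,
    UtilityModel,
)
from hypoecon.risk import RateResult
from hypoecon.tree import (
    annual_hypo_cost,
    annual_therapy_cost,
    evaluate_all,
    evaluate_strategy,
    event_cost_mild,
    event_cost_moderate,
    event_cost_severe,
    expected_qaly,
    p_fatal,
)

RU = ResourceUseModel()


def make_costs(**overrides) -> UnitCostTable:
    base = dict(
        country="US",
        currency="2015 US$",
        gp_visit=0.0,
        np_visit=0.0,
        outpatient_visit=0.0,
        er_visit=0.0,
        hospitalization=0.0,
        ambulance=0.0,
        glucagon_kit=0.0,
        blood_glucose_assay=0.0,
        smbg_strip=0.0,
        smbg_lancet=0.0,
        needle=0.0,
        home_monitor_annual=0.0,
    )
    base.update(overrides)
    return UnitCostTable(**base)


# The worked unit-cost table used in the hand-derived expectations below.
HAND_COSTS = make_costs(
    gp_visit=100.0,
    np_visit=80.0,
    outpatient_visit=150.0,
    er_visit=500.0,
    hospitalization=10000.0,
    ambulance=400.0,
    glucagon_kit=200.0,
    blood_glucose_assay=10.0,
    smbg_strip=1.0,
    smbg_lancet=0.5,
)


class TestEventCosts:
    def test_zero_costs_give_zero(self):
        zero = make_costs()
        assert event_cost_mild(RU, zero) == 0.0
        assert event_cost_moderate(RU, zero) == 0.0
        assert event_cost_severe(RU, zero) == 0.0

    def test_mild_hand_value(self):
        # 0.14 x (100 + 10) + 3.9 x 1.5
        assert event_cost_mild(RU, HAND_COSTS) == pytest.approx(21.25)

    def test_moderate_hand_value(self):
        assert event_cost_moderate(RU, HAND_COSTS) == pytest.approx(25.25)
        assert event_cost_moderate(RU, make_costs(gp_visit=100.0)) == event_cost_mild(
            RU, make_costs(gp_visit=100.0)
        )

    def test_severe_hand_value(self):
        # branch 2551.4 + EMS add-on 184.5 + follow-up 21.25
        assert event_cost_severe(RU, HAND_COSTS) == pytest.approx(2757.15)

    def test_severe_degenerate_hospitalization_branch(self):
        ru = RU.model_copy(deep=True)
        object.__setattr__(
            ru, "severe_branch",
            type(RU.severe_branch)(gp=0, np=0, outpatient=0, er_only=0, hospitalization=1),
        )
        expected = (
            HAND_COSTS.hospitalization
            + HAND_COSTS.ambulance
            + 0.25 * HAND_COSTS.glucagon_kit
            + event_cost_mild(ru, HAND_COSTS)
        )
        assert event_cost_severe(ru, HAND_COSTS) == pytest.approx(expected)

    def test_ordering_and_linearity(self):
        doubled = make_costs(
            **{
                f: 2 * getattr(HAND_COSTS, f)
                for f in (
                    "gp_visit", "np_visit", "outpatient_visit", "er_visit",
                    "hospitalization", "ambulance", "glucagon_kit",
                    "blood_glucose_assay", "smbg_strip", "smbg_lancet",
                )
            }
        )
        assert event_cost_severe(RU, HAND_COSTS) >= event_cost_moderate(RU, HAND_COSTS)
        assert event_cost_moderate(RU, HAND_COSTS) >= event_cost_mild(RU, HAND_COSTS)
        for fn in (event_cost_mild, event_cost_moderate, event_cost_severe):
            assert fn(RU, doubled) == pytest.approx(2 * fn(RU, HAND_COSTS))


class TestAnnualCosts:
    def test_zero_rates_give_zero(self):
        assert annual_hypo_cost(RateResult(0, 0, 0), RU, HAND_COSTS) == 0.0

    def test_hand_value(self):
        rates = RateResult(mild=1.0, moderate=0.04, severe=0.01)
        assert annual_hypo_cost(rates, RU, HAND_COSTS) == pytest.approx(49.83, abs=5e-3)

    def test_therapy_cost_hand_value(self):
        strategy = DrugStrategy(
            name="basal_insulin",
            base_rate=6.3,
            daily_smbg_tests=2.08,
            daily_injections=1.0,
            annual_drug_cost=300.0,
        )
        costs = make_costs(smbg_strip=1.0, smbg_lancet=0.5, needle=0.2, home_monitor_annual=50.0)
        assert annual_therapy_cost(strategy, costs) == pytest.approx(1561.8)

    def test_therapy_structural_difference(self, us_bundle):
        uc = us_bundle.unit_costs
        met = annual_therapy_cost(us_bundle.strategies["metformin"], uc)
        dpp4 = annual_therapy_cost(us_bundle.strategies["dpp4"], uc)
        delta_drug = (
            us_bundle.strategies["dpp4"].annual_drug_cost
            - us_bundle.strategies["metformin"].annual_drug_cost
        )
        assert dpp4 - met == pytest.approx(delta_drug)

    @given(field_idx=st.integers(0, 11), factor=st.floats(1.5, 4.0))
    def test_hypo_cost_linear_in_every_unit_cost(self, us_bundle, field_idx, factor):
        """Scaling any single unit cost scales its contribution linearly."""
        fields = [
            "gp_visit", "np_visit", "outpatient_visit", "er_visit",
            "hospitalization", "ambulance", "glucagon_kit", "blood_glucose_assay",
            "smbg_strip", "smbg_lancet", "needle", "home_monitor_annual",
        ]
        field = fields[field_idx]
        rates = RateResult(mild=1.3736, moderate=0.0578, severe=0.0145)
        uc = us_bundle.unit_costs
        base_val = getattr(uc, field)
        c0 = annual_hypo_cost(rates, RU, uc.model_copy(update={field: 0.0}))
        c1 = annual_hypo_cost(rates, RU, uc)
        c2 = annual_hypo_cost(rates, RU, uc.model_copy(update={field: factor * base_val}))
        # linear: f(k*x) - f(0) = k * (f(x) - f(0))
        assert c2 - c0 == pytest.approx(factor * (c1 - c0), rel=1e-9)


class TestFatality:
    def test_zero_severe_rate(self):
        assert p_fatal(RateResult(1.0, 0.04, 0.0), RU) == 0.0

    def test_closed_form(self):
        rates = RateResult(mild=0.95, moderate=0.04, severe=0.01)
        expected = 1.0 - math.exp(-0.01 * 0.24 * 0.20)
        assert p_fatal(rates, RU) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.00048, abs=1e-6)

    def test_limit_to_one(self):
        assert p_fatal(RateResult(0, 0, 1e9), RU) == pytest.approx(1.0)

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_monotone_in_severe_rate(self, a, b):
        lo, hi = sorted([a, b])
        assert p_fatal(RateResult(0, 0, lo), RU) <= p_fatal(RateResult(0, 0, hi), RU)


class TestQALY:
    def test_no_events_no_fatality_gives_base_utility(self, us_bundle):
        q = expected_qaly(RateResult(0, 0, 0), us_bundle.utilities, 0.0)
        assert q == 0.844

    def test_published_metformin_value(self, us_bundle):
        outcome = evaluate_strategy("metformin", "65-79", us_bundle)
        assert round(outcome.qaly, 3) == 0.831

    def test_doubling_disutilities_weakly_decreases(self, us_bundle):
        rates = RateResult(1.37, 0.058, 0.014)
        ut = us_bundle.utilities
        doubled = ut.model_copy(deep=True)
        d = doubled.disutility_per_event
        for f in type(d).model_fields:
            object.__setattr__(d, f, 2 * getattr(d, f))
        assert expected_qaly(rates, doubled, 0.001) <= expected_qaly(rates, ut, 0.001)

    def test_floor_at_zero(self, us_bundle):
        q = expected_qaly(RateResult(1e6, 0, 0), us_bundle.utilities, 0.0)
        assert q == 0.0


class TestEvaluate:
    def test_24_outcomes_satisfy_invariants(self, us_bundle, ca_bundle):
        outcomes = evaluate_all(us_bundle) + evaluate_all(ca_bundle)
        assert len(outcomes) == 24
        for o in outcomes:
            assert o.annual_total_cost == pytest.approx(
                o.annual_hypo_cost + o.annual_therapy_cost
            )
            assert 0.0 <= o.qaly <= 0.844
            assert 0.0 <= o.p_fatal <= 1.0
            assert o.rates.total > 0

    def test_same_rate_classes_share_rates_and_qalys(self, bundle):
        for cohort in bundle.cohorts:
            met = evaluate_strategy("metformin", cohort, bundle)
            for other in ("dpp4", "tzd"):
                o = evaluate_strategy(other, cohort, bundle)
                assert o.rates == met.rates
                assert o.qaly == pytest.approx(met.qaly)

    def test_qaly_ordering_mirrors_event_rates(self, bundle):
        for cohort in bundle.cohorts:
            insulin = evaluate_strategy("basal_insulin", cohort, bundle)
            su = evaluate_strategy("sulfonylurea", cohort, bundle)
            met = evaluate_strategy("metformin", cohort, bundle)
            assert insulin.qaly < su.qaly < met.qaly

    def test_older_cohort_has_higher_rates_and_lower_qalys(self, bundle):
        for name in bundle.strategies:
            young = evaluate_strategy(name, "65-79", bundle)
            old = evaluate_strategy(name, "80plus", bundle)
            assert old.rates.total > young.rates.total
            assert old.qaly < young.qaly
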