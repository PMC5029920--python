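"""Tornado DSA, PSA sampling conventions, and acceptability curves."""

import numpy as np
import pytest

from hypoecon.benchmarks import reference_outcomes, reference_wtp
from hypoecon.cea import icer
from hypoecon.sensitivity import (
    PSASpec,
    acceptability_at,
    ceac,
    default_psa_parameters,
    get_parameter,
    one_way_dsa,
    psa_from_summary,
    run_psa,
    sample_parameters,
    set_parameter,
)
from hypoecon.tree import evaluate_strategy


class TestParameterPaths:
    def test_get_and_set(self, us_bundle):
        assert get_parameter(us_bundle, "utilities.u_base") == 0.844
        assert get_parameter(us_bundle, "strategies.basal_insulin.base_rate") == 6.3
        b = us_bundle.copy_deep()
        set_parameter(b, "unit_costs.hospitalization", 1.0)
        assert b.unit_costs.hospitalization == 1.0
        assert us_bundle.unit_costs.hospitalization != 1.0

    def test_unresolvable_path(self, us_bundle):
        with pytest.raises(KeyError):
            get_parameter(us_bundle, "strategies.metformin.nonexistent")
        with pytest.raises(KeyError):
            get_parameter(us_bundle, "unit_costs")


class TestTornado:
    def test_degenerate_range_gives_zero_spread(self, us_bundle):
        entries = one_way_dsa(
            us_bundle,
            [("strategies.dpp4.annual_drug_cost", 2055.20, 2055.20)],
            "dpp4",
            "sulfonylurea",
            "65-79",
        )
        assert entries[0].spread == 0.0

    def test_default_range_is_plus_minus_25_percent(self, us_bundle):
        entries = one_way_dsa(
            us_bundle,
            ["strategies.dpp4.annual_drug_cost"],
            "dpp4",
            "sulfonylurea",
            "65-79",
        )
        base = us_bundle.strategies["dpp4"].annual_drug_cost
        assert entries[0].low_value == pytest.approx(0.75 * base)
        assert entries[0].high_value == pytest.approx(1.25 * base)

    def test_drug_cost_moves_icer_monotonically(self, us_bundle):
        entries = one_way_dsa(
            us_bundle,
            ["strategies.dpp4.annual_drug_cost"],
            "dpp4",
            "sulfonylurea",
            "65-79",
        )
        e = entries[0]
        base = icer(
            evaluate_strategy("dpp4", "65-79", us_bundle),
            evaluate_strategy("sulfonylurea", "65-79", us_bundle),
            us_bundle.settings,
        ).icer_value
        assert e.icer_at_low < base < e.icer_at_high

    def test_entries_sorted_by_spread_regardless_of_order(self, us_bundle):
        params = [
            "strategies.dpp4.annual_drug_cost",
            "unit_costs.smbg_lancet",
            "strategies.sulfonylurea.base_rate",
        ]
        fwd = one_way_dsa(us_bundle, params, "dpp4", "sulfonylurea", "65-79")
        rev = one_way_dsa(us_bundle, params[::-1], "dpp4", "sulfonylurea", "65-79")
        assert [e.parameter for e in fwd] == [e.parameter for e in rev]
        spreads = [e.spread for e in fwd]
        assert spreads == sorted(spreads, reverse=True)

    def test_unresolvable_parameter_raises(self, us_bundle):
        with pytest.raises(KeyError):
            one_way_dsa(us_bundle, ["unit_costs.bogus"], "dpp4", "sulfonylurea", "65-79")


class TestSampling:
    def test_seed_determinism(self, us_bundle):
        spec = PSASpec(n_iterations=5, seed=42)
        a = sample_parameters(us_bundle, spec)
        b = sample_parameters(us_bundle, spec)
        for x, y in zip(a, b):
            assert x == y

    def test_gamma_moments(self, us_bundle):
        """Mean within 1% of base, sd consistent with the +/-25%-as-95% rule."""
        spec = PSASpec(n_iterations=10_000, seed=7)
        path = "unit_costs.hospitalization"
        base = get_parameter(us_bundle, path)
        sampled = sample_parameters(us_bundle, spec, gamma_paths=[path], beta_paths=[])
        draws = np.array([get_parameter(b, path) for b in sampled])
        assert draws.mean() == pytest.approx(base, rel=0.01)
        assert draws.std() == pytest.approx(0.25 * base / 1.96, rel=0.05)
        assert (draws > 0).all()

    def test_u_base_never_exceeds_one(self, us_bundle):
        spec = PSASpec(n_iterations=5_000, seed=3)
        sampled = sample_parameters(
            us_bundle, spec, gamma_paths=[], beta_paths=["utilities.u_base"]
        )
        draws = np.array([b.utilities.u_base for b in sampled])
        assert (draws <= 1.0).all()
        assert draws.mean() == pytest.approx(0.844, rel=0.01)

    def test_nonpositive_base_held_fixed_with_warning(self, us_bundle):
        b = us_bundle.copy_deep()
        set_parameter(b, "strategies.metformin.annual_drug_cost", 0.0)
        with pytest.warns(UserWarning, match="held fixed"):
            sampled = sample_parameters(
                b,
                PSASpec(n_iterations=3, seed=0),
                gamma_paths=["strategies.metformin.annual_drug_cost"],
                beta_paths=[],
            )
        assert all(s.strategies["metformin"].annual_drug_cost == 0.0 for s in sampled)

    def test_default_parameter_set_covers_rates_costs_disutilities(self, us_bundle):
        gamma, beta = default_psa_parameters(us_bundle)
        assert "strategies.basal_insulin.base_rate" in gamma
        assert "unit_costs.hospitalization" in gamma
        assert "utilities.disutility_per_event.mild_daytime" in gamma
        assert beta == ["utilities.u_base"]


class TestPSA:
    def test_psa_shape_and_determinism(self, us_bundle):
        spec = PSASpec(n_iterations=20, seed=11)
        a = run_psa(us_bundle, spec, "65-79")
        b = run_psa(us_bundle, spec, "65-79")
        assert a.costs.shape == (20, 6)
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)

    def test_degenerate_psa_collapses_to_base_case(self, us_bundle):
        """With no sampled parameters every iteration equals the base case."""
        spec = PSASpec(n_iterations=1, seed=0)
        result = run_psa(us_bundle, spec, "65-79", gamma_paths=[], beta_paths=[])
        for j, name in enumerate(result.strategies):
            base = evaluate_strategy(name, "65-79", us_bundle)
            assert result.costs[0, j] == pytest.approx(base.annual_total_cost)
            assert result.qalys[0, j] == pytest.approx(base.qaly)

    def test_base_case_icer_inside_sampled_interval(self, us_bundle):
        spec = PSASpec(n_iterations=400, seed=5)
        result = run_psa(us_bundle, spec, "65-79")
        i = result.strategies.index("dpp4")
        j = result.strategies.index("sulfonylurea")
        icers = (result.costs[:, i] - result.costs[:, j]) / (
            result.qalys[:, i] - result.qalys[:, j]
        )
        base = icer(
            evaluate_strategy("dpp4", "65-79", us_bundle),
            evaluate_strategy("sulfonylurea", "65-79", us_bundle),
            us_bundle.settings,
        ).icer_value
        lo, hi = np.percentile(icers, [2.5, 97.5])
        assert lo < base < hi


class TestCEAC:
    def test_probabilities_sum_to_one_and_cheapest_wins_at_zero(self, us_bundle):
        spec = PSASpec(n_iterations=200, seed=9)
        result = run_psa(us_bundle, spec, "65-79")
        points = ceac(result, [0.0, 25_000.0, 54_630.0, 100_000.0])
        for p in points:
            assert sum(p.probability_cost_effective.values()) == pytest.approx(1.0)
        at_zero = points[0].probability_cost_effective
        assert max(at_zero, key=at_zero.get) == "metformin"

    def test_wtp_grid_must_increase(self, us_bundle):
        result = run_psa(us_bundle, PSASpec(n_iterations=5, seed=1), "65-79")
        with pytest.raises(ValueError, match="strictly increasing"):
            ceac(result, [1.0, 1.0])

    def test_summary_level_psa_matches_reference_shape(self):
        cell = reference_outcomes("US", "65-79")
        spec = PSASpec(n_iterations=300, seed=21)
        result = psa_from_summary(cell, spec)
        assert result.costs.shape == (300, 6)
        assert result.wtp_threshold == reference_wtp("US")
        accept = acceptability_at(result, result.wtp_threshold)
        assert sum(accept.values()) == pytest.approx(1.0)
        # strategies dominated by wide margins stay essentially unacceptable
        assert accept["basal_insulin"] < 0.01
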