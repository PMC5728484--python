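"""Ten-year scenario costing: incentives, one-sided management costs."""

import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from pheasim import (
    LandcoverComposition,
    ManagementScenario,
    UnitManagementCosts,
    agricultural_cost,
    composition_to_acres,
    gross_income,
    management_cost,
    total_cost,
)
from pheasim.economics import ACRES_PER_HECTARE


class TestAcresConversion:
    def test_full_township_in_acres(self):
        acres = composition_to_acres(LandcoverComposition({"crp": 1.0}), 9324.0)
        assert acres["crp"] == pytest.approx(9324 * 2.47105381)
        assert acres["crp"] == pytest.approx(23040.11, abs=0.1)

    def test_zero_proportion_is_zero_acres_and_linearity(self):
        half = composition_to_acres(LandcoverComposition({"trees": 0.4}), 9324.0)
        full = composition_to_acres(LandcoverComposition({"trees": 0.8}), 9324.0)
        assert composition_to_acres(LandcoverComposition({}), 9324.0)["trees"] == 0.0
        assert full["trees"] == pytest.approx(2 * half["trees"])

    def test_acres_partition_the_township(self):
        comp = LandcoverComposition({"row_crop": 0.37, "wetland": 0.05})
        acres = composition_to_acres(comp, 9324.0)
        assert sum(acres.values()) == pytest.approx(9324 * ACRES_PER_HECTARE)


class TestGrossIncome:
    def test_zero_landscape_earns_nothing(self, make_profile):
        assert gross_income({}, make_profile()) == 0.0

    def test_row_crop_revenue(self, make_profile):
        profile = make_profile(row_crop_yield=150.0, row_crop_price=4.0)
        assert gross_income({"row_crop": 100.0}, profile) == 60_000.0

    def test_rangeland_rents_not_crops(self, make_profile):
        profile = make_profile(pasture_rental=30.0)
        assert gross_income({"rangeland": 100.0}, profile) == 3_000.0

    def test_noncommercial_classes_earn_nothing(self, make_profile):
        acres = {"crp": 500.0, "trees": 200.0, "wetland": 100.0, "other": 50.0}
        assert gross_income(acres, make_profile()) == 0.0


class TestAgriculturalCost:
    def test_identity_scenario_costs_nothing(self, make_profile):
        acres = {"row_crop": 400.0, "crp": 100.0}
        assert agricultural_cost(acres, acres, make_profile()) == 0.0

    def test_row_crop_to_crp_conversion(self, make_profile):
        """100 acres of 150 bu/ac, $4/bu row crop into CRP at $100/ac/yr, 10 yr."""
        profile = make_profile(row_crop_yield=150.0, row_crop_price=4.0, crp_rental=100.0)
        baseline = {"row_crop": 100.0, "crp": 0.0}
        scenario = {"row_crop": 0.0, "crp": 100.0}
        cost = agricultural_cost(baseline, scenario, profile, horizon_years=10)
        assert cost == 600_000.0 + 100_000.0

    def test_crp_decrease_charges_no_contract(self, make_profile):
        profile = make_profile(crp_rental=100.0)
        cost = agricultural_cost({"crp": 100.0}, {"crp": 0.0}, profile, 10)
        assert cost == 0.0

    def test_charge_all_mode_prices_every_scenario_crp_acre(self, make_profile):
        profile = make_profile(crp_rental=100.0)
        cost = agricultural_cost(
            {"crp": 50.0}, {"crp": 80.0}, profile, 10, crp_charge="all"
        )
        assert cost == 80.0 * 100.0 * 10

    def test_income_difference_scales_linearly(self, make_profile):
        profile = make_profile(row_crop_yield=150.0, row_crop_price=4.0)
        one = agricultural_cost({"row_crop": 100.0}, {"row_crop": 0.0}, profile, 10)
        two = agricultural_cost({"row_crop": 200.0}, {"row_crop": 0.0}, profile, 10)
        assert two == 2 * one

    @settings(
        derandomize=True,
        max_examples=50,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        horizon=st.floats(min_value=0.5, max_value=50),
        base_rc=st.floats(min_value=0, max_value=1000),
        scen_crp=st.floats(min_value=0, max_value=1000),
    )
    def test_horizon_linearity(self, make_profile, horizon, base_rc, scen_crp):
        profile = make_profile()
        baseline = {"row_crop": base_rc}
        scenario = {"crp": scen_crp}
        single = agricultural_cost(baseline, scenario, profile, horizon)
        double = agricultural_cost(baseline, scenario, profile, 2 * horizon)
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_profitable_scenario_yields_negative_cost(self, make_profile):
        profile = make_profile(row_crop_yield=150.0, row_crop_price=4.0)
        cost = agricultural_cost({}, {"row_crop": 100.0}, profile, 10)
        assert cost == -600_000.0


class TestManagementCost:
    def test_tree_removal_rate(self):
        tree, wetland = management_cost({"trees": 11.0}, {"trees": 10.0})
        assert (tree, wetland) == (650.0, 0.0)

    def test_wetland_restoration_rate(self):
        tree, wetland = management_cost({"wetland": 5.0}, {"wetland": 6.0})
        assert (tree, wetland) == (0.0, 6250.0)

    def test_free_directions_cost_nothing(self):
        """Planting trees and draining wetlands are free by assumption."""
        tree, wetland = management_cost(
            {"trees": 10.0, "wetland": 6.0}, {"trees": 20.0, "wetland": 1.0}
        )
        assert (tree, wetland) == (0.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        base=st.floats(min_value=0, max_value=500),
        scen=st.floats(min_value=0, max_value=500),
    )
    def test_one_sidedness_bounds(self, base, scen):
        tree, wetland = management_cost(
            {"trees": base, "wetland": base}, {"trees": scen, "wetland": scen}
        )
        assert tree >= 0.0 and wetland >= 0.0
        if scen >= base:
            assert tree == 0.0
        if scen <= base:
            assert wetland == 0.0

    def test_negative_unit_costs_rejected(self):
        with pytest.raises(ValueError):
            UnitManagementCosts(tree_removal=-1.0)


class TestTotalCost:
    def test_identity_scenario_all_zero(self, make_profile):
        profile = make_profile()
        scenario = ManagementScenario(
            baseline=profile.mean_composition,
            scenario=profile.mean_composition,
            profile=profile,
        )
        breakdown = total_cost(scenario)
        assert breakdown.agricultural_cost == 0.0
        assert breakdown.tree_cost == 0.0
        assert breakdown.wetland_cost == 0.0
        assert breakdown.total == 0.0

    def test_combined_scenario_sums_component_oracles(self, make_profile):
        """100 ac row crop->CRP plus 10 ac tree removal and 2 ac new wetland."""
        total_acres = 9324 * ACRES_PER_HECTARE
        profile = make_profile(
            composition={
                "row_crop": 200 / total_acres,
                "trees": 30 / total_acres,
                "wetland": 5 / total_acres,
            },
            row_crop_yield=150.0,
            row_crop_price=4.0,
            crp_rental=100.0,
        )
        base = profile.mean_composition
        scen = base.replace(
            row_crop=-100 / total_acres,
            crp=100 / total_acres,
            trees=-10 / total_acres,
            wetland=2 / total_acres,
        )
        breakdown = total_cost(
            ManagementScenario(baseline=base, scenario=scen, profile=profile)
        )
        assert breakdown.agricultural_cost == pytest.approx(700_000.0)
        assert breakdown.tree_cost == pytest.approx(6_500.0)
        assert breakdown.wetland_cost == pytest.approx(12_500.0)
        assert breakdown.total == pytest.approx(719_000.0)
        assert breakdown.total == pytest.approx(
            breakdown.agricultural_cost + breakdown.tree_cost + breakdown.wetland_cost
        )

    def test_unit_invariance_acres_vs_proportions(self, make_profile):
        """Working in acres directly agrees with proportions->acres to 1e-6."""
        profile = make_profile(
            composition={"row_crop": 0.4, "trees": 0.1, "wetland": 0.02}
        )
        base = profile.mean_composition
        scen = base.replace(row_crop=-0.1, crp=0.1, trees=-0.05, wetland=0.01)
        via_scenario = total_cost(
            ManagementScenario(baseline=base, scenario=scen, profile=profile)
        )
        base_acres = composition_to_acres(base, 9324.0)
        scen_acres = composition_to_acres(scen, 9324.0)
        ag = agricultural_cost(base_acres, scen_acres, profile, 10.0)
        tree, wet = management_cost(base_acres, scen_acres)
        assert via_scenario.total == pytest.approx(ag + tree + wet, rel=1e-6)

    def test_summary_mentions_negative_income_note(self, make_profile):
        profile = make_profile(row_crop_yield=150.0, row_crop_price=4.0)
        base = profile.mean_composition
        scen = base.replace(row_crop=0.1)
        breakdown = total_cost(
            ManagementScenario(baseline=base, scenario=scen, profile=profile)
        )
        assert breakdown.agricultural_cost < 0
        assert "more profitable" in breakdown.summary()
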