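"""Ten-year cost of converting a baseline landscape into a scenario.

The cost of a management scenario has two parts, both expressed over a
horizon matching a typical CRP contract (10 years):

* **Agricultural incentive cost** — the gross income landowners forgo:
  (baseline gross income - scenario gross income) x horizon, plus the
  horizon cost of the CRP contracts the scenario creates
  (crp_rental x new CRP acres x horizon).  Gross income is crop acres x
  yield x price for row crop and small grain plus rangeland acres x
  pasture rental; CRP, trees, wetland and "other" earn landowners
  nothing here (the CRP rental is accounted in the contract term, never
  double-counted).  The difference may be negative if the scenario is
  more profitable than the baseline; it is reported as-is.

* **Habitat management cost** — one-sided by assumption: removing trees
  costs $650/acre but planting them is free (no forestry industry to
  pay, no cost assumed for natural increase), and restoring wetlands
  costs $6250/acre but draining them costs the manager nothing.

Total cost = agricultural + tree + wetland.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

from .composition import CLASSES, LandcoverComposition
from .profiles import CountyProfile

ACRES_PER_HECTARE = 2.47105381

DEFAULT_TOWNSHIP_AREA_HA = 9324.0
DEFAULT_HORIZON_YEARS = 10.0
DEFAULT_TREE_REMOVAL_PER_ACRE = 650.0
DEFAULT_WETLAND_RESTORATION_PER_ACRE = 6250.0

#: How to charge CRP contract rental: on the increase in CRP acres only
#: ("new", the default — baseline contracts are treated as sunk), or on
#: every scenario CRP acre ("all").
CrpChargeMode = Literal["new", "all"]


@dataclass(frozen=True)
class UnitManagementCosts:
    tree_removal: float = DEFAULT_TREE_REMOVAL_PER_ACRE  # $/acre
    wetland_restoration: float = DEFAULT_WETLAND_RESTORATION_PER_ACRE  # $/acre

    def __post_init__(self) -> None:
        if self.tree_removal < 0 or self.wetland_restoration < 0:
            raise ValueError("unit management costs must be >= 0")


@dataclass(frozen=True)
class ManagementScenario:
    """A baseline-to-scenario landcover conversion priced with county economics."""

    baseline: LandcoverComposition
    scenario: LandcoverComposition
    profile: CountyProfile
    township_area_ha: float = DEFAULT_TOWNSHIP_AREA_HA
    horizon_years: float = DEFAULT_HORIZON_YEARS

    def __post_init__(self) -> None:
        if self.township_area_ha <= 0:
            raise ValueError("township area must be > 0")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be > 0")


@dataclass(frozen=True)
class CostBreakdown:
    agricultural_cost: float  # $ over the horizon; may be negative
    tree_cost: float  # $
    wetland_cost: float  # $
    total: float = field(default=0.0)
    horizon_years: float = DEFAULT_HORIZON_YEARS
    county_id: str = ""

    def as_dict(self) -> dict:
        return {
            "agricultural_cost": self.agricultural_cost,
            "tree_cost": self.tree_cost,
            "wetland_cost": self.wetland_cost,
            "total": self.total,
            "horizon_years": self.horizon_years,
            "county_id": self.county_id,
        }

    def summary(self) -> str:
        """Human-readable cost panel."""
        sign_note = (
            " (negative: the scenario landscape is more profitable than the baseline)"
            if self.agricultural_cost < 0
            else ""
        )
        lines = [
            f"Cost of the specified management scenario over {self.horizon_years:g} years"
            + (f" (county {self.county_id})" if self.county_id else ""),
            f"  Agricultural incentive cost: ${self.agricultural_cost:,.2f}{sign_note}",
            f"  Tree removal cost:           ${self.tree_cost:,.2f}",
            f"  Wetland restoration cost:    ${self.wetland_cost:,.2f}",
            f"  Total cost:                  ${self.total:,.2f}",
        ]
        return "\n".join(lines)


def composition_to_acres(
    composition: LandcoverComposition, township_area_ha: float = DEFAULT_TOWNSHIP_AREA_HA
) -> dict[str, float]:
    """Convert class proportions to acres on a township of the given area."""
    if township_area_ha <= 0:
        raise ValueError("township area must be > 0")
    total_acres = township_area_ha * ACRES_PER_HECTARE
    return {name: composition[name] * total_acres for name in CLASSES}


def gross_income(acres: Mapping[str, float], profile: CountyProfile) -> float:
    """Annual collective gross income to landowners, $/yr."""
    return (
        acres.get("row_crop", 0.0) * profile.row_crop_yield * profile.row_crop_price
        + acres.get("small_grain", 0.0)
        * profile.small_grain_yield
        * profile.small_grain_price
        + acres.get("rangeland", 0.0) * profile.pasture_rental
    )


def agricultural_cost(
    baseline_acres: Mapping[str, float],
    scenario_acres: Mapping[str, float],
    profile: CountyProfile,
    horizon_years: float = DEFAULT_HORIZON_YEARS,
    crp_charge: CrpChargeMode = "new",
) -> float:
    """Incentive cost of the agricultural conversion over the horizon, $."""
    if horizon_years <= 0:
        raise ValueError("horizon must be > 0")
    income_diff = gross_income(baseline_acres, profile) - gross_income(
        scenario_acres, profile
    )
    if crp_charge == "new":
        crp_acres = max(0.0, scenario_acres.get("crp", 0.0) - baseline_acres.get("crp", 0.0))
    elif crp_charge == "all":
        crp_acres = scenario_acres.get("crp", 0.0)
    else:
        raise ValueError(f"crp_charge must be 'new' or 'all', got {crp_charge!r}")
    return income_diff * horizon_years + profile.crp_rental * crp_acres * horizon_years


def management_cost(
    baseline_acres: Mapping[str, float],
    scenario_acres: Mapping[str, float],
    costs: UnitManagementCosts | None = None,
) -> tuple[float, float]:
    """One-sided (tree removal, wetland restoration) costs, $."""
    costs = costs or UnitManagementCosts()
    tree_cost = (
        max(0.0, baseline_acres.get("trees", 0.0) - scenario_acres.get("trees", 0.0))
        * costs.tree_removal
    )
    wetland_cost = (
        max(0.0, scenario_acres.get("wetland", 0.0) - baseline_acres.get("wetland", 0.0))
        * costs.wetland_restoration
    )
    return tree_cost, wetland_cost


def total_cost(
    scenario: ManagementScenario,
    costs: UnitManagementCosts | None = None,
    crp_charge: CrpChargeMode = "new",
) -> CostBreakdown:
    """Full cost breakdown for a management scenario."""
    baseline_acres = composition_to_acres(scenario.baseline, scenario.township_area_ha)
    scenario_acres = composition_to_acres(scenario.scenario, scenario.township_area_ha)
    ag = agricultural_cost(
        baseline_acres,
        scenario_acres,
        scenario.profile,
        horizon_years=scenario.horizon_years,
        crp_charge=crp_charge,
    )
    tree, wetland = management_cost(baseline_acres, scenario_acres, costs)
    return CostBreakdown(
        agricultural_cost=ag,
        tree_cost=tree,
        wetland_cost=wetland,
        total=ag + tree + wetland,
        horizon_years=scenario.horizon_years,
        county_id=scenario.profile.county_id,
    )
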