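"""System nutrient budgets: inputs, productive outputs, surplus, efficiency.

For one accounting unit (a county, or the whole watershed), year, nutrient and
CAFE system, the budget is

    efficiency = productive_outputs / inputs          (NUE or PUE)
    surplus    = inputs - productive_outputs          (N_sur / P_sur)

A positive surplus is potential nutrient loss to the environment; a negative
surplus (efficiency above 1) means the system is drawing nutrients out of
storage -- for phosphorus this is "soil mining" of legacy P.

Which flow kinds count as a system's inputs and productive outputs is
configuration (:class:`SystemMapping`).  The default mapping encodes the
nesting of the four systems: moving downstream, recycled flows (manure applied
to cropland, locally fed crops) become internal, while imports and urban
inputs are added.  The Food system's productive output -- food reaching
consumers plus exports -- is expressed as supply minus processing/retail
waste, so output coefficients may be signed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import UNDEFINED, is_undefined, round_half_away
from .flow_model import CafeSystem, FlowKind, FlowTable, Nutrient

__all__ = [
    "SystemBudget",
    "SystemMapping",
    "SurplusRate",
    "DEFAULT_MAPPING",
    "system_budget",
    "budget_table",
    "efficiency_percent",
    "surplus_rate",
    "aggregate",
    "period_average",
    "BudgetContractError",
]

WATERSHED = "WATERSHED"


class BudgetContractError(ValueError):
    """Operands violate a budget-operation contract (mixed systems, empty window...)."""


@dataclass(frozen=True)
class SystemBudget:
    """Inputs, productive outputs and derived surplus/efficiency for one cell."""

    unit_id: str
    year: int
    nutrient: Nutrient
    system: CafeSystem
    inputs: float  # kg/yr
    productive_outputs: float  # kg/yr

    @property
    def surplus(self) -> float:
        """inputs - productive_outputs, kg/yr; negative values preserved."""
        return self.inputs - self.productive_outputs

    @property
    def efficiency(self) -> float:
        """productive_outputs / inputs; NaN when inputs == 0 (undefined)."""
        if self.inputs == 0:
            return UNDEFINED
        return self.productive_outputs / self.inputs

    @property
    def soil_mining(self) -> bool:
        """True when efficiency exceeds 1 (net extraction from stores)."""
        eff = self.efficiency
        return (not is_undefined(eff)) and eff > 1.0


@dataclass(frozen=True)
class SurplusRate:
    unit_id: str
    year: int
    nutrient: Nutrient
    system: CafeSystem
    rate_cropland: float  # kg ha-1 yr-1, surplus / cropland area (NaN if area 0)
    rate_land: float  # kg ha-1 yr-1, surplus / total land area


@dataclass(frozen=True)
class SystemMapping:
    """Per-system flow-kind coefficient maps for inputs and productive outputs.

    Coefficients on the input side must be positive; output-side coefficients
    may be negative to express net quantities (supply minus waste).  A flow
    kind may appear at most once per side within a system.
    """

    inputs: Mapping[CafeSystem, Mapping[FlowKind, float]]
    outputs: Mapping[CafeSystem, Mapping[FlowKind, float]]

    def __post_init__(self) -> None:
        for side in (self.inputs, self.outputs):
            for system, coeffs in side.items():
                CafeSystem(system)
                for kind in coeffs:
                    FlowKind(kind)
        for system, coeffs in self.inputs.items():
            if any(c <= 0 for c in coeffs.values()):
                raise BudgetContractError(f"non-positive input coefficient in {system!r}")

    def covers(self, system: CafeSystem) -> bool:
        return system in self.inputs and system in self.outputs


def _default_mapping() -> SystemMapping:
    F = FlowKind
    cropping_in = {
        F.mineral_fertilizer_cropland: 1.0,
        F.manure_applied_cropland: 1.0,
        F.biosolids_applied_cropland: 1.0,
        F.fixation_cropland: 1.0,
        F.deposition_cropland: 1.0,
    }
    # Downstream of Cropping, manure/biosolids recycling is internal.
    animal_in = {
        F.mineral_fertilizer_cropland: 1.0,
        F.fixation_cropland: 1.0,
        F.deposition_cropland: 1.0,
        F.feed_import: 1.0,
    }
    food_in = dict(animal_in, **{F.food_import: 1.0})
    eco_in = dict(food_in, **{F.urban_fertilizer: 1.0, F.urban_deposition_fixation: 1.0})
    return SystemMapping(
        inputs={
            CafeSystem.Cropping: cropping_in,
            CafeSystem.AnimalCrop: animal_in,
            CafeSystem.Food: food_in,
            CafeSystem.Ecosystem: eco_in,
        },
        outputs={
            CafeSystem.Cropping: {F.crop_harvest: 1.0},
            CafeSystem.AnimalCrop: {F.crop_harvest: 1.0, F.animal_products: 1.0},
            # Food reaching consumers + exports = total supply - processing/retail waste.
            CafeSystem.Food: {
                F.crop_harvest: 1.0,
                F.animal_products: 1.0,
                F.food_import: 1.0,
                F.food_processing_retail_waste: -1.0,
            },
            # Consumed food stays in the landscape (becomes human waste -> surplus).
            CafeSystem.Ecosystem: {F.food_export: 1.0},
        },
    )


DEFAULT_MAPPING = _default_mapping()


def _weighted_sum(df: pd.DataFrame, coeffs: Mapping[FlowKind, float]) -> float:
    total = 0.0
    by_flow = df.groupby("flow")["value_kg"].sum()
    for kind, coeff in coeffs.items():
        total += coeff * float(by_flow.get(FlowKind(kind).value, 0.0))
    return total


def system_budget(table: FlowTable, unit_id: str, year: int,
                  nutrient: Nutrient | str, system: CafeSystem,
                  mapping: SystemMapping = DEFAULT_MAPPING) -> SystemBudget:
    """Budget for one (unit, year, nutrient, system) cell.

    ``unit_id`` may be a county id, or :data:`WATERSHED` to sum over all
    counties in the table (also matches a literal "WATERSHED" unit id).
    """
    if not mapping.covers(system):
        raise BudgetContractError(f"mapping does not cover system {system!r}")
    nutrient = Nutrient(nutrient)
    if unit_id == WATERSHED and WATERSHED not in table.county_ids:
        df = table.select(None, year, nutrient)
    else:
        df = table.select(unit_id, year, nutrient)
    return SystemBudget(
        unit_id=unit_id,
        year=year,
        nutrient=nutrient,
        system=system,
        inputs=_weighted_sum(df, mapping.inputs[system]),
        productive_outputs=_weighted_sum(df, mapping.outputs[system]),
    )


def budget_table(table: FlowTable, mapping: SystemMapping = DEFAULT_MAPPING,
                 units: Sequence[str] | None = None,
                 years: Sequence[int] | None = None) -> pd.DataFrame:
    """All county budgets as a tidy DataFrame (one row per cell).

    Columns: unit_id, year, nutrient, system, inputs_kg, outputs_kg,
    surplus_kg, efficiency.
    """
    units = list(units) if units is not None else table.county_ids
    years = list(years) if years is not None else table.years
    rows = []
    for unit in units:
        for year in years:
            for nutrient in Nutrient:
                for system in CafeSystem:
                    b = system_budget(table, unit, year, nutrient, system, mapping)
                    rows.append(
                        {
                            "unit_id": unit,
                            "year": year,
                            "nutrient": nutrient.value,
                            "system": system.label,
                            "inputs_kg": b.inputs,
                            "outputs_kg": b.productive_outputs,
                            "surplus_kg": b.surplus,
                            "efficiency": b.efficiency,
                        }
                    )
    return pd.DataFrame(rows)


def efficiency_percent(budget: SystemBudget, digits: int = 0) -> float:
    """Efficiency as a percent, rounded half away from zero to ``digits``.

    Raises when inputs are zero (the ratio is undefined, never infinity).
    """
    if budget.inputs == 0:
        raise BudgetContractError(
            f"efficiency undefined: zero inputs for {budget.unit_id}/{budget.system.label}"
        )
    return round_half_away(100.0 * budget.productive_outputs / budget.inputs, digits)


def surplus_rate(budget: SystemBudget, cropland_area_ha: float,
                 land_area_ha: float) -> SurplusRate:
    """Surplus per hectare of cropland and of total land (sign preserved)."""
    rate_c = budget.surplus / cropland_area_ha if cropland_area_ha > 0 else UNDEFINED
    rate_l = budget.surplus / land_area_ha if land_area_ha > 0 else UNDEFINED
    return SurplusRate(budget.unit_id, budget.year, budget.nutrient, budget.system,
                       rate_c, rate_l)


def aggregate(budgets: Iterable[SystemBudget], unit_id: str = WATERSHED) -> SystemBudget:
    """Sum county budgets into one unit; efficiency recomputed from the sums.

    All operands must share year, nutrient and system.
    """
    budgets = list(budgets)
    if not budgets:
        raise BudgetContractError("cannot aggregate an empty collection of budgets")
    first = budgets[0]
    for b in budgets[1:]:
        if (b.year, b.nutrient, b.system) != (first.year, first.nutrient, first.system):
            raise BudgetContractError(
                "aggregate requires identical (year, nutrient, system) across budgets"
            )
    return SystemBudget(
        unit_id=unit_id,
        year=first.year,
        nutrient=first.nutrient,
        system=first.system,
        inputs=sum(b.inputs for b in budgets),
        productive_outputs=sum(b.productive_outputs for b in budgets),
    )


def period_average(table: FlowTable, window: tuple[int, int],
                   label_year: int | None = None) -> FlowTable:
    """Replace each flow by its arithmetic mean over ``window`` (inclusive).

    Flows are averaged first and ratios taken afterwards, so a period's
    efficiency is the ratio of mean flows (which generally differs from the
    mean of yearly efficiencies).  Covariates are averaged the same way.
    The result carries a single ``label_year`` (default: window start).
    """
    lo, hi = window
    years = [y for y in table.years if lo <= y <= hi]
    if lo > hi or not years:
        raise BudgetContractError(f"empty averaging window {window}")
    missing = set(range(lo, hi + 1)) - set(years)
    if missing:
        raise BudgetContractError(f"window {window} not covered by table; missing years {sorted(missing)}")
    if label_year is None:
        label_year = lo
    sub = table.flows[table.flows["year"].isin(years)]
    grouped = (
        sub.groupby(["county_id", "county_name", "state", "nutrient", "flow"], as_index=False)[
            "value_kg"
        ].mean()
    )
    grouped["year"] = label_year
    cov_sub = table.covariates[table.covariates["year"].isin(years)]
    cov = cov_sub.groupby("county_id", as_index=False)[
        ["cropland_area_ha", "land_area_ha", "population", "livestock_units"]
    ].mean()
    cov["year"] = label_year
    from .flow_model import COVARIATE_COLUMNS, FLOW_COLUMNS

    return FlowTable(grouped[FLOW_COLUMNS], cov[COVARIATE_COLUMNS])
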