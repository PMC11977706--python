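"""Theoretically recyclable waste and its potential to offset fertilizer.

Three waste streams beyond croplands carry nutrients that are not currently
recycled but in principle could substitute for mineral fertilizer:

* unrecycled manure (pasture-deposited manure excluded -- it is already on
  the land and not recoverable),
* food-processing and retail waste,
* human waste (municipal and industrial wastewater-treatment loads, combined
  sewer overflows, and septic runoff).

"Fertilizer demand" is operationalized as the current mineral fertilizer
input to cropland; no agronomic demand model is attempted.  An optional
per-component recovery multiplier lets users impose recovery efficiencies
below the theoretical 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import UNDEFINED, is_undefined
from .flow_model import FlowKind, FlowTable, Nutrient

__all__ = [
    "RecyclableInventory",
    "RecoveryFractions",
    "recyclable_inventory",
    "offset_percent",
    "classify_source_sink",
    "waste_composition",
    "INFINITE_OFFSET",
]

#: Sentinel for a positive recyclable total against zero fertilizer demand.
INFINITE_OFFSET = float("inf")

_HUMAN_WASTE_KINDS = (
    FlowKind.human_waste_municipal_wwtp,
    FlowKind.human_waste_industrial_wwtp,
    FlowKind.human_waste_cso,
    FlowKind.human_waste_septic,
)


@dataclass(frozen=True)
class RecoveryFractions:
    """Recovery efficiency multipliers per waste component (default: 1.0)."""

    manure: float = 1.0
    food: float = 1.0
    human: float = 1.0


@dataclass(frozen=True)
class RecyclableInventory:
    unit_id: str
    year: int
    nutrient: Nutrient
    manure_unrecycled: float  # kg/yr, never includes pasture-deposited manure
    food_waste: float  # kg/yr, processing + retail
    human_waste: float  # kg/yr, municipal + industrial WWTP + CSO + septic
    fertilizer_demand: float  # kg/yr, current cropland mineral fertilizer input

    @property
    def total(self) -> float:
        return self.manure_unrecycled + self.food_waste + self.human_waste


def recyclable_inventory(table: FlowTable, unit_id: str, year: int,
                         nutrient: Nutrient | str,
                         recovery: RecoveryFractions = RecoveryFractions()) -> RecyclableInventory:
    """Sum the recyclable components for a unit-year-nutrient.

    Missing flows count as 0 (the reader warns about them); pasture-deposited
    manure is never counted.
    """
    nutrient = Nutrient(nutrient)
    if unit_id == "WATERSHED" and "WATERSHED" not in table.county_ids:
        df = table.select(None, year, nutrient)
    else:
        df = table.select(unit_id, year, nutrient)
    by_flow = df.groupby("flow")["value_kg"].sum()

    def get(kind: FlowKind) -> float:
        return float(by_flow.get(kind.value, 0.0))

    return RecyclableInventory(
        unit_id=unit_id,
        year=year,
        nutrient=nutrient,
        manure_unrecycled=recovery.manure * get(FlowKind.manure_unrecycled),
        food_waste=recovery.food * get(FlowKind.food_processing_retail_waste),
        human_waste=recovery.human * sum(get(k) for k in _HUMAN_WASTE_KINDS),
        fertilizer_demand=get(FlowKind.mineral_fertilizer_cropland),
    )


def offset_percent(inv: RecyclableInventory) -> float:
    """Percent of mineral fertilizer input the recyclable total could avoid.

    Uncapped (values above 100 mean waste exceeds local demand).  Zero demand
    with a positive total yields the infinite-offset sentinel; 0/0 is
    undefined (NaN).
    """
    if inv.fertilizer_demand == 0:
        return UNDEFINED if inv.total == 0 else INFINITE_OFFSET
    return 100.0 * inv.total / inv.fertilizer_demand


def classify_source_sink(inv: RecyclableInventory) -> str:
    """"source" iff recyclable total strictly exceeds fertilizer demand."""
    return "source" if inv.total > inv.fertilizer_demand else "sink"


def waste_composition(inv: RecyclableInventory) -> dict[str, float]:
    """Component percentages of the recyclable total.

    Returns manure vs. food vs. human percentages plus the combined
    food+human share; manure + food + human sums to exactly 100.  Undefined
    (all NaN) when the total is 0.
    """
    if inv.total == 0:
        return {"manure_pct": UNDEFINED, "food_pct": UNDEFINED,
                "human_pct": UNDEFINED, "food_human_pct": UNDEFINED}
    manure = 100.0 * inv.manure_unrecycled / inv.total
    food = 100.0 * inv.food_waste / inv.total
    human = 100.0 * inv.human_waste / inv.total
    # reconcile float residue so the parts sum to exactly 100
    human = 100.0 - manure - food
    return {
        "manure_pct": manure,
        "food_pct": food,
        "human_pct": human,
        "food_human_pct": 100.0 - manure,
    }
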