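"""N:P ratio of system surpluses and its temporal trend counting.

Rising N:P ratios in the surplus signal a growing stoichiometric imbalance in
potential losses to receiving waters, a risk factor for harmful algal blooms.
Ratios are only defined where both surpluses are strictly positive -- the
indicator concerns the potential to reduce loading, so negative (mining)
surpluses are excluded rather than carried with sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .budget_engine import BudgetContractError, SystemBudget
from .flow_model import CafeSystem

__all__ = ["NPRatio", "np_ratio", "ratio_trend_counts", "watershed_np_ratio"]


@dataclass(frozen=True)
class NPRatio:
    unit_id: str
    year: int
    system: CafeSystem
    ratio: float | None  # None when invalid
    valid: bool
    reason: str | None = None  # "nonpositive-N" | "nonpositive-P" when invalid


def np_ratio(n_budget: SystemBudget, p_budget: SystemBudget) -> NPRatio:
    """N surplus / P surplus; invalid (with a reason) unless both are > 0."""
    if (n_budget.unit_id, n_budget.year, n_budget.system) != (
        p_budget.unit_id,
        p_budget.year,
        p_budget.system,
    ):
        raise BudgetContractError("np_ratio operands must share unit, year and system")
    n_sur, p_sur = n_budget.surplus, p_budget.surplus
    if n_sur <= 0:
        return NPRatio(n_budget.unit_id, n_budget.year, n_budget.system,
                       None, False, "nonpositive-N")
    if p_sur <= 0:
        return NPRatio(n_budget.unit_id, n_budget.year, n_budget.system,
                       None, False, "nonpositive-P")
    return NPRatio(n_budget.unit_id, n_budget.year, n_budget.system,
                   n_sur / p_sur, True)


def ratio_trend_counts(
    ratios_start: Iterable[NPRatio],
    ratios_end: Iterable[NPRatio],
) -> dict:
    """Count counties with increasing / decreasing N:P ratios per system.

    A county contributes to a system's counts only when its ratio is valid at
    both endpoints; exact equality ("unchanged") counts toward neither
    direction.  Also reports the joint counts of counties increasing
    (respectively decreasing) in all four systems simultaneously, over
    counties valid at both endpoints in all four.
    """
    start = _index(ratios_start)
    end = _index(ratios_end)

    per_system: dict[CafeSystem, dict[str, int]] = {}
    direction: dict[CafeSystem, dict[str, str]] = {}
    for system in CafeSystem:
        counts = {"increasing": 0, "decreasing": 0, "unchanged": 0, "excluded": 0}
        direction[system] = {}
        units = {u for (u, s) in start if s == system} | {u for (u, s) in end if s == system}
        if not units:
            continue
        for unit in units:
            r0 = start.get((unit, system))
            r1 = end.get((unit, system))
            if r0 is None or r1 is None or not (r0.valid and r1.valid):
                counts["excluded"] += 1
                continue
            if r1.ratio > r0.ratio:
                counts["increasing"] += 1
                direction[system][unit] = "increasing"
            elif r1.ratio < r0.ratio:
                counts["decreasing"] += 1
                direction[system][unit] = "decreasing"
            else:
                counts["unchanged"] += 1
                direction[system][unit] = "unchanged"
        per_system[system] = counts
    if not per_system:
        raise BudgetContractError("no overlapping counties between start and end ratios")

    joint_units = None
    for system in per_system:
        units = set(direction[system])
        joint_units = units if joint_units is None else joint_units & units
    joint_units = joint_units or set()
    joint_inc = sum(
        1 for u in joint_units if all(direction[s][u] == "increasing" for s in per_system)
    )
    joint_dec = sum(
        1 for u in joint_units if all(direction[s][u] == "decreasing" for s in per_system)
    )
    return {
        "per_system": {s.label: c for s, c in per_system.items()},
        "all_systems_increasing": joint_inc,
        "all_systems_decreasing": joint_dec,
    }


def watershed_np_ratio(
    n_budgets: Iterable[SystemBudget],
    p_budgets: Iterable[SystemBudget],
    positive_only_aggregation: bool = False,
) -> NPRatio:
    """Watershed N:P surplus ratio from county budgets for one system.

    Two aggregation modes:

    * default: sum all county surpluses (negative ones included) and take the
      ratio of the watershed totals -- consistent with watershed-total budget
      reporting;
    * ``positive_only_aggregation``: sum only counties with positive surplus
      for each nutrient separately before taking the ratio.  With widespread
      P soil mining the two modes diverge strongly (the positive-only
      numerator and denominator exclude the mining counties).
    """
    n_list = list(n_budgets)
    p_list = list(p_budgets)
    if not n_list or not p_list:
        raise BudgetContractError("watershed_np_ratio requires non-empty budget sets")
    system = n_list[0].system
    year = n_list[0].year
    for b in n_list + p_list:
        if b.system != system or b.year != year:
            raise BudgetContractError("watershed_np_ratio operands must share year and system")
    if positive_only_aggregation:
        n_sum = sum(b.surplus for b in n_list if b.surplus > 0)
        p_sum = sum(b.surplus for b in p_list if b.surplus > 0)
    else:
        n_sum = sum(b.surplus for b in n_list)
        p_sum = sum(b.surplus for b in p_list)
    if n_sum <= 0:
        return NPRatio("WATERSHED", year, system, None, False, "nonpositive-N")
    if p_sum <= 0:
        return NPRatio("WATERSHED", year, system, None, False, "nonpositive-P")
    return NPRatio("WATERSHED", year, system, n_sum / p_sum, True)


def _index(ratios: Iterable[NPRatio]) -> Mapping[tuple[str, CafeSystem], NPRatio]:
    out: dict[tuple[str, CafeSystem], NPRatio] = {}
    for r in ratios:
        out[(r.unit_id, r.system)] = r
    return out
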