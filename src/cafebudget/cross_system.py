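"""Cross-hierarchy comparisons between the four systems.

Moving downstream through the hierarchy the surplus typically grows; the
operations here quantify that growth: adjacent-system surplus changes,
attribution of the largest positive change, county-share metrics comparing
on-farm against beyond-farm surpluses and efficiencies, and counts of
counties whose cropland surplus rate exceeds planetary-boundary reference
points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import is_undefined
from .budget_engine import BudgetContractError, SurplusRate, SystemBudget
from .flow_model import CafeSystem, Nutrient

__all__ = [
    "SurplusChange",
    "PBThresholds",
    "surplus_change",
    "largest_change_system",
    "county_share_metrics",
    "pb_exceedance",
]


@dataclass(frozen=True)
class SurplusChange:
    """Surplus difference between two adjacent systems (to minus from)."""

    unit_id: str
    year: int
    nutrient: Nutrient
    from_system: CafeSystem
    to_system: CafeSystem
    delta: float  # kg/yr


@dataclass(frozen=True)
class PBThresholds:
    """Planetary-boundary reference surplus rates, kg ha-1 yr-1 of cropland.

    Modeled safe-range reference points: 24 kg N/ha/yr at the global scale,
    15 kg N/ha/yr for the United States, and a 3.5-6.9 kg P/ha/yr range.
    """

    n_global: float = 24.0
    n_us: float = 15.0
    p_range: tuple[float, float] = (3.5, 6.9)

    def __post_init__(self) -> None:
        if not self.n_us < self.n_global:
            raise ValueError("US N threshold must lie below the global one")
        if not self.p_range[0] < self.p_range[1]:
            raise ValueError("P range must be (low, high) with low < high")


def surplus_change(to_budget: SystemBudget, from_budget: SystemBudget) -> SurplusChange:
    """surplus(to) - surplus(from) for an adjacent system pair."""
    if (to_budget.unit_id, to_budget.year, to_budget.nutrient) != (
        from_budget.unit_id,
        from_budget.year,
        from_budget.nutrient,
    ):
        raise BudgetContractError("surplus_change operands must share unit, year and nutrient")
    if not to_budget.system.is_adjacent(from_budget.system):
        raise BudgetContractError(
            f"systems {from_budget.system.label} and {to_budget.system.label} are not adjacent"
        )
    return SurplusChange(
        unit_id=to_budget.unit_id,
        year=to_budget.year,
        nutrient=to_budget.nutrient,
        from_system=from_budget.system,
        to_system=to_budget.system,
        delta=to_budget.surplus - from_budget.surplus,
    )


def largest_change_system(
    budgets: Mapping[CafeSystem, SystemBudget],
) -> CafeSystem | None:
    """System with the largest strictly positive surplus change.

    Candidates are the Cropping surplus itself and the three adjacent-system
    deltas; only positive candidates compete.  Returns None when no candidate
    is positive.  Ties break toward the most upstream system.
    """
    missing = [s for s in CafeSystem if s not in budgets]
    if missing:
        raise BudgetContractError(f"missing system budget(s): {[s.label for s in missing]}")
    candidates: list[tuple[CafeSystem, float]] = [
        (CafeSystem.Cropping, budgets[CafeSystem.Cropping].surplus)
    ]
    for lo, hi in zip(list(CafeSystem)[:-1], list(CafeSystem)[1:]):
        candidates.append((hi, budgets[hi].surplus - budgets[lo].surplus))
    positive = [(s, d) for s, d in candidates if d > 0]
    if not positive:
        return None
    best = max(d for _, d in positive)
    # ties -> most upstream (candidates are already in upstream order)
    for s, d in positive:
        if d == best:
            return s
    raise AssertionError("unreachable")


def county_share_metrics(
    budgets: Iterable[SystemBudget],
    half_factor: float = 0.5,
) -> pd.DataFrame:
    """County-share metrics comparing Cropping against each downstream system.

    For each (year, nutrient, downstream system D) present:

    * ``pct_surplus_lt_half``: % of counties with Cropping surplus strictly
      below ``half_factor`` x D's surplus.
    * ``pct_efficiency_gt``: % of counties with Cropping efficiency strictly
      above D's efficiency (counties with an undefined efficiency on either
      side are excluded from numerator and denominator; excluded counts are
      reported).

    Strict inequalities throughout; ties count against the metric.
    """
    df = pd.DataFrame(
        [
            {
                "unit_id": b.unit_id,
                "year": b.year,
                "nutrient": b.nutrient.value,
                "system": b.system,
                "surplus": b.surplus,
                "efficiency": b.efficiency,
            }
            for b in budgets
        ]
    )
    if df.empty:
        raise BudgetContractError("county_share_metrics requires a non-empty budget set")
    rows = []
    for (year, nutrient), grp in df.groupby(["year", "nutrient"]):
        wide = grp.pivot(index="unit_id", columns="system", values=["surplus", "efficiency"])
        if CafeSystem.Cropping not in wide["surplus"].columns:
            raise BudgetContractError("Cropping budgets are required for share metrics")
        s_c = wide[("surplus", CafeSystem.Cropping)]
        e_c = wide[("efficiency", CafeSystem.Cropping)]
        for downstream in (CafeSystem.AnimalCrop, CafeSystem.Food, CafeSystem.Ecosystem):
            if downstream not in wide["surplus"].columns:
                continue
            s_d = wide[("surplus", downstream)]
            ok_s = s_c.notna() & s_d.notna()
            n_s = int(ok_s.sum())
            if n_s == 0:
                raise BudgetContractError("no counties with both systems' surpluses")
            pct_s = 100.0 * float((s_c[ok_s] < half_factor * s_d[ok_s]).sum()) / n_s
            e_d = wide[("efficiency", downstream)]
            ok_e = e_c.notna() & e_d.notna()
            n_e = int(ok_e.sum())
            pct_e = (
                100.0 * float((e_c[ok_e] > e_d[ok_e]).sum()) / n_e if n_e else float("nan")
            )
            rows.append(
                {
                    "year": year,
                    "nutrient": nutrient,
                    "downstream_system": downstream.label,
                    "n_counties_surplus": n_s,
                    "pct_surplus_lt_half": pct_s,
                    "n_counties_efficiency": n_e,
                    "n_excluded_efficiency": len(e_c) - n_e,
                    "pct_efficiency_gt": pct_e,
                }
            )
    return pd.DataFrame(rows)


def pb_exceedance(
    rates: Sequence[SurplusRate],
    thresholds: PBThresholds = PBThresholds(),
) -> dict[str, int]:
    """Counts of units against planetary-boundary reference rates.

    N rates are compared strictly (> threshold) against the US and global
    reference points; P rates are counted as *within* the boundary when not
    exceeding the upper bound of the P range.  N and P entries are filled from
    the rates of the corresponding nutrient.
    """
    n_rates = [r.rate_cropland for r in rates if r.nutrient == Nutrient.N and not is_undefined(r.rate_cropland)]
    p_rates = [r.rate_cropland for r in rates if r.nutrient == Nutrient.P and not is_undefined(r.rate_cropland)]
    return {
        "n_exceed_global": sum(1 for r in n_rates if r > thresholds.n_global),
        "n_exceed_us": sum(1 for r in n_rates if r > thresholds.n_us),
        "p_within_upper": sum(1 for r in p_rates if r <= thresholds.p_range[1]),
        "n_units_n": len(n_rates),
        "n_units_p": len(p_rates),
    }
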