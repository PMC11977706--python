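"""Result-table rendering and end-to-end orchestration.

Renders the watershed budget summary (inputs / outputs / surplus / efficiency
per system, nutrient and period), county-share metrics, recyclable-waste
quantities, N:P ratios and largest-change attribution counts from a flow
table, and writes them as a CSV bundle with a JSON run manifest.  Report
cells round half away from zero to integers (Gg and %); unrounded CSVs are
always emitted alongside.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._util import UNDEFINED, round_half_away
from .budget_engine import (
    DEFAULT_MAPPING,
    SystemMapping,
    aggregate,
    period_average,
    system_budget,
)
from .cross_system import county_share_metrics, largest_change_system
from .flow_model import CafeSystem, FlowTable, Nutrient
from .imbalance import np_ratio
from .recycling import classify_source_sink, offset_percent, recyclable_inventory, waste_composition

__all__ = ["ReportBundle", "run_pipeline", "percent_reduction", "surplus_share", "write_bundle"]

log = logging.getLogger("cafebudget")


@dataclass
class ReportBundle:
    """The rendered result tables plus the run manifest."""

    table1: pd.DataFrame  # watershed budgets per period/nutrient/system
    table2: pd.DataFrame  # county-share metrics
    recyclable: pd.DataFrame  # per-county recyclable inventories
    np_ratios: pd.DataFrame  # watershed N:P surplus ratios
    changes: pd.DataFrame  # largest-change attribution counts
    manifest: dict


def percent_reduction(start: float, end: float, digits: int = 0) -> float:
    """100 x (start - end) / start, report-rounded; undefined for start <= 0."""
    if start <= 0:
        return UNDEFINED
    return round_half_away(100.0 * (start - end) / start, digits)


def surplus_share(numerator_surplus: float, denominator_surplus: float,
                  digits: int = 0) -> float:
    """Surplus of one system as a percent of another's; undefined if the
    denominator surplus is not positive."""
    if denominator_surplus <= 0:
        return UNDEFINED
    return round_half_away(100.0 * numerator_surplus / denominator_surplus, digits)


def _watershed_summary(table: FlowTable, periods: dict[int, tuple[int, int]],
                       mapping: SystemMapping) -> pd.DataFrame:
    rows = []
    for label, window in periods.items():
        avg = table if window == (label, label) else period_average(table, window, label)
        for nutrient in Nutrient:
            for system in CafeSystem:
                budgets = [
                    system_budget(avg, c, label, nutrient, system, mapping)
                    for c in avg.county_ids
                ]
                w = aggregate(budgets)
                rows.append(
                    {
                        "period": label,
                        "nutrient": nutrient.value,
                        "system": system.label,
                        "inputs_gg": w.inputs / 1e6,
                        "outputs_gg": w.productive_outputs / 1e6,
                        "surplus_gg": w.surplus / 1e6,
                        "efficiency_pct": 100.0 * w.efficiency,
                        "inputs_gg_rounded": round_half_away(w.inputs / 1e6),
                        "outputs_gg_rounded": round_half_away(w.productive_outputs / 1e6),
                        "surplus_gg_rounded": round_half_away(w.surplus / 1e6),
                        "efficiency_pct_rounded": round_half_away(100.0 * w.efficiency),
                        "provenance": "budget_engine.aggregate/period_average",
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(table: FlowTable, periods: dict[int, tuple[int, int]] | None = None,
                 mapping: SystemMapping = DEFAULT_MAPPING, seed: int | None = None) -> ReportBundle:
    """Run every reporting stage on a validated flow table.

    ``periods`` maps a label year to an inclusive averaging window, e.g.
    ``{1985: (1985, 1989), 2019: (2015, 2019)}``.  By default the earliest
    and latest five available years are used (or single years if the table
    holds fewer than five).
    """
    if not table.county_ids:
        raise ValueError("run_pipeline: empty county set")
    years = table.years
    if periods is None:
        if len(years) >= 5:
            periods = {years[0]: (years[0], years[4]), years[-1]: (years[-5], years[-1])}
        else:
            periods = {years[0]: (years[0], years[0]), years[-1]: (years[-1], years[-1])}

    log.info("stage=watershed_summary records=%d", len(table))
    table1 = _watershed_summary(table, periods, mapping)

    # per-period county tables
    share_rows, rec_rows, np_rows, change_rows = [], [], [], []
    for label, window in periods.items():
        avg = table if window == (label, label) else period_average(table, window, label)
        counties = avg.county_ids
        budgets = {
            (c, n, s): system_budget(avg, c, label, n, s, mapping)
            for c in counties
            for n in Nutrient
            for s in CafeSystem
        }
        log.info("stage=county_budgets period=%s counties=%d", label, len(counties))
        share = county_share_metrics(budgets.values())
        share_rows.append(share.assign(provenance="cross_system.county_share_metrics"))
        for nutrient in Nutrient:
            counts: dict[str, int] = {s.label: 0 for s in CafeSystem}
            none_count = 0
            for c in counties:
                best = largest_change_system({s: budgets[(c, nutrient, s)] for s in CafeSystem})
                if best is None:
                    none_count += 1
                else:
                    counts[best.label] += 1
            change_rows.append(
                {
                    "period": label,
                    "nutrient": nutrient.value,
                    **counts,
                    "none": none_count,
                    "provenance": "cross_system.largest_change_system",
                }
            )
            for system in CafeSystem:
                r = np_ratio(
                    aggregate([budgets[(c, Nutrient.N, system)] for c in counties]),
                    aggregate([budgets[(c, Nutrient.P, system)] for c in counties]),
                )
                if nutrient is Nutrient.N:  # emit once per period/system
                    np_rows.append(
                        {
                            "period": label,
                            "system": system.label,
                            "np_ratio": r.ratio if r.valid else UNDEFINED,
                            "valid": r.valid,
                            "reason": r.reason,
                            "provenance": "imbalance.np_ratio",
                        }
                    )
            for c in counties:
                inv = recyclable_inventory(avg, c, label, nutrient)
                comp = waste_composition(inv)
                rec_rows.append(
                    {
                        "period": label,
                        "unit_id": c,
                        "nutrient": nutrient.value,
                        "manure_unrecycled_kg": inv.manure_unrecycled,
                        "food_waste_kg": inv.food_waste,
                        "human_waste_kg": inv.human_waste,
                        "total_kg": inv.total,
                        "fertilizer_demand_kg": inv.fertilizer_demand,
                        "offset_percent": offset_percent(inv),
                        "class": classify_source_sink(inv),
                        "food_human_pct": comp["food_human_pct"],
                        "provenance": "recycling.recyclable_inventory",
                    }
                )

    manifest = {
        "periods": {str(k): list(v) for k, v in periods.items()},
        "n_counties": len(table.county_ids),
        "n_records": len(table),
        "seed": seed,
        "flows_sha256": hashlib.sha256(
            pd.util.hash_pandas_object(table.flows, index=False).values.tobytes()
        ).hexdigest(),
    }
    return ReportBundle(
        table1=table1,
        table2=pd.concat(share_rows, ignore_index=True) if share_rows else pd.DataFrame(),
        recyclable=pd.DataFrame(rec_rows),
        np_ratios=pd.DataFrame(np_rows),
        changes=pd.DataFrame(change_rows),
        manifest=manifest,
    )


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write the bundle as CSVs plus a JSON manifest (deterministic bytes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.table1.to_csv(out / "table1.csv", index=False)
    bundle.table2.to_csv(out / "table2.csv", index=False)
    bundle.recyclable.to_csv(out / "recyclable.csv", index=False)
    bundle.np_ratios.to_csv(out / "np_ratios.csv", index=False)
    bundle.changes.to_csv(out / "changes.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))


def configure_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
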