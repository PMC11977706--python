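"""Group-wise association machinery: share binning, rank test, regression.

Counties are grouped by the share of their cropland inputs supplied as
mineral fertilizer (versus recycled manure) and the efficiency distributions
of the groups are compared with the Kruskal-Wallis rank test; simple ordinary
least squares covers continuous relationships.  The same binning machinery
serves efficiency-based groupings, including an open-ended >=100% bin for
soil-mining counties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import UNDEFINED, is_undefined
from .flow_model import FlowKind, FlowTable, Nutrient

__all__ = [
    "ShareBins",
    "GroupTestResult",
    "fertilizer_share",
    "bin_units",
    "kruskal_wallis",
    "linear_fit",
]


@dataclass(frozen=True)
class ShareBins:
    """Percent breakpoints defining left-closed, right-open bins.

    The final bin is closed (so 100.0 lands in [80, 100]).  With
    ``open_ended=True`` an extra unbounded bin is appended past the last
    edge (e.g. >=100 for efficiency groupings with soil-mining counties).
    """

    edges: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
    open_ended: bool = False

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or any(
            b <= a for a, b in zip(self.edges, self.edges[1:])
        ):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        out = [f"[{a:g},{b:g})" for a, b in zip(self.edges, self.edges[1:])]
        if self.open_ended:
            out.append(f">={self.edges[-1]:g}")
        else:
            out[-1] = f"[{self.edges[-2]:g},{self.edges[-1]:g}]"
        return out

    def assign(self, value: float) -> str:
        if is_undefined(value):
            raise ValueError("cannot bin an undefined value")
        if value < self.edges[0] or (not self.open_ended and value > self.edges[-1]):
            raise ValueError(f"value {value} outside [{self.edges[0]}, {self.edges[-1]}]")
        if self.open_ended and value >= self.edges[-1]:
            return self.labels[-1]
        for i, (a, b) in enumerate(zip(self.edges, self.edges[1:])):
            if a <= value < b:
                return self.labels[i]
        return self.labels[-1]  # value == closed upper edge


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float  # tie-corrected Kruskal-Wallis H
    p_value: float  # chi-square approximation, k-1 df
    group_sizes: tuple[int, ...]


def fertilizer_share(table: FlowTable, unit_id: str, year: int,
                     nutrient: Nutrient | str) -> float:
    """Percent of fertilizer+manure cropland input supplied as fertilizer.

    100 x fertilizer / (fertilizer + manure); NaN when both inputs are 0.
    """
    nutrient = Nutrient(nutrient)
    if unit_id == "WATERSHED" and "WATERSHED" not in table.county_ids:
        df = table.select(None, year, nutrient)
    else:
        df = table.select(unit_id, year, nutrient)
    by_flow = df.groupby("flow")["value_kg"].sum()
    fert = float(by_flow.get(FlowKind.mineral_fertilizer_cropland.value, 0.0))
    manure = float(by_flow.get(FlowKind.manure_applied_cropland.value, 0.0))
    if fert + manure == 0:
        return UNDEFINED
    return 100.0 * fert / (fert + manure)


def bin_units(values: dict[str, float] | Sequence[float],
              bins: ShareBins = ShareBins()) -> tuple[dict, int]:
    """Assign each defined value to exactly one bin.

    Accepts a unit_id -> value mapping or a plain sequence (index keys).
    Undefined (NaN) values are dropped; returns (assignments, n_dropped).
    """
    if not isinstance(values, dict):
        values = {str(i): v for i, v in enumerate(values)}
    assignments: dict[str, str] = {}
    dropped = 0
    for unit, value in values.items():
        if is_undefined(value):
            dropped += 1
            continue
        assignments[unit] = bins.assign(value)
    return assignments, dropped


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """Kruskal-Wallis H test across two or more groups.

    Midranks with tie correction; p-value from the chi-square approximation
    with k-1 degrees of freedom.  When every observation is identical the
    statistic is 0 and p is 1.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis groups must all be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("kruskal_wallis needs at least three observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(0.0, 1.0, tuple(a.size for a in arrays))
    h, p = stats.kruskal(*arrays)
    return GroupTestResult(float(h), float(p), tuple(a.size for a in arrays))


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    p_value: float  # two-sided t-test on the slope
    r_value: float


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares of y on x with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("linear_fit needs matched x/y with n >= 3")
    if np.all(x == x[0]):
        raise ValueError("linear_fit requires non-constant x")
    res = stats.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept),
                     float(res.pvalue), float(res.rvalue))
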