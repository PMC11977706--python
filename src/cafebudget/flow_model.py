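"""Canonical flow taxonomy and long-format flow-table I/O.

The package accounts for nitrogen (N) and phosphorus (P) mass flows through a
nested hierarchy of four nutrient-management systems -- Cropping, Animal-crop,
Food, and Ecosystem (the CAFE hierarchy) -- at the county scale.  Everything
downstream operates on a :class:`FlowTable`: a long-format table of one mass
flow value per (county, year, nutrient, flow kind), plus per-county-year
covariates (areas, population, livestock units).

Values are stored in kg/yr on an elemental basis (P is elemental P, never
P2O5-equivalent).  Signs are imposed by budget arithmetic, never stored: every
flow value is non-negative.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Nutrient",
    "CafeSystem",
    "FlowDirection",
    "FlowKind",
    "FlowTable",
    "FlowSchemaError",
    "FlowValidationError",
    "read_flow_table",
    "write_flow_table",
    "FLOW_COLUMNS",
    "COVARIATE_COLUMNS",
]

FLOW_COLUMNS = ["county_id", "county_name", "state", "year", "nutrient", "flow", "value_kg"]
COVARIATE_COLUMNS = [
    "county_id",
    "year",
    "cropland_area_ha",
    "land_area_ha",
    "population",
    "livestock_units",
]


class FlowSchemaError(ValueError):
    """A row violates the flow-table schema (unknown flow kind, bad column...)."""


class FlowValidationError(ValueError):
    """A structurally valid table violates a domain invariant."""


class Nutrient(str, enum.Enum):
    """The two budgeted nutrients, on an elemental mass basis."""

    N = "N"
    P = "P"


@enum.unique
class CafeSystem(enum.IntEnum):
    """The four nested systems, ordered from most upstream to most downstream.

    The integer values encode the strict total order Cropping < AnimalCrop <
    Food < Ecosystem, so comparisons and adjacency checks use plain ``<``.
    """

    Cropping = 1
    AnimalCrop = 2
    Food = 3
    Ecosystem = 4

    @property
    def label(self) -> str:
        return _SYSTEM_LABELS[self]

    def is_adjacent(self, other: "CafeSystem") -> bool:
        return abs(int(self) - int(other)) == 1


_SYSTEM_LABELS = {
    CafeSystem.Cropping: "Cropping",
    CafeSystem.AnimalCrop: "Animal-crop",
    CafeSystem.Food: "Food",
    CafeSystem.Ecosystem: "Ecosystem",
}


class FlowDirection(str, enum.Enum):
    INPUT = "input"
    PRODUCTIVE_OUTPUT = "productive_output"
    WASTE = "waste"
    NEUTRAL = "covariate-neutral"


class FlowKind(str, enum.Enum):
    """Closed vocabulary of accounted flows.

    Anything outside this set (pet food/waste, industrial production...) is out
    of accounting scope and rejected at read time.
    """

    mineral_fertilizer_cropland = "mineral_fertilizer_cropland"
    manure_applied_cropland = "manure_applied_cropland"
    biosolids_applied_cropland = "biosolids_applied_cropland"
    fixation_cropland = "fixation_cropland"
    deposition_cropland = "deposition_cropland"
    crop_harvest = "crop_harvest"
    feed_import = "feed_import"
    food_import = "food_import"
    food_export = "food_export"
    animal_products = "animal_products"
    manure_generated = "manure_generated"
    manure_pasture = "manure_pasture"
    manure_unrecycled = "manure_unrecycled"
    food_processing_retail_waste = "food_processing_retail_waste"
    human_waste_municipal_wwtp = "human_waste_municipal_wwtp"
    human_waste_industrial_wwtp = "human_waste_industrial_wwtp"
    human_waste_cso = "human_waste_cso"
    human_waste_septic = "human_waste_septic"
    urban_fertilizer = "urban_fertilizer"
    urban_deposition_fixation = "urban_deposition_fixation"

    @property
    def direction(self) -> FlowDirection:
        return _FLOW_DIRECTIONS[self]


_FLOW_DIRECTIONS = {
    FlowKind.mineral_fertilizer_cropland: FlowDirection.INPUT,
    FlowKind.manure_applied_cropland: FlowDirection.INPUT,
    FlowKind.biosolids_applied_cropland: FlowDirection.INPUT,
    FlowKind.fixation_cropland: FlowDirection.INPUT,
    FlowKind.deposition_cropland: FlowDirection.INPUT,
    FlowKind.crop_harvest: FlowDirection.PRODUCTIVE_OUTPUT,
    FlowKind.feed_import: FlowDirection.INPUT,
    FlowKind.food_import: FlowDirection.INPUT,
    FlowKind.food_export: FlowDirection.PRODUCTIVE_OUTPUT,
    FlowKind.animal_products: FlowDirection.PRODUCTIVE_OUTPUT,
    FlowKind.manure_generated: FlowDirection.NEUTRAL,
    FlowKind.manure_pasture: FlowDirection.NEUTRAL,
    FlowKind.manure_unrecycled: FlowDirection.WASTE,
    FlowKind.food_processing_retail_waste: FlowDirection.WASTE,
    FlowKind.human_waste_municipal_wwtp: FlowDirection.WASTE,
    FlowKind.human_waste_industrial_wwtp: FlowDirection.WASTE,
    FlowKind.human_waste_cso: FlowDirection.WASTE,
    FlowKind.human_waste_septic: FlowDirection.WASTE,
    FlowKind.urban_fertilizer: FlowDirection.INPUT,
    FlowKind.urban_deposition_fixation: FlowDirection.INPUT,
}

_VALID_FLOWS = frozenset(k.value for k in FlowKind)
_VALID_NUTRIENTS = frozenset(n.value for n in Nutrient)
_KEY = ["county_id", "year", "nutrient", "flow"]


@dataclass
class FlowTable:
    """Validated long-format flow records plus county covariates.

    ``flows`` columns: county_id, county_name, state, year, nutrient, flow,
    value_kg.  ``covariates`` columns: county_id, year, cropland_area_ha,
    land_area_ha, population, livestock_units.  The (county_id, year, nutrient,
    flow) key is unique; values are finite and >= 0.
    """

    flows: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COVARIATE_COLUMNS))
    strict: bool = False

    def __post_init__(self) -> None:
        self.flows = _validate_flows(self.flows)
        self.covariates = _validate_covariates(self.covariates)
        self._check_coverage()

    # -- validation ------------------------------------------------------

    def _check_coverage(self) -> None:
        if self.flows.empty:
            return
        have = set(map(tuple, self.covariates[["county_id", "year"]].itertuples(index=False)))
        need = set(map(tuple, self.flows[["county_id", "year"]].drop_duplicates().itertuples(index=False)))
        missing = sorted(need - have)
        if missing:
            msg = f"{len(missing)} county-year(s) lack covariates, e.g. {missing[:3]}"
            if self.strict:
                raise FlowValidationError(msg)
            warnings.warn(msg, stacklevel=3)

    # -- accessors -------------------------------------------------------

    @property
    def years(self) -> list[int]:
        return sorted(self.flows["year"].unique().tolist())

    @property
    def county_ids(self) -> list[str]:
        return sorted(self.flows["county_id"].unique().tolist())

    def value(self, unit_id: str, year: int, nutrient: Nutrient | str, flow: FlowKind | str) -> float:
        """Single flow value; missing combinations are 0 (with a warning)."""
        sel = self.select(unit_id, year, nutrient)
        fl = FlowKind(flow).value
        hit = sel.loc[sel["flow"] == fl, "value_kg"]
        if hit.empty:
            warnings.warn(
                f"no record for ({unit_id}, {year}, {Nutrient(nutrient).value}, {fl}); treating as 0",
                stacklevel=2,
            )
            return 0.0
        return float(hit.iloc[0])

    def select(self, unit_id: str | None = None, year: int | None = None,
               nutrient: Nutrient | str | None = None) -> pd.DataFrame:
        df = self.flows
        if unit_id is not None:
            df = df[df["county_id"] == unit_id]
        if year is not None:
            df = df[df["year"] == year]
        if nutrient is not None:
            df = df[df["nutrient"] == Nutrient(nutrient).value]
        return df

    def covariates_for(self, unit_id: str, year: int) -> pd.Series:
        hit = self.covariates[
            (self.covariates["county_id"] == unit_id) & (self.covariates["year"] == year)
        ]
        if hit.empty:
            raise FlowValidationError(f"no covariates for ({unit_id}, {year})")
        return hit.iloc[0]

    def subset_years(self, years: Iterable[int]) -> "FlowTable":
        ys = set(years)
        return FlowTable(
            self.flows[self.flows["year"].isin(ys)].reset_index(drop=True),
            self.covariates[self.covariates["year"].isin(ys)].reset_index(drop=True),
        )

    def __len__(self) -> int:
        return len(self.flows)

    def equals(self, other: "FlowTable") -> bool:
        a = self.flows.sort_values(_KEY).reset_index(drop=True)
        b = other.flows.sort_values(_KEY).reset_index(drop=True)
        ca = self.covariates.sort_values(["county_id", "year"]).reset_index(drop=True)
        cb = other.covariates.sort_values(["county_id", "year"]).reset_index(drop=True)
        return a.equals(b) and ca.equals(cb)


def _validate_flows(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in FLOW_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FlowSchemaError(f"flow table missing column(s): {missing_cols}")
    df = df[FLOW_COLUMNS].copy()
    df["county_id"] = df["county_id"].astype(str).str.zfill(5)
    df["year"] = df["year"].astype(int)
    df["nutrient"] = df["nutrient"].astype(str)
    df["flow"] = df["flow"].astype(str)
    df["value_kg"] = df["value_kg"].astype(float)

    bad_nut = df.loc[~df["nutrient"].isin(_VALID_NUTRIENTS)]
    if not bad_nut.empty:
        raise FlowSchemaError(
            f"unknown nutrient(s) {sorted(bad_nut['nutrient'].unique())} at row(s) {bad_nut.index[:5].tolist()}"
        )
    bad_flow = df.loc[~df["flow"].isin(_VALID_FLOWS)]
    if not bad_flow.empty:
        raise FlowSchemaError(
            f"unknown flow kind(s) {sorted(bad_flow['flow'].unique())} at row(s) {bad_flow.index[:5].tolist()}"
        )
    neg = df.loc[(df["value_kg"] < 0) | ~df["value_kg"].apply(pd.notna)]
    if not neg.empty:
        raise FlowValidationError(
            f"negative or missing value_kg at row(s) {neg.index[:5].tolist()}"
        )
    dup = df.duplicated(subset=_KEY)
    if dup.any():
        rows = df.loc[dup, _KEY].head(5).to_dict("records")
        raise FlowValidationError(f"duplicate (county, year, nutrient, flow) key(s): {rows}")
    return df.reset_index(drop=True)


def _validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FlowSchemaError(f"covariates table missing column(s): {missing_cols}")
    df = df[COVARIATE_COLUMNS].copy()
    if df.empty:
        return df.reset_index(drop=True)
    df["county_id"] = df["county_id"].astype(str).str.zfill(5)
    df["year"] = df["year"].astype(int)
    for c in COVARIATE_COLUMNS[2:]:
        df[c] = df[c].astype(float)
        if (df[c] < 0).any():
            raise FlowValidationError(f"negative {c} in covariates")
    over = df["cropland_area_ha"] > df["land_area_ha"]
    if over.any():
        raise FlowValidationError(
            f"cropland_area_ha exceeds land_area_ha at row(s) {df.index[over][:5].tolist()}"
        )
    if df.duplicated(subset=["county_id", "year"]).any():
        raise FlowValidationError("duplicate (county_id, year) in covariates")
    return df.reset_index(drop=True)


def read_flow_table(path: str | Path, covariates_path: str | Path | None = None,
                    strict: bool = False) -> FlowTable:
    """Read a flows CSV (and optional covariates CSV) into a validated table.

    Parameters
    ----------
    path:
        Flows CSV with header ``county_id,county_name,state,year,nutrient,flow,value_kg``.
    covariates_path:
        Covariates CSV with header
        ``county_id,year,cropland_area_ha,land_area_ha,population,livestock_units``.
        Defaults to ``<path stem>.covariates.csv`` next to ``path`` if present.
    strict:
        If True a missing covariate row is an error instead of a warning.
    """
    path = Path(path)
    flows = pd.read_csv(path, dtype={"county_id": str}, float_precision="round_trip")
    if covariates_path is None:
        candidate = path.with_suffix(".covariates.csv")
        covariates_path = candidate if candidate.exists() else None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, dtype={"county_id": str},
                          float_precision="round_trip")
    else:
        cov = pd.DataFrame(columns=COVARIATE_COLUMNS)
    return FlowTable(flows, cov, strict=strict)


def write_flow_table(table: FlowTable, path: str | Path,
                     covariates_path: str | Path | None = None) -> None:
    """Write a table to CSV so that read(write(t)) reproduces t exactly.

    Floats are written with 17 significant digits, which round-trips IEEE
    doubles bit-for-bit.
    """
    path = Path(path)
    if covariates_path is None:
        covariates_path = path.with_suffix(".covariates.csv")
    table.flows.to_csv(path, index=False, float_format="%.17g")
    table.covariates.to_csv(covariates_path, index=False, float_format="%.17g")
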