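"""Domain types and I/O for priced, composition-annotated food lists.

The central container is :class:`MarketTable`: the locally available food
items of one place and period, each carrying a retail price, a food
composition record per 100 g edible portion, and food-group labels under two
taxonomies — the six Healthy Diet Basket (HDB) groups used for the cost of a
healthy diet, and the ten Minimum Dietary Diversity for Women (MDD-W) groups
used for the diet-diversity indicator.

Unit conventions (applied everywhere downstream):

* prices are standardized to **currency per 100 g edible portion**
  (``effective_price = price_as_purchased / edible_fraction``);
* diet quantities are in **units of 100 g edible per day**;
* composition values are **per 100 g edible portion**, energy in kcal.

A single convention avoids silent per-gram vs per-100 g errors in the
optimizers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# --- closed group vocabularies -------------------------------------------

HDB_GROUPS: tuple[str, ...] = (
    "starchy_staples",
    "vegetables",
    "fruits",
    "animal_source_foods",
    "legumes_nuts_seeds",
    "fats_oils",
)
HDB_OTHER = "other"
HDB_VOCABULARY = HDB_GROUPS + (HDB_OTHER,)

MDDW_GROUPS: tuple[str, ...] = (
    "grains_roots_tubers",
    "pulses",
    "nuts_seeds",
    "dairy",
    "meat_poultry_fish",
    "eggs",
    "dark_green_leafy_vegetables",
    "vitamin_a_rich_fruits_vegetables",
    "other_vegetables",
    "other_fruits",
)
MDDW_NONE = "none"
MDDW_VOCABULARY = MDDW_GROUPS + (MDDW_NONE,)

#: columns every MarketTable frame carries besides one column per nutrient
CORE_COLUMNS = (
    "item_id",
    "name",
    "hdb_group",
    "mddw_group",
    "edible_fraction",
    "price",
    "effective_price",
    "energy_kcal_100g",
)

PPP_CURRENCY = "PPP$"


class MarketJoinError(ValueError):
    """A priced item lacks a composition row or a group label."""


# --- nutrient-level types -------------------------------------------------


@dataclass(frozen=True)
class NutrientBounds:
    """Daily lower/upper bound for one nutrient; ``upper=None`` means unbounded."""

    lower: float = 0.0
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError(f"lower bound must be >= 0, got {self.lower}")
        if self.upper is not None and self.upper < self.lower:
            raise ValueError(
                f"upper bound {self.upper} below lower bound {self.lower}"
            )


@dataclass(frozen=True)
class NutrientVector:
    """Energy (kcal) and nutrient amounts per 100 g edible portion."""

    energy_kcal: float
    amounts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.energy_kcal < 0:
            raise ValueError("energy must be >= 0")
        for name, value in self.amounts.items():
            if value < 0:
                raise ValueError(f"nutrient {name!r} amount must be >= 0, got {value}")


@dataclass(frozen=True)
class FoodItem:
    item_id: str
    name: str
    hdb_group: str
    mddw_group: str
    composition: NutrientVector
    edible_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.hdb_group not in HDB_VOCABULARY:
            raise ValueError(f"unknown HDB group {self.hdb_group!r}")
        if self.mddw_group not in MDDW_VOCABULARY:
            raise ValueError(f"unknown MDD-W group {self.mddw_group!r}")
        if not (0 < self.edible_fraction <= 1):
            raise ValueError("edible_fraction must be in (0, 1]")


@dataclass(frozen=True)
class PriceRecord:
    item_id: str
    price: float  # currency per 100 g as purchased
    currency: str
    place: str
    period: str

    def __post_init__(self) -> None:
        if self.price <= 0:
            raise ValueError(f"price must be > 0, got {self.price}")


# --- requirement profile and HDB specification ---------------------------


@dataclass(frozen=True)
class RequirementProfile:
    """Energy target plus nutrient bounds for one demographic group.

    ``bounds`` maps nutrient name -> :class:`NutrientBounds`; daily amounts in
    each nutrient's declared unit.
    """

    group_label: str
    energy_target: float  # kcal/day
    bounds: Mapping[str, NutrientBounds] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.energy_target <= 0:
            raise ValueError("energy_target must be > 0")

    def scaled(self, factor: float, label: str | None = None) -> "RequirementProfile":
        """Profile with energy target and all bounds multiplied by ``factor``."""
        bounds = {
            n: NutrientBounds(b.lower * factor,
                              None if b.upper is None else b.upper * factor)
            for n, b in self.bounds.items()
        }
        return RequirementProfile(label or self.group_label,
                                  self.energy_target * factor, bounds)


@dataclass(frozen=True)
class GroupTarget:
    """Item count and daily energy allocation for one HDB group."""

    items: int
    energy_kcal: float

    def __post_init__(self) -> None:
        if self.items < 1:
            raise ValueError("required item count must be >= 1")
        if self.energy_kcal <= 0:
            raise ValueError("group energy allocation must be > 0")


#: Default HDB allocation: 11 items over six groups, 2330 kcal/day total.
#: Counts 2/3/2/2/1/1; per-group energies from the HDB methodology config.
DEFAULT_HDB_ALLOCATION: dict[str, GroupTarget] = {
    "starchy_staples": GroupTarget(2, 1160.0),
    "vegetables": GroupTarget(3, 110.0),
    "fruits": GroupTarget(2, 160.0),
    "animal_source_foods": GroupTarget(2, 300.0),
    "legumes_nuts_seeds": GroupTarget(1, 300.0),
    "fats_oils": GroupTarget(1, 300.0),
}


@dataclass(frozen=True)
class HDBSpec:
    """Healthy Diet Basket: per-group item counts and energy allocations."""

    groups: Mapping[str, GroupTarget]
    total_energy: float = 2330.0

    def __post_init__(self) -> None:
        if set(self.groups) != set(HDB_GROUPS):
            raise ValueError(
                f"HDBSpec must cover exactly the six groups {HDB_GROUPS}"
            )
        allocated = sum(g.energy_kcal for g in self.groups.values())
        if not math.isclose(allocated, self.total_energy, rel_tol=1e-9):
            raise ValueError(
                f"group energy allocations sum to {allocated}, "
                f"expected total_energy={self.total_energy}"
            )

    @classmethod
    def default(cls) -> "HDBSpec":
        return cls(groups=dict(DEFAULT_HDB_ALLOCATION), total_energy=2330.0)

    @property
    def total_items(self) -> int:
        return sum(g.items for g in self.groups.values())


# --- the market table -----------------------------------------------------


@dataclass
class MarketTable:
    """Priced, composition-annotated, group-labelled food list for one
    place/period.

    ``frame`` holds one row per item with the :data:`CORE_COLUMNS` plus one
    column per nutrient in ``nutrients``. ``metadata`` is free-form (the
    synthetic generator records ground-truth rankings there).
    """

    place: str
    period: str
    currency: str
    frame: pd.DataFrame
    nutrients: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in CORE_COLUMNS if c not in f.columns]
        if missing:
            raise ValueError(f"market frame missing columns {missing}")
        for n in self.nutrients:
            if n not in f.columns:
                raise ValueError(f"market frame missing nutrient column {n!r}")
        if len(f) == 0:
            raise ValueError("market table must have at least one row")
        if f["item_id"].duplicated().any():
            dups = sorted(f.loc[f["item_id"].duplicated(), "item_id"])
            raise ValueError(f"duplicate item_ids: {dups}")
        bad_hdb = set(f["hdb_group"]) - set(HDB_VOCABULARY)
        if bad_hdb:
            raise ValueError(f"unknown HDB groups: {sorted(bad_hdb)}")
        bad_mddw = set(f["mddw_group"]) - set(MDDW_VOCABULARY)
        if bad_mddw:
            raise ValueError(f"unknown MDD-W groups: {sorted(bad_mddw)}")
        if (f["effective_price"] <= 0).any():
            bad = sorted(f.loc[f["effective_price"] <= 0, "item_id"])
            raise ValueError(f"nonpositive effective prices for {bad}")
        if ((f["edible_fraction"] <= 0) | (f["edible_fraction"] > 1)).any():
            raise ValueError("edible_fraction must be in (0, 1]")
        if (f[list(self.nutrients)].to_numpy() < 0).any():
            raise ValueError("nutrient amounts must be >= 0")
        self.frame = f.reset_index(drop=True)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_items(
        cls,
        items: Sequence[FoodItem],
        prices: Mapping[str, float],
        *,
        place: str = "synthetic",
        period: str = "2021",
        currency: str = PPP_CURRENCY,
        nutrients: Sequence[str] | None = None,
        metadata: dict | None = None,
    ) -> "MarketTable":
        """Build a table from :class:`FoodItem` objects and an item->price map."""
        if nutrients is None:
            seen: list[str] = []
            for it in items:
                for n in it.composition.amounts:
                    if n not in seen:
                        seen.append(n)
            nutrients = seen
        rows = []
        for it in items:
            if it.item_id not in prices:
                raise MarketJoinError(f"no price for item {it.item_id!r}")
            price = float(prices[it.item_id])
            if price <= 0:
                raise ValueError(f"price must be > 0 for {it.item_id!r}")
            row = {
                "item_id": it.item_id,
                "name": it.name,
                "hdb_group": it.hdb_group,
                "mddw_group": it.mddw_group,
                "edible_fraction": it.edible_fraction,
                "price": price,
                "effective_price": price / it.edible_fraction,
                "energy_kcal_100g": it.composition.energy_kcal,
            }
            for n in nutrients:
                row[n] = float(it.composition.amounts.get(n, 0.0))
            rows.append(row)
        frame = pd.DataFrame(rows)
        return cls(place=place, period=period, currency=currency, frame=frame,
                   nutrients=tuple(nutrients), metadata=metadata or {})

    # -- basic accessors ---------------------------------------------------

    @property
    def item_ids(self) -> list[str]:
        return list(self.frame["item_id"])

    def __len__(self) -> int:
        return len(self.frame)

    def row(self, item_id: str) -> pd.Series:
        match = self.frame[self.frame["item_id"] == item_id]
        if match.empty:
            raise KeyError(f"unknown item {item_id!r}")
        return match.iloc[0]

    def energy(self) -> np.ndarray:
        return self.frame["energy_kcal_100g"].to_numpy(dtype=float)

    def effective_prices(self) -> np.ndarray:
        return self.frame["effective_price"].to_numpy(dtype=float)

    def nutrient_matrix(self, nutrients: Sequence[str] | None = None) -> np.ndarray:
        """Items x nutrients matrix (per 100 g edible); absent nutrients are 0."""
        names = list(nutrients) if nutrients is not None else list(self.nutrients)
        cols = []
        for n in names:
            if n in self.frame.columns:
                cols.append(self.frame[n].to_numpy(dtype=float))
            else:
                logger.warning("nutrient %r absent from market; treated as 0", n)
                cols.append(np.zeros(len(self.frame)))
        return np.column_stack(cols) if cols else np.zeros((len(self.frame), 0))

    # -- transformed copies ------------------------------------------------

    def scale_prices(self, factor: float) -> "MarketTable":
        """Uniformly scale all prices by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        frame = self.frame.copy()
        frame["price"] = frame["price"] * factor
        frame["effective_price"] = frame["effective_price"] * factor
        return replace(self, frame=frame, metadata=dict(self.metadata))

    def convert_ppp(self, ppp_factor: float) -> "MarketTable":
        """Convert all prices to international dollars at a PPP factor
        (local currency per international dollar)."""
        if ppp_factor <= 0:
            raise ValueError("PPP factor must be > 0")
        out = self.scale_prices(1.0 / ppp_factor)
        out.currency = PPP_CURRENCY
        return out


# --- per-item cost indicators --------------------------------------------


def cost_per_kcal(market: MarketTable) -> pd.Series:
    """Effective price per kcal for each item, indexed by item_id.

    Zero-energy items (e.g. iodized salt) have no defined price per calorie:
    they get NaN and are *non-rankable* — excluded from the per-calorie
    selection rules (CoCA/CoDD/CoHD) but retained as LP variables in CoNA.
    """
    energy = market.energy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cpk = np.where(energy > 0, market.effective_prices() / energy, np.nan)
    return pd.Series(cpk, index=market.frame["item_id"], name="cost_per_kcal")


def rankable_mask(market: MarketTable) -> pd.Series:
    """Boolean mask (indexed by item_id) of items with positive energy."""
    return pd.Series(market.energy() > 0, index=market.frame["item_id"])


def convert_price_ppp(price: float, ppp_factor: float) -> float:
    """Local-currency price -> international dollars at PPP.

    ``ppp_factor`` is local currency per international dollar. Applied
    uniformly to a market this commutes with every cost indicator.
    """
    if ppp_factor <= 0:
        raise ValueError("PPP factor must be > 0")
    return price / ppp_factor


def inflate_cost(cost: float, cpi_base: float, cpi_target: float) -> float:
    """Update a cost from the CPI base period to the target period.

    Standard index-ratio updating with the food-and-non-alcoholic-beverages
    CPI: ``cost * cpi_target / cpi_base``.
    """
    if cpi_base <= 0 or cpi_target <= 0:
        raise ValueError("CPI indices must be > 0")
    return cost * cpi_target / cpi_base


# --- config + file I/O ----------------------------------------------------


def _load_yaml(source) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    with open(source, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {source} must be a mapping")
    return data


def _bundled(name: str) -> dict:
    text = resources.files("dietcost.data").joinpath(name).read_text("utf-8")
    return yaml.safe_load(text)


def load_nutrient_config(path=None) -> dict[str, str]:
    """Nutrient name -> unit mapping; bundled 22-nutrient default if no path."""
    data = _bundled("nutrients.yml") if path is None else _load_yaml(path)
    nutrients = data.get("nutrients")
    if not isinstance(nutrients, list):
        raise ValueError("nutrient config must contain a 'nutrients' list")
    out: dict[str, str] = {}
    for entry in nutrients:
        out[str(entry["name"])] = str(entry.get("unit", ""))
    return out


def load_requirement_profile(path=None) -> RequirementProfile:
    """Load a requirement profile from YAML (bundled illustrative default).

    The bundled profile is *illustrative only* — plausible orders of
    magnitude for an adult woman, not authoritative reference intakes.
    """
    data = (_bundled("profile_adult_woman_illustrative.yml") if path is None
            else _load_yaml(path))
    bounds = {}
    for name, spec in (data.get("bounds") or {}).items():
        spec = spec or {}
        upper = spec.get("upper")
        bounds[str(name)] = NutrientBounds(
            lower=float(spec.get("lower", 0.0)),
            upper=None if upper is None else float(upper),
        )
    return RequirementProfile(
        group_label=str(data.get("group_label", "unnamed")),
        energy_target=float(data["energy_target_kcal"]),
        bounds=bounds,
    )


def load_hdb_spec(path=None) -> HDBSpec:
    """Load an HDB specification from YAML; bundled default if no path."""
    if path is None:
        return HDBSpec.default()
    data = _load_yaml(path)
    groups = {
        str(g): GroupTarget(int(spec["items"]), float(spec["energy_kcal"]))
        for g, spec in data["groups"].items()
    }
    return HDBSpec(groups=groups, total_energy=float(data["total_energy_kcal"]))


def read_market_table(
    prices_path,
    composition_path,
    taxonomy_config=None,
    nutrient_config=None,
) -> MarketTable:
    """Join a price table to a composition table into a validated MarketTable.

    ``prices_path``: delimited text with header
    (item_id, name, price, currency, place, period).
    ``composition_path``: delimited text, one row per item_id, columns
    energy_kcal_100g, edible_fraction, and one per nutrient; may also carry
    hdb_group / mddw_group columns directly.
    ``taxonomy_config``: mapping or YAML path with ``hdb:`` and ``mddw:``
    item_id -> group maps; overrides any group columns in the composition.

    Raises :class:`MarketJoinError` naming every priced item with no
    composition row or no HDB group label.
    """
    prices = pd.read_csv(prices_path)
    comp = pd.read_csv(composition_path)
    for col in ("item_id", "price"):
        if col not in prices.columns:
            raise ValueError(f"price table missing column {col!r}")
    if "item_id" not in comp.columns:
        raise ValueError("composition table missing column 'item_id'")
    for col in ("energy_kcal_100g", "edible_fraction"):
        if col not in comp.columns:
            raise ValueError(f"composition table missing column {col!r}")

    if (prices["price"] <= 0).any():
        bad = sorted(prices.loc[prices["price"] <= 0, "item_id"].astype(str))
        raise ValueError(f"nonpositive prices for items {bad}")

    missing = sorted(set(prices["item_id"]) - set(comp["item_id"]))
    if missing:
        raise MarketJoinError(
            f"priced items with no composition row: {missing}"
        )

    taxonomy = _load_yaml(taxonomy_config) if taxonomy_config is not None else None

    merged = prices.merge(comp, on="item_id", how="left",
                          suffixes=("", "_comp"), validate="one_to_one")
    if "name" not in merged.columns:
        merged["name"] = merged["item_id"]

    if taxonomy is not None:
        hdb_map = {str(k): str(v) for k, v in (taxonomy.get("hdb") or {}).items()}
        mddw_map = {str(k): str(v) for k, v in (taxonomy.get("mddw") or {}).items()}
        merged["hdb_group"] = merged["item_id"].map(hdb_map)
        merged["mddw_group"] = merged["item_id"].map(mddw_map).fillna(MDDW_NONE)
    if "hdb_group" not in merged.columns or merged["hdb_group"].isna().any():
        unlabelled = sorted(
            merged.loc[merged.get("hdb_group", pd.Series(np.nan, index=merged.index))
                       .isna(), "item_id"].astype(str)
        ) if "hdb_group" in merged.columns else sorted(merged["item_id"].astype(str))
        raise MarketJoinError(f"items with no HDB group label: {unlabelled}")
    if "mddw_group" not in merged.columns:
        merged["mddw_group"] = MDDW_NONE
    merged["mddw_group"] = merged["mddw_group"].fillna(MDDW_NONE)

    reserved = set(CORE_COLUMNS) | {"currency", "place", "period"}
    nutrient_names = [c for c in comp.columns
                      if c not in reserved and c != "item_id"]
    if nutrient_config is not None:
        configured = list(load_nutrient_config(nutrient_config))
        nutrient_names = [n for n in configured]
        for n in configured:
            if n not in merged.columns:
                logger.warning("configured nutrient %r not in composition; "
                               "treated as 0", n)
                merged[n] = 0.0

    na_counts = merged[nutrient_names].isna().sum()
    for n, count in na_counts.items():
        if count:
            logger.warning("nutrient %r missing for %d items; treated as 0 "
                           "(never imputed)", n, int(count))
    merged[nutrient_names] = merged[nutrient_names].fillna(0.0)

    def _single(col: str, default: str) -> str:
        if col not in prices.columns:
            return default
        vals = sorted(set(prices[col].astype(str)))
        if len(vals) > 1:
            raise ValueError(f"price table mixes multiple {col} values: {vals}")
        return vals[0]

    merged["effective_price"] = merged["price"] / merged["edible_fraction"]
    keep = list(CORE_COLUMNS) + nutrient_names
    return MarketTable(
        place=_single("place", "unknown"),
        period=_single("period", "unknown"),
        currency=_single("currency", "local"),
        frame=merged[keep].copy(),
        nutrients=tuple(nutrient_names),
    )


def write_market_table(market: MarketTable, prices_path, composition_path) -> None:
    """Write a market back to price + composition delimited files.

    Numeric fields are written at full precision so a read/write round trip
    reproduces every value exactly.
    """
    f = market.frame
    prices = pd.DataFrame(
        {
            "item_id": f["item_id"],
            "name": f["name"],
            "price": f["price"],
            "currency": market.currency,
            "place": market.place,
            "period": market.period,
        }
    )
    comp_cols = ["item_id", "energy_kcal_100g", "edible_fraction",
                 "hdb_group", "mddw_group"] + list(market.nutrients)
    prices.to_csv(prices_path, index=False)
    f[comp_cols].to_csv(composition_path, index=False)
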