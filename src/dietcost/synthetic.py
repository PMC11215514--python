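"""Seeded synthetic fixtures: markets, income distributions, oracle instances.

The market generator emulates a consumer-price-survey style item list: a
handful of priced items in each of the six Healthy Diet Basket groups with
group-archetype compositions (staples are dense and carbohydrate-heavy,
vegetables dilute and micronutrient-rich, oils nearly pure fat, ...),
covering all ten MDD-W groups, plus three deliberate edge cases —

* a zero-energy item (iodized salt) that has no price per calorie but can
  still enter the nutrient-adequacy LP;
* a strictly dominated item (same composition as an existing staple at a
  higher price) that must never change any indicator;
* a "complete food" whose nutrient density sits at the midpoint of the
  bundled illustrative bounds, guaranteeing the nutrient-adequacy LP is
  feasible on every generated market.

All generators are pure functions of their seed (numpy ``default_rng``),
with generated values rounded to fixed precision so tables are byte-stable
across platforms. Prices are drawn log-uniformly inside ``price_range`` to
spread per-calorie rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .food_data import (
    HDB_GROUPS,
    HDB_OTHER,
    MDDW_NONE,
    FoodItem,
    MarketTable,
    NutrientBounds,
    NutrientVector,
    RequirementProfile,
    load_requirement_profile,
)
from .affordability import (
    MEASURE_INCOME,
    IncomeDistribution,
)
from . import oracles


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic market draw."""

    seed: int = 0
    items_per_hdb_group: int = 3
    price_range: tuple[float, float] = (0.05, 2.0)  # currency per 100 g
    nutrient_noise: float = 0.25  # relative lognormal spread
    population: float = 1_000_000.0

    def __post_init__(self) -> None:
        if self.items_per_hdb_group < 1:
            raise ValueError("items_per_hdb_group must be >= 1")
        lo, hi = self.price_range
        if not (0 < lo < hi):
            raise ValueError("price_range must satisfy 0 < min < max")
        if self.nutrient_noise < 0:
            raise ValueError("nutrient_noise must be >= 0")


# rough per-100 g composition of a "generic food"; group factors below
# sculpt archetypes out of it
_BASELINE = {
    "protein": 5.0, "fat": 5.0, "carbohydrate": 15.0, "fiber": 2.0,
    "vitamin_a": 30.0, "vitamin_c": 5.0, "vitamin_d": 0.2, "vitamin_e": 0.8,
    "thiamin": 0.08, "riboflavin": 0.08, "niacin": 1.0, "vitamin_b6": 0.12,
    "folate": 25.0, "vitamin_b12": 0.2, "calcium": 30.0, "iron": 1.0,
    "zinc": 0.8, "magnesium": 25.0, "potassium": 250.0, "sodium": 50.0,
    "copper": 0.1, "selenium": 5.0,
}

_GROUP_ENERGY = {  # kcal per 100 g edible, archetype centre
    "starchy_staples": 350.0,
    "vegetables": 35.0,
    "fruits": 60.0,
    "animal_source_foods": 180.0,
    "legumes_nuts_seeds": 380.0,
    "fats_oils": 880.0,
}

_GROUP_FACTORS = {
    "starchy_staples": {
        "carbohydrate": 5.0, "protein": 1.6, "fiber": 1.5, "fat": 0.3,
        "thiamin": 2.0, "niacin": 2.5, "iron": 1.5, "vitamin_c": 0.0,
        "vitamin_a": 0.1, "vitamin_b12": 0.0, "vitamin_d": 0.0,
        "folate": 1.2, "magnesium": 2.0, "potassium": 0.6, "sodium": 0.1,
        "calcium": 0.5, "zinc": 1.5, "selenium": 2.0, "copper": 2.0,
        "vitamin_e": 0.5, "riboflavin": 0.8, "vitamin_b6": 1.5,
    },
    "vegetables": {
        "vitamin_a": 10.0, "vitamin_c": 8.0, "folate": 3.0, "fiber": 1.5,
        "carbohydrate": 0.4, "protein": 0.4, "fat": 0.1, "calcium": 1.5,
        "iron": 1.2, "potassium": 1.2, "vitamin_e": 1.5,
        "vitamin_b12": 0.0, "vitamin_d": 0.0,
    },
    "fruits": {
        "vitamin_c": 10.0, "vitamin_a": 2.0, "fiber": 1.2, "potassium": 1.1,
        "protein": 0.15, "fat": 0.1, "vitamin_b12": 0.0, "vitamin_d": 0.0,
    },
    "animal_source_foods": {
        "protein": 4.0, "fat": 2.4, "carbohydrate": 0.1, "vitamin_b12": 10.0,
        "vitamin_d": 10.0, "riboflavin": 3.0, "iron": 1.8, "zinc": 3.0,
        "calcium": 2.0, "vitamin_a": 2.0, "selenium": 4.0, "vitamin_c": 0.0,
    },
    "legumes_nuts_seeds": {
        "protein": 4.4, "fat": 2.5, "carbohydrate": 2.5, "fiber": 5.0,
        "folate": 6.0, "iron": 4.0, "zinc": 3.5, "magnesium": 5.0,
        "calcium": 2.5, "copper": 6.0, "potassium": 3.0,
        "vitamin_b12": 0.0, "vitamin_d": 0.0, "vitamin_c": 0.2,
    },
    "fats_oils": {
        "fat": 19.8, "vitamin_e": 18.0, "protein": 0.0, "carbohydrate": 0.0,
        "fiber": 0.0, "vitamin_a": 0.5, "vitamin_c": 0.0, "vitamin_d": 0.0,
        "thiamin": 0.0, "riboflavin": 0.0, "niacin": 0.0, "vitamin_b6": 0.0,
        "folate": 0.0, "vitamin_b12": 0.0, "calcium": 0.0, "iron": 0.0,
        "zinc": 0.0, "magnesium": 0.0, "potassium": 0.0, "sodium": 0.0,
        "copper": 0.0, "selenium": 0.0,
    },
}

_GROUP_PREFIX = {
    "starchy_staples": "staple",
    "vegetables": "veg",
    "fruits": "fruit",
    "animal_source_foods": "asf",
    "legumes_nuts_seeds": "legume",
    "fats_oils": "oil",
}

# MDD-W label cycled over the items of each HDB group; with >= 3 items per
# group all ten MDD-W groups are populated
_MDDW_CYCLE = {
    "starchy_staples": ("grains_roots_tubers",),
    "vegetables": ("dark_green_leafy_vegetables",
                   "vitamin_a_rich_fruits_vegetables", "other_vegetables"),
    "fruits": ("other_fruits", "vitamin_a_rich_fruits_vegetables"),
    "animal_source_foods": ("meat_poultry_fish", "dairy", "eggs"),
    "legumes_nuts_seeds": ("pulses", "nuts_seeds"),
    "fats_oils": (MDDW_NONE,),
}


def _midpoint_per_kcal(profile: RequirementProfile) -> dict[str, float]:
    """Per-kcal nutrient density that sits mid-bounds at the energy target."""
    out = {}
    for n, b in profile.bounds.items():
        mid = (b.lower + b.upper) / 2 if b.upper is not None else 1.5 * b.lower
        out[n] = mid / profile.energy_target
    return out


def generate_market(spec: FixtureSpec,
                    profile: RequirementProfile | None = None) -> MarketTable:
    """Deterministic synthetic market covering all HDB and MDD-W groups.

    ``metadata`` records the independently computed ground truth:
    ``cpk_ranking`` (item ids per HDB group, ascending price per kcal with
    lexicographic tie-break) and ``cheapest_by_group``.
    """
    rng = np.random.default_rng(spec.seed)
    if profile is None:
        profile = load_requirement_profile()
    lo, hi = spec.price_range
    nutrients = list(_BASELINE)

    items: list[FoodItem] = []
    prices: dict[str, float] = {}

    def draw_price() -> float:
        return round(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))), 4)

    for group in HDB_GROUPS:
        cycle = _MDDW_CYCLE[group]
        factors = _GROUP_FACTORS[group]
        for k in range(spec.items_per_hdb_group):
            energy = round(
                _GROUP_ENERGY[group] * float(np.exp(
                    rng.normal(0.0, 0.15))), 2)
            amounts = {}
            for n in nutrients:
                centre = _BASELINE[n] * factors.get(n, 1.0)
                noise = float(np.exp(rng.normal(0.0, spec.nutrient_noise)))
                amounts[n] = round(centre * noise, 4)
            edible = round(float(rng.uniform(0.6, 1.0)), 2)
            item_id = f"{_GROUP_PREFIX[group]}_{k:02d}"
            items.append(FoodItem(
                item_id=item_id,
                name=f"{group.replace('_', ' ')} item {k}",
                hdb_group=group,
                mddw_group=cycle[k % len(cycle)],
                composition=NutrientVector(energy, amounts),
                edible_fraction=edible,
            ))
            prices[item_id] = draw_price()

    # zero-energy item: iodized salt (non-rankable, LP-admissible)
    items.append(FoodItem(
        item_id="iodized_salt", name="iodized salt",
        hdb_group=HDB_OTHER, mddw_group=MDDW_NONE,
        composition=NutrientVector(0.0, {"sodium": 38000.0}),
        edible_fraction=1.0,
    ))
    prices["iodized_salt"] = round((lo * hi) ** 0.5 * 0.2, 4)

    # dominated item: first staple's composition at 1.5x its price
    staple = items[0]
    items.append(FoodItem(
        item_id="staple_dominated", name="dominated staple",
        hdb_group=staple.hdb_group, mddw_group=staple.mddw_group,
        composition=staple.composition,
        edible_fraction=staple.edible_fraction,
    ))
    prices["staple_dominated"] = round(prices[staple.item_id] * 1.5, 4)

    # complete food: mid-bounds density, keeps the CoNA LP feasible
    per_kcal = _midpoint_per_kcal(profile)
    complete_energy = 230.0
    items.append(FoodItem(
        item_id="complete_food", name="synthetic complete food",
        hdb_group=HDB_OTHER, mddw_group=MDDW_NONE,
        composition=NutrientVector(
            complete_energy,
            {n: round(v * complete_energy, 6) for n, v in per_kcal.items()},
        ),
        edible_fraction=1.0,
    ))
    prices["complete_food"] = round((lo * hi) ** 0.5, 4)

    market = MarketTable.from_items(
        items, prices,
        place=f"synthetic-{spec.seed}", period="2021",
        nutrients=nutrients,
    )

    # ground truth recorded independently of the optimizer module
    ranking: dict[str, list[str]] = {}
    for group in HDB_GROUPS:
        scored = []
        for it in items:
            if it.hdb_group != group or it.composition.energy_kcal <= 0:
                continue
            eff = prices[it.item_id] / it.edible_fraction
            scored.append((eff / it.composition.energy_kcal, it.item_id))
        ranking[group] = [iid for _, iid in sorted(scored)]
    market.metadata["cpk_ranking"] = ranking
    market.metadata["cheapest_by_group"] = {
        g: ids[0] for g, ids in ranking.items() if ids
    }
    market.metadata["seed"] = spec.seed
    return market


def generate_income_distribution(
    seed: int,
    mu: float = 0.5,
    sigma: float = 0.8,
    population: float = 1_000_000.0,
    as_percentiles: bool = False,
    measure: str = MEASURE_INCOME,
    currency: str = "PPP$",
) -> IncomeDistribution:
    """Lognormal per-capita daily income/expenditure distribution.

    With ``as_percentiles`` a 100-point percentile table is built from the
    quantiles of 20 000 seeded draws (rounded to 6 dp for byte stability);
    otherwise the exact lognormal parameters are carried.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not as_percentiles:
        return IncomeDistribution(
            kind="lognormal", mu=mu, sigma=sigma,
            measure=measure, population=population, currency=currency,
        )
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(mu, sigma, size=20_000)
    shares = np.arange(1, 101) / 100.0
    values = np.round(np.quantile(draws, shares), 6)
    return IncomeDistribution(
        kind="percentiles",
        percentiles=list(zip(shares.tolist(), values.tolist())),
        measure=measure, population=population, currency=currency,
    )


# --- oracle instances -----------------------------------------------------

_ORACLE_NUTRIENT_POOL = (
    ("protein", 46.0, 250.0),
    ("iron", 18.0, 45.0),
    ("calcium", 800.0, 2500.0),
)


@dataclass
class OracleInstance:
    """A small instance whose optimum is known by exhaustive enumeration."""

    kind: str
    market: MarketTable
    profile: RequirementProfile | None
    known_cost: float
    known_solution: dict
    bundle_pairs: dict[str, float] | None = None


def _mini_market(rng: np.random.Generator, nutrients, profile
                 ) -> MarketTable:
    """3-4 item market on few nutrients; one item is mid-bounds complete."""
    n_items = int(rng.integers(3, 5))
    per_kcal = _midpoint_per_kcal(profile)
    items, prices = [], {}
    for k in range(n_items):
        if k == 0:
            energy = 250.0
            amounts = {n: round(per_kcal[n] * energy, 6) for n in nutrients}
        else:
            energy = round(float(rng.uniform(100.0, 500.0)), 2)
            amounts = {
                n: round(float(rng.uniform(0.0, 2.0 * per_kcal[n] * energy)), 6)
                for n in nutrients
            }
        item_id = f"food_{k}"
        items.append(FoodItem(
            item_id=item_id, name=item_id, hdb_group=HDB_OTHER,
            mddw_group=MDDW_NONE,
            composition=NutrientVector(energy, amounts),
        ))
        prices[item_id] = round(float(np.exp(rng.uniform(
            np.log(0.1), np.log(1.0)))), 4)
    return MarketTable.from_items(items, prices, nutrients=nutrients)


def make_oracle_instance(kind: str, seed: int) -> OracleInstance:
    """Construct a seeded instance with an enumerated known optimum.

    Kinds: ``cona_vertex`` (vertex-enumerated LP), ``cohd_enum`` /
    ``codd_enum`` (subset-enumerated baskets), ``bundle_residual``
    (vertex-enumerated LP after fixing half the optimal basket as an
    in-kind bundle).
    """
    rng = np.random.default_rng(seed)
    if kind in ("cona_vertex", "bundle_residual"):
        n_nut = int(rng.integers(2, 4))
        picks = [_ORACLE_NUTRIENT_POOL[i] for i in range(n_nut)]
        nutrients = [p[0] for p in picks]
        bounds = {n: NutrientBounds(lower, upper) for n, lower, upper in picks}
        profile = RequirementProfile("oracle", 2330.0, bounds)
        market = _mini_market(rng, nutrients, profile)
        full = oracles.cona_by_enumeration(market, profile)
        assert full is not None, "oracle instance must be feasible by design"
        cost, x = full
        if kind == "cona_vertex":
            return OracleInstance(kind, market, profile, cost,
                                  {"quantities": x})
        # bundle: half the optimal basket, delivered as purchased grams
        pairs = {}
        for item_id, q in x.items():
            if q > 1e-9:
                ef = float(market.row(item_id)["edible_fraction"])
                pairs[item_id] = 0.5 * q * 100.0 / ef
        from .interventions import Bundle, residual_profile

        res_prof = residual_profile(profile, Bundle.from_pairs(pairs), market)
        residual = oracles.cona_by_enumeration(market, res_prof)
        assert residual is not None
        return OracleInstance(kind, market, profile, residual[0],
                              {"quantities": residual[1],
                               "full_cost": cost},
                              bundle_pairs=pairs)
    if kind == "cohd_enum":
        spec = FixtureSpec(seed=seed,
                           items_per_hdb_group=int(rng.integers(3, 5)))
        market = generate_market(spec)
        result = oracles.cohd_by_enumeration(market)
        assert result is not None
        cost, basket = result
        return OracleInstance(kind, market, None, cost,
                              {"basket": sorted(basket)})
    if kind == "codd_enum":
        spec = FixtureSpec(seed=seed, items_per_hdb_group=3)
        market = generate_market(spec)
        result = oracles.codd_by_enumeration(market, 2330.0)
        assert result is not None
        cost, groups = result
        return OracleInstance(kind, market, None, cost,
                              {"groups": sorted(groups)})
    raise ValueError(f"unknown oracle kind {kind!r}")
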