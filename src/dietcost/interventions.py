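"""Scenario engine: interventions on markets, requirements and transfers.

Models the standard levers of nutrition-sensitive programming against the
cost of a nutrient-adequate diet:

* **fortification** — replace an item's composition (and optionally price)
  and re-solve;
* **in-kind bundles / rations** — food given to the household at zero cost
  reduces the residual energy target and nutrient bounds, and the remaining
  least-cost purchase is re-optimized (residual CoNA);
* **cash offsets** — monetized transfers subtracted from the diet cost;
* **cash transfers** — coverage ratio of a target diet cost after applying
  the household's food expenditure share.

Households are modelled life-cycle style: one requirement profile per
member, costed individually on the shared market and summed (no shared-pot
optimization across members).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .affordability import AffordabilityResult, IncomeDistribution, share_unable_fng_rule
from .diet_optim import DietSolution, compute_cona
from .food_data import (
    MarketTable,
    NutrientBounds,
    NutrientVector,
    RequirementProfile,
)


@dataclass(frozen=True)
class BundleEntry:
    item_id: str
    grams_per_day: float  # grams as purchased per day

    def __post_init__(self) -> None:
        if self.grams_per_day < 0:
            raise ValueError("bundle grams must be >= 0")


@dataclass(frozen=True)
class Bundle:
    """An in-kind food bundle or ration delivered at zero cost."""

    entries: Sequence[BundleEntry] = ()
    transfer_value: float | None = None  # currency/day equivalent
    label: str = ""

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, float], **kwargs) -> "Bundle":
        return cls(entries=tuple(BundleEntry(i, g) for i, g in pairs.items()),
                   **kwargs)


@dataclass(frozen=True)
class Household:
    """Life-cycle household: one requirement profile per member."""

    members: Sequence[RequirementProfile]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("household must have at least one member")


@dataclass
class HouseholdCost:
    total_cost: float
    per_member: list[tuple[str, DietSolution]]


@dataclass
class ScenarioResult:
    base_cost: float
    scenario_cost: float
    label: str = ""
    affordability_before: AffordabilityResult | None = None
    affordability_after: AffordabilityResult | None = None

    @property
    def percent_reduction(self) -> float:
        if self.base_cost <= 0:
            raise ValueError("percent reduction undefined for base cost <= 0")
        return 100.0 * (self.base_cost - self.scenario_cost) / self.base_cost

    def to_dict(self) -> dict:
        out = {
            "label": self.label,
            "base_cost": self.base_cost,
            "scenario_cost": self.scenario_cost,
            "percent_reduction": self.percent_reduction,
        }
        for key, res in (("affordability_before", self.affordability_before),
                         ("affordability_after", self.affordability_after)):
            out[key] = None if res is None else {
                "share_unable": res.share_unable,
                "headcount": res.headcount,
                "threshold_rule": res.threshold_rule,
            }
        return out


# --- fortification --------------------------------------------------------


def apply_fortification(
    market: MarketTable,
    item_id: str,
    fortified_composition: NutrientVector,
    fortified_price: float | None = None,
    *,
    keep_original: bool = False,
    fortified_id: str | None = None,
) -> MarketTable:
    """Market with ``item_id`` replaced by its fortified version.

    By default the fortified item substitutes the unfortified one; with
    ``keep_original=True`` both are available and the fortified row gets
    ``fortified_id`` (default ``<item_id>_fortified``). The input market is
    never mutated.
    """
    frame = market.frame.copy()
    match = frame.index[frame["item_id"] == item_id]
    if len(match) == 0:
        raise KeyError(f"unknown item {item_id!r}")
    idx = match[0]
    new_row = frame.loc[idx].copy()
    new_row["energy_kcal_100g"] = fortified_composition.energy_kcal
    for n in market.nutrients:
        new_row[n] = float(fortified_composition.amounts.get(n, new_row[n]))
    if fortified_price is not None:
        if fortified_price <= 0:
            raise ValueError("fortified price must be > 0")
        new_row["price"] = fortified_price
        new_row["effective_price"] = fortified_price / new_row["edible_fraction"]
    if keep_original:
        new_row["item_id"] = fortified_id or f"{item_id}_fortified"
        new_row["name"] = f"{new_row['name']} (fortified)"
        frame.loc[len(frame)] = new_row
    else:
        frame.loc[idx] = new_row
    return MarketTable(
        place=market.place, period=market.period, currency=market.currency,
        frame=frame, nutrients=market.nutrients,
        metadata=dict(market.metadata),
    )


# --- bundles and residual CoNA -------------------------------------------


def bundle_contribution(bundle: Bundle, market: MarketTable
                        ) -> tuple[float, dict[str, float]]:
    """Daily energy (kcal) and nutrient totals supplied by a bundle.

    Bundle quantities are grams *as purchased*; the edible fraction converts
    them to edible 100 g units before applying the composition.
    """
    energy = 0.0
    totals = {n: 0.0 for n in market.nutrients}
    for entry in bundle.entries:
        row = market.row(entry.item_id)  # raises KeyError if unknown
        q_edible = entry.grams_per_day / 100.0 * float(row["edible_fraction"])
        energy += q_edible * float(row["energy_kcal_100g"])
        for n in market.nutrients:
            totals[n] += q_edible * float(row[n])
    return energy, totals


def residual_profile(profile: RequirementProfile, bundle: Bundle,
                     market: MarketTable) -> RequirementProfile:
    """Requirements left after consuming the bundle at zero cost.

    The bundle's energy is removed from the equality target; its nutrient
    contribution is subtracted from both lower bounds (floored at zero) and
    upper bounds. A bundle that alone breaches an upper bound makes the
    residual problem infeasible and raises ``ValueError`` naming the
    nutrient; bundle energy above the target is an error.
    """
    energy_b, totals = bundle_contribution(bundle, market)
    if energy_b > profile.energy_target * (1 + 1e-12):
        raise ValueError(
            f"bundle energy {energy_b:.1f} kcal exceeds target "
            f"{profile.energy_target:.1f} kcal"
        )
    bounds = _residual_bounds(profile, totals)
    return RequirementProfile(
        group_label=f"{profile.group_label}|residual",
        energy_target=profile.energy_target - energy_b,
        bounds=bounds,
    )


def _residual_bounds(profile: RequirementProfile,
                     totals: Mapping[str, float]) -> dict[str, NutrientBounds]:
    bounds = {}
    for n, b in profile.bounds.items():
        supplied = totals.get(n, 0.0)
        upper = None
        if b.upper is not None:
            upper = b.upper - supplied
            if upper < -1e-9:
                raise ValueError(
                    f"bundle alone violates the upper bound for {n!r} "
                    f"({supplied} > {b.upper})"
                )
            upper = max(upper, 0.0)
        bounds[n] = NutrientBounds(max(b.lower - supplied, 0.0), upper)
    return bounds


def residual_cona(profile: RequirementProfile, bundle: Bundle,
                  market: MarketTable,
                  item_caps: Mapping[str, float] | None = None
                  ) -> DietSolution:
    """Cost remaining to the household to reach nutrient adequacy after
    consuming ``bundle`` at zero cost (the ration / in-kind transfer model).

    With an empty bundle this is exactly CoNA. A bundle that covers the
    whole energy target costs nothing further if its residual lower bounds
    are all met; if nutrient gaps remain at zero residual energy, nothing
    can be bought without breaking energy balance and the residual problem
    is infeasible.
    """
    energy_b, totals = bundle_contribution(bundle, market)
    if energy_b > profile.energy_target * (1 + 1e-12):
        raise ValueError(
            f"bundle energy {energy_b:.1f} kcal exceeds target "
            f"{profile.energy_target:.1f} kcal"
        )
    residual_energy = profile.energy_target - energy_b
    bounds = _residual_bounds(profile, totals)
    if residual_energy <= 1e-9 * profile.energy_target:
        unmet = sorted(n for n, b in bounds.items() if b.lower > 1e-9)
        if unmet:
            return DietSolution(
                indicator="CoNA", status="infeasible",
                diagnostics={"bundle": bundle.label,
                             "reason": "bundle covers the energy target but "
                                       "leaves nutrient gaps",
                             "impossible_nutrients": unmet})
        return DietSolution(indicator="CoNA", status="optimal",
                            items=[], total_cost=0.0, energy_total=0.0,
                            nutrient_totals={n: 0.0 for n in market.nutrients},
                            diagnostics={"bundle": bundle.label,
                                         "bundle_energy_kcal": energy_b})
    res_profile = RequirementProfile(
        group_label=f"{profile.group_label}|residual",
        energy_target=residual_energy,
        bounds=bounds,
    )
    sol = compute_cona(market, res_profile, item_caps=item_caps)
    sol.diagnostics["bundle"] = bundle.label
    sol.diagnostics["bundle_energy_kcal"] = energy_b
    return sol


# --- households -----------------------------------------------------------


def household_cona(household: Household, market: MarketTable,
                   item_caps: Mapping[str, float] | None = None
                   ) -> HouseholdCost:
    """Sum of per-member nutrient-adequate diet costs on a shared market.

    Additive over members by construction; raises ``ValueError`` naming the
    first member whose individual problem is infeasible.
    """
    per_member = []
    total = 0.0
    for member in household.members:
        sol = compute_cona(market, member, item_caps=item_caps)
        if not sol.is_optimal:
            raise ValueError(
                f"nutrient-adequate diet infeasible for member "
                f"{member.group_label!r}: {sol.diagnostics}"
            )
        per_member.append((member.group_label, sol))
        total += sol.total_cost
    return HouseholdCost(total_cost=total, per_member=per_member)


# --- transfers ------------------------------------------------------------


def transfer_coverage_ratio(transfer_value: float, food_share: float,
                            target_cost: float) -> float:
    """Fraction of a target diet cost covered by the food share of a cash
    transfer: ``transfer_value * food_share / target_cost`` (uncapped)."""
    if target_cost <= 0:
        raise ValueError("target_cost must be > 0")
    if not (0 < food_share <= 1):
        raise ValueError("food_share must be in (0, 1]")
    if transfer_value < 0:
        raise ValueError("transfer_value must be >= 0")
    return transfer_value * food_share / target_cost


def apply_cash_offset(base_cost: float, offset_value: float) -> float:
    """Diet cost after a monetized offset (e.g. garden-crop sales),
    floored at zero."""
    if offset_value < 0:
        raise ValueError("offset_value must be >= 0")
    return max(0.0, base_cost - offset_value)


# --- comparison -----------------------------------------------------------


def _as_cost(value: DietSolution | float) -> float:
    if isinstance(value, DietSolution):
        if not value.is_optimal:
            raise ValueError("cannot compare an infeasible solution")
        return float(value.total_cost)
    return float(value)


def compare_scenarios(base: DietSolution | float,
                      scenario: DietSolution | float,
                      dist: IncomeDistribution | None = None,
                      label: str = "") -> ScenarioResult:
    """Before/after comparison of diet costs, optionally with affordability
    under the food-expenditure rule."""
    base_cost = _as_cost(base)
    scenario_cost = _as_cost(scenario)
    if base_cost <= 0:
        raise ValueError("base cost must be > 0")
    before = after = None
    if dist is not None:
        before = share_unable_fng_rule(base_cost, dist)
        after = share_unable_fng_rule(scenario_cost, dist)
    return ScenarioResult(
        base_cost=base_cost,
        scenario_cost=scenario_cost,
        label=label,
        affordability_before=before,
        affordability_after=after,
    )
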