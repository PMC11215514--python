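"""The ladder of least-cost diet indicators: CoCA, CoNA, CoDD, CoHD.

Four benchmark diets of increasing ambition are costed on one market table:

* **CoCA** — cost of caloric adequacy: meet the energy target with the
  single cheapest item per calorie (by default restricted to starchy
  staples).
* **CoNA** — cost of nutrient adequacy: linear program minimizing cost
  subject to an energy equality and lower/upper bounds for every configured
  nutrient.
* **CoDD** — cost of diet diversity: cheapest items from at least five of
  the ten MDD-W food groups, energy split equally across selected groups.
* **CoHD** — cost of a healthy diet: cheapest items within each of the six
  Healthy Diet Basket groups at the basket's per-group counts and energy
  allocations.

All selection by "cheapest" means lowest effective price per kcal; exact
ties break by ascending ``item_id`` so outputs are deterministic. Zero-
energy items (iodized salt, water) have no price per calorie: they never
enter the per-calorie selections but remain ordinary LP variables in CoNA.

Costs are the contract. CoNA may admit alternative optimal bases; the
optimal *cost* is unique and is what callers should compare.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .food_data import (
    HDB_GROUPS,
    MDDW_GROUPS,
    MDDW_NONE,
    HDBSpec,
    MarketTable,
    RequirementProfile,
)

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"

#: quantities below this (100 g units/day) are dropped from reported baskets
_QUANTITY_EPS = 1e-10


@dataclass(frozen=True)
class ItemAllocation:
    """One selected item: daily quantity and its energy/cost contribution."""

    item_id: str
    quantity: float  # 100 g edible units per day
    energy_kcal: float  # kcal/day
    cost: float  # currency/day


@dataclass
class DietSolution:
    """Result of one indicator computation on one market."""

    indicator: str
    status: str
    items: list[ItemAllocation] = field(default_factory=list)
    total_cost: float | None = None
    energy_total: float | None = None
    nutrient_totals: dict[str, float] = field(default_factory=dict)
    groups_used: frozenset[str] = frozenset()
    diagnostics: dict = field(default_factory=dict)

    @property
    def is_optimal(self) -> bool:
        return self.status == STATUS_OPTIMAL

    def quantities(self) -> dict[str, float]:
        return {a.item_id: a.quantity for a in self.items}

    def to_dict(self) -> dict:
        return {
            "indicator": self.indicator,
            "status": self.status,
            "total_cost": self.total_cost,
            "energy_kcal": self.energy_total,
            "items": [
                {
                    "item_id": a.item_id,
                    "quantity_100g": a.quantity,
                    "energy_kcal": a.energy_kcal,
                    "cost": a.cost,
                }
                for a in self.items
            ],
            "groups_used": sorted(self.groups_used),
            "nutrient_totals": dict(self.nutrient_totals),
            "diagnostics": self.diagnostics,
        }


@dataclass
class LadderResult:
    """All rungs of the diet-cost ladder computed on one market/period."""

    coca: DietSolution
    cona: DietSolution
    cohd: DietSolution
    codd: DietSolution | None = None

    def rungs(self) -> list[DietSolution]:
        out = [self.coca, self.cona]
        if self.codd is not None:
            out.append(self.codd)
        out.append(self.cohd)
        return out


def _infeasible(indicator: str, **diagnostics) -> DietSolution:
    return DietSolution(indicator=indicator, status=STATUS_INFEASIBLE,
                        diagnostics=diagnostics)


def _nutrient_totals(market: MarketTable, quantities: Mapping[str, float]
                     ) -> dict[str, float]:
    q = np.array([quantities.get(i, 0.0) for i in market.item_ids])
    totals = market.nutrient_matrix().T @ q
    return {n: float(v) for n, v in zip(market.nutrients, totals)}


def _ranked(frame: pd.DataFrame) -> pd.DataFrame:
    """Rankable rows sorted by (cost per kcal, item_id)."""
    f = frame[frame["energy_kcal_100g"] > 0].copy()
    f["cpk"] = f["effective_price"] / f["energy_kcal_100g"]
    return f.sort_values(["cpk", "item_id"], kind="mergesort")


def _solution_from_shares(indicator: str, market: MarketTable,
                          shares: Sequence[tuple[pd.Series, float]],
                          groups_used: Sequence[str]) -> DietSolution:
    """Build a DietSolution from (row, kcal share) pairs."""
    items = []
    for row, kcal in shares:
        density = float(row["energy_kcal_100g"])
        quantity = kcal / density
        items.append(ItemAllocation(
            item_id=str(row["item_id"]),
            quantity=quantity,
            energy_kcal=kcal,
            cost=quantity * float(row["effective_price"]),
        ))
    items.sort(key=lambda a: a.item_id)
    quantities = {a.item_id: a.quantity for a in items}
    return DietSolution(
        indicator=indicator,
        status=STATUS_OPTIMAL,
        items=items,
        total_cost=float(sum(a.cost for a in items)),
        energy_total=float(sum(a.energy_kcal for a in items)),
        nutrient_totals=_nutrient_totals(market, quantities),
        groups_used=frozenset(groups_used),
    )


# --- CoCA -----------------------------------------------------------------


def compute_coca(market: MarketTable, energy_target: float,
                 staples_only: bool = True) -> DietSolution:
    """Cost of caloric adequacy: the energy target from the single item with
    the lowest price per calorie.

    With ``staples_only`` (the default, matching the bottom rung of the
    ladder) only starchy staples are eligible; with ``staples_only=False``
    the cheapest calorie source of any group is used, which equals the
    optimum of the energy-only LP over all items and serves as a lower bound
    for CoNA.
    """
    if energy_target <= 0:
        raise ValueError("energy_target must be > 0")
    frame = market.frame
    if staples_only:
        frame = frame[frame["hdb_group"] == "starchy_staples"]
    ranked = _ranked(frame)
    if ranked.empty:
        return _infeasible(
            "CoCA", reason="no rankable eligible item",
            staples_only=staples_only,
        )
    best = ranked.iloc[0]
    sol = _solution_from_shares("CoCA", market, [(best, energy_target)],
                                [str(best["hdb_group"])])
    return sol


# --- CoNA -----------------------------------------------------------------


def _cona_matrices(market: MarketTable, profile: RequirementProfile):
    """LP ingredients: cost vector, energy row, stacked nutrient rows."""
    nutrients = list(profile.bounds)
    a = market.nutrient_matrix(nutrients)  # items x nutrients
    c = market.effective_prices()
    energy = market.energy()
    a_ub_rows, b_ub = [], []
    row_labels = []
    for j, n in enumerate(nutrients):
        b = profile.bounds[n]
        if b.lower > 0:
            a_ub_rows.append(-a[:, j])
            b_ub.append(-b.lower)
            row_labels.append((n, "lower"))
        if b.upper is not None:
            a_ub_rows.append(a[:, j])
            b_ub.append(b.upper)
            row_labels.append((n, "upper"))
    return c, energy, a, nutrients, a_ub_rows, np.array(b_ub), row_labels


def _cona_diagnosis(market: MarketTable, profile: RequirementProfile,
                    caps: np.ndarray | None) -> list[str]:
    """Nutrients whose bound cannot be met even ignoring all other
    constraints (only variable bounds 0 <= q <= cap apply)."""
    impossible = []
    a = market.nutrient_matrix(list(profile.bounds))
    for j, n in enumerate(profile.bounds):
        b = profile.bounds[n]
        if b.lower <= 0:
            continue
        col = a[:, j]
        if caps is None:
            attainable = math.inf if (col > 0).any() else 0.0
        else:
            attainable = float(col @ caps)
        if attainable < b.lower:
            impossible.append(n)
    return impossible


def compute_cona(market: MarketTable, profile: RequirementProfile,
                 item_caps: Mapping[str, float] | None = None) -> DietSolution:
    """Cost of nutrient adequacy by linear programming.

    Minimizes total cost subject to an *equality* on energy (the target is
    energy balance, not an energy floor) and the profile's lower/upper
    bounds per nutrient, with 0 <= quantity <= cap per item. Nutrients in the
    profile that the market's composition does not report are treated as
    zero contributions.

    Returns an optimal solution with a per-nutrient constraint report
    (totals, bounds, and which are binding), or an infeasible solution whose
    diagnostics list every nutrient whose bound cannot be met even in
    isolation.
    """
    c, energy, a, nutrients, a_ub_rows, b_ub, row_labels = _cona_matrices(
        market, profile)
    n_items = len(market)
    if item_caps is None:
        caps_arr = None
        bounds = [(0.0, None)] * n_items
    else:
        caps_arr = np.array([float(item_caps.get(i, math.inf))
                             for i in market.item_ids])
        bounds = [(0.0, None if math.isinf(cap) else cap) for cap in caps_arr]

    res = linprog(
        c,
        A_ub=np.array(a_ub_rows) if a_ub_rows else None,
        b_ub=b_ub if a_ub_rows else None,
        A_eq=energy.reshape(1, -1),
        b_eq=[profile.energy_target],
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        finite_caps = None
        if caps_arr is not None:
            finite_caps = caps_arr
        return _infeasible(
            "CoNA",
            reason="linear program infeasible",
            impossible_nutrients=_cona_diagnosis(market, profile, finite_caps),
            profile=profile.group_label,
        )

    q = np.asarray(res.x)
    items = []
    for i, item_id in enumerate(market.item_ids):
        if q[i] > _QUANTITY_EPS:
            items.append(ItemAllocation(
                item_id=item_id,
                quantity=float(q[i]),
                energy_kcal=float(q[i] * energy[i]),
                cost=float(q[i] * c[i]),
            ))
    items.sort(key=lambda al: al.item_id)
    totals = a.T @ q
    nutrient_totals = _nutrient_totals(market, {m: float(v) for m, v
                                                in zip(market.item_ids, q)})
    report = {}
    for j, n in enumerate(nutrients):
        b = profile.bounds[n]
        tol = 1e-6 * max(1.0, abs(totals[j]))
        report[n] = {
            "total": float(totals[j]),
            "lower": b.lower,
            "upper": b.upper,
            "binding_lower": bool(b.lower > 0 and totals[j] <= b.lower + tol),
            "binding_upper": bool(b.upper is not None
                                  and totals[j] >= b.upper - tol),
        }
    selected_groups = {
        str(market.row(al.item_id)["hdb_group"]) for al in items
    }
    return DietSolution(
        indicator="CoNA",
        status=STATUS_OPTIMAL,
        items=items,
        total_cost=float(sum(al.cost for al in items)),
        energy_total=float(q @ energy),
        nutrient_totals=nutrient_totals,
        groups_used=frozenset(selected_groups),
        diagnostics={"constraint_report": report,
                     "lp_objective": float(res.fun)},
    )


# --- CoDD -----------------------------------------------------------------


def compute_codd(market: MarketTable, energy_target: float,
                 groups_required: int = 5) -> DietSolution:
    """Cost of diet diversity at the MDD-W threshold.

    Takes the cheapest item per calorie in each populated MDD-W group,
    selects the ``groups_required`` groups whose champions are cheapest, and
    splits the energy target equally among the selected items. Greedy
    selection is optimal here because the objective is separable across
    groups with identical energy shares.
    """
    if energy_target <= 0:
        raise ValueError("energy_target must be > 0")
    if not (1 <= groups_required <= len(MDDW_GROUPS)):
        raise ValueError("groups_required must be in 1..10")
    frame = market.frame[market.frame["mddw_group"] != MDDW_NONE]
    ranked = _ranked(frame)
    champions = ranked.groupby("mddw_group", sort=False).head(1)
    populated = list(champions["mddw_group"])
    if len(populated) < groups_required:
        return _infeasible(
            "CoDD",
            reason="too few populated MDD-W groups",
            populated_groups=sorted(populated),
            groups_required=groups_required,
        )
    champions = champions.sort_values(["cpk", "item_id"], kind="mergesort")
    chosen = champions.head(groups_required)
    share = energy_target / groups_required
    sol = _solution_from_shares(
        "CoDD", market,
        [(row, share) for _, row in chosen.iterrows()],
        [str(g) for g in chosen["mddw_group"]],
    )
    return sol


# --- CoHD -----------------------------------------------------------------


def compute_cohd(market: MarketTable, hdb: HDBSpec | None = None) -> DietSolution:
    """Cost of a healthy diet against a Healthy Diet Basket specification.

    Within each of the six HDB groups the ``items`` cheapest items per
    calorie are selected and the group's energy allocation is split equally
    among them; under the default basket this yields 11 items and 2330
    kcal/day. Infeasible when any group has too few rankable items, naming
    the deficient groups.
    """
    if hdb is None:
        hdb = HDBSpec.default()
    shares: list[tuple[pd.Series, float]] = []
    deficient: dict[str, int] = {}
    for group in HDB_GROUPS:
        target = hdb.groups[group]
        ranked = _ranked(market.frame[market.frame["hdb_group"] == group])
        if len(ranked) < target.items:
            deficient[group] = len(ranked)
            continue
        per_item_kcal = target.energy_kcal / target.items
        for _, row in ranked.head(target.items).iterrows():
            shares.append((row, per_item_kcal))
    if deficient:
        return _infeasible(
            "CoHD",
            reason="groups with too few rankable items",
            deficient_groups=deficient,
        )
    return _solution_from_shares("CoHD", market, shares, list(HDB_GROUPS))


# --- the ladder -----------------------------------------------------------


def compute_ladder(market: MarketTable, profile: RequirementProfile,
                   hdb: HDBSpec | None = None, *,
                   include_codd: bool = True,
                   staples_only_coca: bool = True,
                   item_caps: Mapping[str, float] | None = None
                   ) -> LadderResult:
    """Compute every rung of the diet-cost ladder on identical inputs.

    CoCA uses the basket's total energy as its target. Per-indicator
    infeasibility is carried in each solution's status; one infeasible rung
    never aborts the others.
    """
    if hdb is None:
        hdb = HDBSpec.default()
    coca = compute_coca(market, hdb.total_energy, staples_only=staples_only_coca)
    cona = compute_cona(market, profile, item_caps=item_caps)
    cohd = compute_cohd(market, hdb)
    codd = (compute_codd(market, hdb.total_energy) if include_codd else None)
    return LadderResult(coca=coca, cona=cona, cohd=cohd, codd=codd)


# --- independent feasibility certificate ---------------------------------


def verify_solution(market: MarketTable, profile: RequirementProfile,
                    solution: DietSolution, rel_tol: float = 1e-6) -> list[str]:
    """Re-check a CoNA-style solution against its constraints, independent
    of the solver. Returns a list of violation descriptions (empty = clean).
    """
    if not solution.is_optimal:
        return ["solution not optimal"]
    violations = []
    q = solution.quantities()
    if any(v < -rel_tol for v in q.values()):
        violations.append("negative quantity")
    energy = sum(
        qty * float(market.row(i)["energy_kcal_100g"]) for i, qty in q.items()
    )
    if not math.isclose(energy, profile.energy_target,
                        rel_tol=rel_tol, abs_tol=rel_tol):
        violations.append(
            f"energy {energy} != target {profile.energy_target}")
    for n, b in profile.bounds.items():
        total = sum(
            qty * float(market.row(i).get(n, 0.0)) for i, qty in q.items()
        )
        slack = rel_tol * max(1.0, abs(total))
        if total < b.lower - slack:
            violations.append(f"{n} total {total} below lower {b.lower}")
        if b.upper is not None and total > b.upper + slack:
            violations.append(f"{n} total {total} above upper {b.upper}")
    return violations
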