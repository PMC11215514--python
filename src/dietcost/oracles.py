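"""Brute-force reference optimizers for cross-checking the indicators.

These deliberately avoid the production code paths: the CoNA oracle
enumerates every vertex of the LP polytope from first principles, and the
CoHD/CoDD oracles enumerate every admissible basket. They are exponential
in problem size and intended for small instances (<= 4 items, <= 3
nutrients for the LP; <= ~5 items per group for the baskets).
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping

import numpy as np

from .food_data import (
    HDB_GROUPS,
    MDDW_GROUPS,
    HDBSpec,
    MarketTable,
    RequirementProfile,
)

_FEAS_TOL = 1e-8


def solve_lp_by_vertex_enumeration(
    c: np.ndarray,
    a_eq: np.ndarray,
    b_eq: np.ndarray,
    a_ub: np.ndarray | None,
    b_ub: np.ndarray | None,
    caps: np.ndarray | None = None,
) -> tuple[float, np.ndarray] | None:
    """Minimize ``c @ x`` s.t. ``a_eq x = b_eq``, ``a_ub x <= b_ub``,
    ``0 <= x <= caps`` by enumerating basic feasible points.

    Assumes a bounded feasible region (true whenever an energy-equality row
    with all-positive coefficients is present, or caps are finite). Returns
    ``(cost, x)`` at the optimum or ``None`` if no vertex is feasible.
    """
    n = c.shape[0]
    rows: list[tuple[np.ndarray, float]] = [
        (a_eq[i], float(b_eq[i])) for i in range(a_eq.shape[0])
    ]
    n_eq = len(rows)
    if a_ub is not None:
        for i in range(a_ub.shape[0]):
            rows.append((a_ub[i], float(b_ub[i])))
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        rows.append((-e, 0.0))  # -x_i <= 0
        if caps is not None and math.isfinite(caps[i]):
            rows.append((e, float(caps[i])))

    def feasible(x: np.ndarray) -> bool:
        for k, (a, b) in enumerate(rows):
            v = float(a @ x)
            tol = _FEAS_TOL * max(1.0, abs(b))
            if k < n_eq:
                if abs(v - b) > tol:
                    return False
            elif v > b + tol:
                return False
        return True

    best: tuple[float, np.ndarray] | None = None
    candidate_idx = range(n_eq, len(rows))
    for extra in itertools.combinations(candidate_idx, n - n_eq):
        active = list(range(n_eq)) + list(extra)
        a_mat = np.array([rows[k][0] for k in active])
        b_vec = np.array([rows[k][1] for k in active])
        if np.linalg.matrix_rank(a_mat, tol=1e-10) < n:
            continue
        try:
            x = np.linalg.solve(a_mat, b_vec)
        except np.linalg.LinAlgError:
            continue
        if not feasible(x):
            continue
        cost = float(c @ x)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, x)
    return best


def cona_by_enumeration(
    market: MarketTable,
    profile: RequirementProfile,
    item_caps: Mapping[str, float] | None = None,
) -> tuple[float, dict[str, float]] | None:
    """CoNA optimum by vertex enumeration, built directly from the frame."""
    f = market.frame
    c = f["effective_price"].to_numpy(dtype=float)
    energy = f["energy_kcal_100g"].to_numpy(dtype=float)
    rows_ub, b_ub = [], []
    for n, b in profile.bounds.items():
        col = (f[n].to_numpy(dtype=float) if n in f.columns
               else np.zeros(len(f)))
        if b.lower > 0:
            rows_ub.append(-col)
            b_ub.append(-b.lower)
        if b.upper is not None:
            rows_ub.append(col)
            b_ub.append(b.upper)
    caps = None
    if item_caps is not None:
        caps = np.array([float(item_caps.get(i, math.inf))
                         for i in market.item_ids])
    result = solve_lp_by_vertex_enumeration(
        c,
        energy.reshape(1, -1),
        np.array([profile.energy_target]),
        np.array(rows_ub) if rows_ub else None,
        np.array(b_ub) if rows_ub else None,
        caps,
    )
    if result is None:
        return None
    cost, x = result
    return cost, dict(zip(market.item_ids, x))


def cohd_by_enumeration(market: MarketTable, hdb: HDBSpec | None = None
                        ) -> tuple[float, frozenset[str]] | None:
    """CoHD optimum by exhaustive enumeration of per-group item subsets."""
    if hdb is None:
        hdb = HDBSpec.default()
    f = market.frame
    per_group_choices: list[list[tuple[float, frozenset[str]]]] = []
    for group in HDB_GROUPS:
        target = hdb.groups[group]
        rows = f[(f["hdb_group"] == group) & (f["energy_kcal_100g"] > 0)]
        if len(rows) < target.items:
            return None
        options = []
        per_item_kcal = target.energy_kcal / target.items
        for combo in itertools.combinations(rows.index, target.items):
            cost = sum(
                per_item_kcal * f.at[i, "effective_price"]
                / f.at[i, "energy_kcal_100g"]
                for i in combo
            )
            options.append((cost, frozenset(f.at[i, "item_id"] for i in combo)))
        per_group_choices.append(options)
    # the objective separates across groups, so the overall optimum is the
    # cheapest enumerated subset of each group
    total_cost = 0.0
    basket: set[str] = set()
    for options in per_group_choices:
        cost, ids = min(options, key=lambda o: (o[0], tuple(sorted(o[1]))))
        total_cost += cost
        basket |= ids
    return total_cost, frozenset(basket)


def codd_by_enumeration(market: MarketTable, energy_target: float,
                        groups_required: int = 5
                        ) -> tuple[float, frozenset[str]] | None:
    """CoDD optimum by brute force over all group subsets and champions."""
    f = market.frame
    share = energy_target / groups_required
    group_best: dict[str, float] = {}
    for group in MDDW_GROUPS:
        rows = f[(f["mddw_group"] == group) & (f["energy_kcal_100g"] > 0)]
        if rows.empty:
            continue
        group_best[group] = min(
            share * r["effective_price"] / r["energy_kcal_100g"]
            for _, r in rows.iterrows()
        )
    if len(group_best) < groups_required:
        return None
    best = None
    for combo in itertools.combinations(sorted(group_best), groups_required):
        cost = sum(group_best[g] for g in combo)
        if best is None or cost < best[0] - 1e-15:
            best = (cost, frozenset(combo))
    return best
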