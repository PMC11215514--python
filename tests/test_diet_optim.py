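"""The diet-cost ladder: CoCA, CoNA, CoDD, CoHD and their invariants."""

import pytest

from dietcost import (
    FixtureSpec,
    FoodItem,
    MarketTable,
    NutrientBounds,
    NutrientVector,
    RequirementProfile,
    compute_coca,
    compute_codd,
    compute_cohd,
    compute_cona,
    compute_ladder,
    generate_market,
    verify_solution,
)
from dietcost.oracles import (
    codd_by_enumeration,
    cohd_by_enumeration,
    cona_by_enumeration,
)


def _item(item_id, energy, group="starchy_staples", mddw="none",
          ef=1.0, **amounts):
    return FoodItem(item_id=item_id, name=item_id, hdb_group=group,
                    mddw_group=mddw,
                    composition=NutrientVector(energy, amounts),
                    edible_fraction=ef)


class TestCoCA:
    def test_picks_cheapest_per_kcal_staple(self):
        # 0.0001/kcal vs 0.0002/kcal at a 2330 kcal target
        m = MarketTable.from_items(
            [_item("maize", 400.0), _item("rice", 400.0)],
            {"maize": 0.04, "rice": 0.08},
        )
        sol = compute_coca(m, 2330.0)
        assert sol.is_optimal
        assert [a.item_id for a in sol.items] == ["maize"]
        assert sol.total_cost == pytest.approx(0.233)
        assert sol.energy_total == pytest.approx(2330.0)

    def test_single_item_market(self):
        m = MarketTable.from_items([_item("maize", 365.0)], {"maize": 0.5})
        sol = compute_coca(m, 2000.0)
        assert sol.items[0].quantity == pytest.approx(2000.0 / 365.0)

    def test_exact_tie_breaks_lexicographically(self):
        m = MarketTable.from_items(
            [_item("b_grain", 400.0), _item("a_grain", 400.0)],
            {"b_grain": 0.04, "a_grain": 0.04},
        )
        sol = compute_coca(m, 2330.0)
        assert sol.items[0].item_id == "a_grain"

    def test_no_eligible_staple_infeasible(self):
        m = MarketTable.from_items([_item("oil", 880.0, group="fats_oils")],
                                   {"oil": 0.4})
        sol = compute_coca(m, 2330.0, staples_only=True)
        assert sol.status == "infeasible"
        # all-items variant can still run
        assert compute_coca(m, 2330.0, staples_only=False).is_optimal


class TestCoNA:
    def test_single_food_forced_by_energy_equality(self):
        m = MarketTable.from_items([_item("only", 250.0, protein=10.0)],
                                   {"only": 0.8})
        prof = RequirementProfile("p", 2330.0,
                                  {"protein": NutrientBounds(40.0, 250.0)})
        sol = compute_cona(m, prof)
        assert sol.is_optimal
        assert sol.total_cost == pytest.approx(0.8 * 2330.0 / 250.0)

    def test_two_foods_binding_lower_bound_matches_vertex_oracle(self):
        # cheap energy-dense food vs pricier protein source: the optimum
        # sits where the protein lower bound and energy equality intersect
        m = MarketTable.from_items(
            [_item("grain", 350.0, protein=6.0),
             _item("bean", 340.0, protein=22.0)],
            {"grain": 0.10, "bean": 0.60},
        )
        prof = RequirementProfile("p", 2330.0,
                                  {"protein": NutrientBounds(60.0)})
        sol = compute_cona(m, prof)
        oracle = cona_by_enumeration(m, prof)
        assert sol.is_optimal and oracle is not None
        assert sol.total_cost == pytest.approx(oracle[0], rel=1e-9)
        assert sol.diagnostics["constraint_report"]["protein"]["binding_lower"]

    def test_dominated_item_changes_nothing(self):
        items = [_item("grain", 350.0, protein=6.0),
                 _item("bean", 340.0, protein=22.0)]
        prices = {"grain": 0.10, "bean": 0.60}
        prof = RequirementProfile("p", 2330.0,
                                  {"protein": NutrientBounds(60.0)})
        base = compute_cona(MarketTable.from_items(items, prices), prof)
        worse = items + [_item("lux_grain", 350.0, protein=6.0)]
        prices2 = dict(prices, lux_grain=0.90)
        with_dominated = compute_cona(
            MarketTable.from_items(worse, prices2), prof)
        assert with_dominated.total_cost == pytest.approx(
            base.total_cost, rel=1e-9)

    def test_infeasible_diagnosis_names_nutrient(self):
        m = MarketTable.from_items([_item("grain", 350.0, protein=6.0)],
                                   {"grain": 0.10})
        prof = RequirementProfile(
            "p", 2330.0,
            {"protein": NutrientBounds(10.0),
             "vitamin_b12": NutrientBounds(2.0)})  # nothing supplies B12
        sol = compute_cona(m, prof)
        assert sol.status == "infeasible"
        assert sol.diagnostics["impossible_nutrients"] == ["vitamin_b12"]

    def test_item_caps_never_cheaper(self, market7, profile):
        free = compute_cona(market7, profile)
        capped = compute_cona(market7, profile,
                              item_caps={i: 3.0 for i in market7.item_ids})
        if capped.is_optimal:
            assert capped.total_cost >= free.total_cost - 1e-9

    def test_feasibility_certificate(self, market7, profile):
        sol = compute_cona(market7, profile)
        assert verify_solution(market7, profile, sol) == []


class TestCoDD:
    def test_ten_groups_yield_exactly_five(self, market7):
        sol = compute_codd(market7, 2330.0)
        assert sol.is_optimal
        assert len(sol.groups_used) == 5
        assert len(sol.items) == 5
        assert sol.energy_total == pytest.approx(2330.0)

    def test_exactly_five_groups_forced(self):
        groups = ["grains_roots_tubers", "pulses", "dairy", "eggs",
                  "other_fruits"]
        items = [_item(f"i{k}", 300.0, group="other", mddw=g)
                 for k, g in enumerate(groups)]
        prices = {f"i{k}": 0.2 + 0.3 * k for k in range(5)}
        sol = compute_codd(MarketTable.from_items(items, prices), 2330.0)
        assert sol.groups_used == frozenset(groups)

    def test_too_few_groups_infeasible(self):
        m = MarketTable.from_items(
            [_item("a", 300.0, mddw="pulses", group="other")], {"a": 0.2})
        sol = compute_codd(m, 2330.0)
        assert sol.status == "infeasible"

    def test_six_groups_matches_subset_enumeration(self):
        groups = ["grains_roots_tubers", "pulses", "dairy", "eggs",
                  "other_fruits", "other_vegetables"]
        items = [_item(f"i{k}", 250.0 + 30 * k, group="other", mddw=g)
                 for k, g in enumerate(groups)]
        prices = {"i0": 0.2, "i1": 0.5, "i2": 0.4, "i3": 0.9,
                  "i4": 0.3, "i5": 5.0}  # one much more expensive
        m = MarketTable.from_items(items, prices)
        sol = compute_codd(m, 2330.0)
        cost, chosen = codd_by_enumeration(m, 2330.0)
        assert sol.total_cost == pytest.approx(cost, rel=1e-12)
        assert sol.groups_used == chosen
        assert "other_vegetables" not in chosen


class TestCoHD:
    def test_default_basket_shape(self, market7, hdb):
        sol = compute_cohd(market7, hdb)
        assert sol.is_optimal
        assert len(sol.items) == 11
        assert len(sol.groups_used) == 6
        assert sol.energy_total == pytest.approx(2330.0, rel=1e-12)

    def test_per_group_energy_allocations_respected(self, market7, hdb):
        sol = compute_cohd(market7, hdb)
        by_group = {g: 0.0 for g in hdb.groups}
        for a in sol.items:
            by_group[str(market7.row(a.item_id)["hdb_group"])] += a.energy_kcal
        for g, target in hdb.groups.items():
            assert by_group[g] == pytest.approx(target.energy_kcal, rel=1e-12)

    def test_deficient_group_named(self, hdb):
        items = [_item(f"s{k}", 350.0) for k in range(2)]
        items += [_item(f"v{k}", 35.0, group="vegetables") for k in range(2)]
        items += [_item(f"f{k}", 60.0, group="fruits") for k in range(2)]
        items += [_item(f"a{k}", 180.0, group="animal_source_foods")
                  for k in range(2)]
        items += [_item("l0", 380.0, group="legumes_nuts_seeds"),
                  _item("o0", 880.0, group="fats_oils")]
        prices = {it.item_id: 0.5 for it in items}
        sol = compute_cohd(MarketTable.from_items(items, prices), hdb)
        assert sol.status == "infeasible"
        assert list(sol.diagnostics["deficient_groups"]) == ["vegetables"]

    def test_matches_exhaustive_enumeration_four_per_group(self, hdb):
        market = generate_market(FixtureSpec(seed=11, items_per_hdb_group=4))
        sol = compute_cohd(market, hdb)
        cost, basket = cohd_by_enumeration(market, hdb)
        assert sol.total_cost == pytest.approx(cost, rel=1e-9)
        assert {a.item_id for a in sol.items} == set(basket)


class TestLadder:
    def test_nutrient_bounds_force_diversity(self):
        """A market whose staple lacks vitamin A: energy alone is cheap but
        nutrient adequacy must buy the dearer vitamin source."""
        m = MarketTable.from_items(
            [_item("grain", 350.0, vitamin_a=0.0),
             _item("greens", 40.0, group="vegetables",
                   mddw="dark_green_leafy_vegetables", vitamin_a=300.0)],
            {"grain": 0.08, "greens": 0.30},
        )
        prof = RequirementProfile("p", 2330.0,
                                  {"vitamin_a": NutrientBounds(500.0)})
        coca = compute_coca(m, 2330.0)
        cona = compute_cona(m, prof)
        oracle = cona_by_enumeration(m, prof)
        assert cona.total_cost == pytest.approx(oracle[0], rel=1e-9)
        assert coca.total_cost < cona.total_cost

    def test_identical_complete_items_collapse_ladder(self):
        comp = dict(protein=12.0, vitamin_a=300.0)
        m = MarketTable.from_items(
            [_item("a", 300.0, **comp), _item("b", 300.0, **comp)],
            {"a": 0.5, "b": 0.5},
        )
        prof = RequirementProfile(
            "p", 2330.0, {"protein": NutrientBounds(40.0, 200.0)})
        coca = compute_coca(m, 2330.0)
        cona = compute_cona(m, prof)
        assert cona.total_cost == pytest.approx(coca.total_cost, rel=1e-9)

    def test_price_doubling_doubles_every_rung(self, market7, profile, hdb):
        base = compute_ladder(market7, profile, hdb)
        doubled = compute_ladder(market7.scale_prices(2.0), profile, hdb)
        for b, d in zip(base.rungs(), doubled.rungs()):
            assert d.total_cost == pytest.approx(2.0 * b.total_cost,
                                                 rel=1e-12)

    def test_infeasible_rung_does_not_abort_others(self, profile, hdb):
        # no starchy staples at all: CoCA and CoHD fail, CoNA can still run
        market = generate_market(FixtureSpec(seed=7))
        frame = market.frame[market.frame["hdb_group"] != "starchy_staples"]
        stripped = MarketTable(place=market.place, period=market.period,
                               currency=market.currency,
                               frame=frame.reset_index(drop=True),
                               nutrients=market.nutrients)
        ladder = compute_ladder(stripped, profile, hdb)
        assert ladder.coca.status == "infeasible"
        assert ladder.cohd.status == "infeasible"
        assert ladder.cona.is_optimal

    def test_removing_an_item_never_cheapens(self, market7, profile, hdb):
        base = compute_ladder(market7, profile, hdb)
        victim = base.cohd.items[0].item_id
        frame = market7.frame[market7.frame["item_id"] != victim]
        smaller = MarketTable(place=market7.place, period=market7.period,
                              currency=market7.currency,
                              frame=frame.reset_index(drop=True),
                              nutrients=market7.nutrients)
        shrunk = compute_ladder(smaller, profile, hdb)
        for b, s in zip(base.rungs(), shrunk.rungs()):
            if b.is_optimal and s.is_optimal:
                assert s.total_cost >= b.total_cost - 1e-9
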