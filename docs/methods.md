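# Methods

## Model overview

The package computes daily least-cost benchmark diets from a *market
table*: the food items locally available in one place and period, each with
a retail price, a composition record per 100 g edible portion, and labels
under two food-group taxonomies (six Healthy Diet Basket groups, ten MDD-W
groups). Four indicators of increasing ambition form the diet-cost ladder.

**Units.** Prices are standardized on construction to currency per 100 g
*edible* portion (`price / edible_fraction`); all diet quantities are in
100 g-edible units per day; energy is kcal. Every optimizer shares this one
convention.

**CoCA (caloric adequacy).** The single cheapest item per calorie supplies
the whole energy target. By default only starchy staples are eligible,
matching the "survival" rung of the ladder; `staples_only=False` gives the
all-items energy-only optimum, which is also the exact lower bound of the
CoNA linear program (a linear objective over the energy simplex attains its
minimum at the cheapest single source).

**CoNA (nutrient adequacy).** A linear program: minimize `p·q` subject to
an energy *equality* `e·q = E` and per-nutrient bounds `l ≤ Aq ≤ u`, with
`0 ≤ q ≤ cap` (caps optional). Energy is an equality, not a floor: the
target is energy balance, and an inequality would admit degenerate
low-energy solutions when energy-dense foods are expensive. Solved with
scipy's HiGHS backend. On infeasibility, the diagnostics list every
nutrient whose bound cannot be met even in isolation (no item supplies it,
or caps bound its attainable total below the requirement). Optimal
solutions carry a per-nutrient constraint report with binding flags. The
optimal *cost* is the contract; with degenerate optima the item basis need
not be unique, so comparisons should be on cost.

**CoDD (diet diversity).** Within each populated MDD-W group take the
champion (lowest price per calorie); select the 5 groups with the cheapest
champions; split the energy target equally across the selected items.
Because the objective is separable across groups at identical energy
shares, the greedy choice is exactly optimal (the test suite confirms it
against subset enumeration).

**CoHD (healthy diet).** Within each of the six HDB groups the required
number of cheapest-per-calorie items is selected and the group's energy
allocation is split equally among them. The default basket is 2/3/2/2/1/1
items with energy allocations 1160/110/160/300/300/300 kcal (2330 total).
The counts and total come from the global basket definition; the per-group
energy allocations are not fixed by that definition alone and are shipped
as editable configuration taken from the published basket methodology. The
equal within-group energy split is this package's reproducible default —
the basket standard fixes counts and group energies but not the split.

**Ties.** All "cheapest per calorie" selections break exact ties by
ascending `item_id`, so outputs are deterministic across runs and
platforms.

**Zero-energy items.** Items with zero energy density (iodized salt, water)
have no defined price per calorie. They are excluded from the per-calorie
selections (CoCA/CoDD/CoHD) but remain ordinary LP variables in CoNA,
where they can serve micronutrient bounds.

## Affordability

Diet costs map to population shares via a distribution of per-capita daily
income/expenditure (global rule: unable when the diet costs more than a
food share — default 52% — of the total; equivalently income strictly below
`cost / food_share`) or of food expenditure (unable when food expenditure
is strictly below the diet cost). Both boundaries are strict on the unable
side: a value exactly at the threshold counts as able. Headcounts are
`round(share × population)`. All values are per capita per day; household
aggregates must be pre-divided by household size.

Percentile tables reconstruct the distribution function as follows
(`interpolation="linear"`, the default): rows are bin upper endpoints, mass
is spread linearly inside each bin, the first row is an atom at its value
(its bin has no lower endpoint), tied values are atoms, and extrapolation
outside the table is flat. `interpolation="step"` instead treats every row
as an atom, which is the faithful reading of genuinely discrete or grouped
data (a two-point distribution is representable exactly only this way).
Lognormal distributions use the closed-form distribution function; the test
suite checks it against 10⁶ Monte-Carlo draws within three binomial
standard errors.

## Interventions

All scenarios act on the cost of nutrient adequacy and re-solve the LP:

- **Fortification** replaces an item's composition (and optionally price);
  by default the fortified item substitutes its unfortified counterpart,
  with a flag to keep both.
- **Bundles/rations** (grams as purchased per day, converted through the
  edible fraction) are consumed at zero cost: the bundle's energy is
  removed from the equality target and its nutrient totals are subtracted
  from lower bounds (floored at 0) *and* upper bounds. A bundle that alone
  breaches an upper bound is an explicit infeasibility, never silently
  clipped; a bundle that covers the whole energy target while leaving
  nutrient gaps is likewise infeasible, since nothing further can be bought
  under energy balance (except via zero-energy items, which that corner
  case does not attempt). Residual cost with an empty bundle is identically
  CoNA; enlarging a bundle never increases the residual cost.
- **Cash offsets** subtract a monetized value from the cost, floored at 0.
- **Cash transfers** report the coverage ratio
  `transfer × food_share / target_cost`, uncapped (callers may cap at 1).
- **Households** are life-cycle sets of requirement profiles costed
  individually on the shared market and summed — no shared-pot
  optimization across members; the per-member breakdown is retained.
  Rations are applied daily; a days-per-week weighting can be emulated by
  scaling bundle quantities.

## Synthetic data generator

No real price, composition, or income data ships with the package. The
generator emulates a consumer-price-survey style item list: a configurable
number of items (default 3) in each HDB group, with group-archetype
compositions (staples energy-dense and carbohydrate-heavy, vegetables
dilute and vitamin-rich, oils nearly pure fat, ...) jittered by lognormal
noise (default 25% relative), edible fractions in [0.6, 1], and prices
drawn log-uniformly in a configurable range so per-calorie rankings vary
across seeds. Three constructed items are always present: a zero-energy
iodized salt, a strictly dominated duplicate of the first staple at 1.5×
its price (the LP must never buy it), and a synthetic "complete food" whose
nutrient density sits at the midpoint of the bundled illustrative bounds,
which guarantees CoNA feasibility on every generated market. Income
distributions are lognormal (default μ=0.5, σ=0.8 of log daily value),
optionally materialized as a 100-point percentile table from 20 000 seeded
draws.

Everything is a pure function of its seed (numpy `default_rng`), with
generated values rounded to fixed precision so tables are byte-identical
across platforms. The generator does **not** mimic real price levels,
item-description matching, seasonal or spatial price variation, or real
national income distributions — passing tests demonstrate the correctness
of the algorithms and their contracts, not empirical adequacy on any real
market.

The bundled requirement profile enumerates 22 nutrients with *illustrative*
bounds (plausible orders of magnitude for an adult woman); it exists so the
pipeline runs end to end and must be replaced with vetted reference intakes
for real assessments. Missing composition values are treated as zero with a
logged warning, never imputed — conservative for lower bounds, and a
documented downward bias for upper-bound slack.

## Numerical choices

- LP: HiGHS via `scipy.optimize.linprog` at its default (≈1e-9)
  feasibility/optimality tolerances; reported quantities below 1e-10 are
  dropped from baskets.
- Independent verification: a hand-written vertex-enumeration solver (all
  basic points of the constraint system) cross-checks CoNA and the residual
  LP on small instances to 1e-9 relative cost; CoHD/CoDD are checked
  against exhaustive subset enumeration. Test comparisons use 1e-6–1e-9
  relative on costs and 1e-12 on exact algebraic identities (price
  scaling, PPP/CPI commutation).
- PPP conversion and CPI updating are scalar multiplications and therefore
  commute with every indicator; this homogeneity is asserted in tests.
- Degenerate inputs: empty eligible sets, deficient HDB groups, or
  unsatisfiable nutrient bounds yield structured `infeasible` results with
  diagnoses, not exceptions; genuine input errors (nonpositive prices,
  unknown items, mixed currencies) raise.

## Problem sizes in the test suite

Oracle-equivalence checks run 200 seeded instances (LPs of ≤ 4 items and
≤ 3 nutrients against vertex enumeration; full synthetic markets against
basket enumeration), and the ladder scaling/ordering laws run on 100 seeded
markets of ~21 items and 22 nutrients; the whole suite completes in well
under a minute on one CPU.

## Known limitations

- No integer programming, palatability or meal-structure constraints
  beyond per-item daily caps; no multi-day menu sequencing.
- Household costs are sums of individual least-cost diets; intra-household
  allocation is not modelled.
- The 52% food-share threshold is a single global constant; country-
  specific non-food requirement adjustments are not implemented.
- Item-description matching between price lists and composition tables is
  the caller's responsibility (join on `item_id`).
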