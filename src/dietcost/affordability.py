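"""Affordability: from diet costs to population shares and headcounts.

Two rules are implemented:

* the **global rule**: a person cannot afford a diet when its cost exceeds
  a fixed share (default 52%) of per-capita income or total expenditure —
  equivalently when income falls strictly below ``cost / food_share``;
* the **food-expenditure (FNG) rule**: a household cannot afford a
  nutrient-adequate diet when its food expenditure falls strictly below the
  diet's cost.

Both boundaries are strict on the unable side: a value exactly at the
threshold counts as able to afford. All values are per capita per day;
household-level inputs must be divided by household size by the caller.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .diet_optim import LadderResult

MEASURE_INCOME = "income_expenditure"
MEASURE_FOOD = "food_expenditure"

DEFAULT_FOOD_SHARE = 0.52


class CurrencyMismatchError(ValueError):
    """Diet cost and income distribution are in different currencies."""


@dataclass
class IncomeDistribution:
    """Per-capita daily income/expenditure distribution for a population.

    Either a percentile table — ordered ``(cumulative share, value)`` pairs,
    shares strictly increasing in (0, 1] and values nondecreasing — or
    lognormal parameters ``mu``/``sigma`` of log daily value.

    For percentile tables the distribution function is reconstructed per the
    ``interpolation`` mode:

    * ``"linear"`` (default): rows are bin upper endpoints; mass is spread
      linearly inside each bin, the first row is an atom at its value, tied
      values are atoms, and extrapolation outside the table is flat.
    * ``"step"``: every row is an atom at its value (discrete/grouped data).
    """

    kind: Literal["percentiles", "lognormal"]
    measure: str = MEASURE_INCOME
    population: float = 0.0
    currency: str = "PPP$"
    percentiles: Sequence[tuple[float, float]] | None = None
    mu: float | None = None
    sigma: float | None = None
    interpolation: Literal["linear", "step"] = "linear"

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError("population must be >= 0")
        if self.kind == "percentiles":
            if not self.percentiles:
                raise ValueError("percentile table required")
            shares = [s for s, _ in self.percentiles]
            values = [v for _, v in self.percentiles]
            if any(b <= a for a, b in zip(shares, shares[1:])):
                raise ValueError("cumulative shares must be strictly increasing")
            if not (0 < shares[0] and shares[-1] <= 1 + 1e-12):
                raise ValueError("shares must lie in (0, 1]")
            if any(b < a for a, b in zip(values, values[1:])):
                raise ValueError("percentile values must be nondecreasing")
        elif self.kind == "lognormal":
            if self.mu is None or self.sigma is None:
                raise ValueError("lognormal distribution needs mu and sigma")
            if self.sigma <= 0:
                raise ValueError("sigma must be > 0")
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    # -- distribution function --------------------------------------------

    def share_below(self, threshold: float) -> float:
        """P(value < threshold), strict."""
        if self.kind == "lognormal":
            if threshold <= 0:
                return 0.0
            return float(stats.lognorm.cdf(threshold, s=self.sigma,
                                           scale=np.exp(self.mu)))
        shares = [s for s, _ in self.percentiles]
        values = [v for _, v in self.percentiles]
        if self.interpolation == "step":
            mass = 0.0
            prev = 0.0
            for s, v in zip(shares, values):
                if v < threshold:
                    mass += s - prev
                prev = s
            return mass
        # linear: first index whose value >= threshold
        idx = bisect.bisect_left(values, threshold)
        if idx == 0:
            return 0.0
        if idx == len(values):
            return shares[-1]
        v_lo, v_hi = values[idx - 1], values[idx]
        s_lo, s_hi = shares[idx - 1], shares[idx]
        if v_hi == v_lo:  # defensive; bisect_left lands on first of a tie
            return s_lo
        t = (threshold - v_lo) / (v_hi - v_lo)
        return s_lo + t * (s_hi - s_lo)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Monte-Carlo draws (lognormal kind only)."""
        if self.kind != "lognormal":
            raise ValueError("sampling implemented for lognormal kind")
        return rng.lognormal(self.mu, self.sigma, size=n)


@dataclass
class AffordabilityResult:
    indicator: str
    threshold_rule: str  # "food_share" or "food_expenditure"
    share_unable: float
    headcount: int
    diet_cost: float | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.share_unable <= 1.0):
            raise ValueError("share_unable must lie in [0, 1]")


def _result(indicator: str, rule: str, share: float,
            dist: IncomeDistribution, cost: float | None,
            **details) -> AffordabilityResult:
    share = min(max(share, 0.0), 1.0)
    return AffordabilityResult(
        indicator=indicator,
        threshold_rule=rule,
        share_unable=share,
        headcount=int(round(share * dist.population)),
        diet_cost=cost,
        details=details,
    )


def share_unable_food_share_rule(
    diet_cost: float,
    dist: IncomeDistribution,
    food_share: float = DEFAULT_FOOD_SHARE,
    indicator: str = "CoHD",
    currency: str | None = None,
) -> AffordabilityResult:
    """Share and headcount unable to afford a diet under the global rule.

    Unable when the diet costs more than ``food_share`` of per-capita
    income/expenditure, i.e. income < diet_cost / food_share (strict).
    """
    if dist.measure != MEASURE_INCOME:
        raise ValueError(
            "food-share rule requires a total income/expenditure distribution"
        )
    if not (0 < food_share <= 1):
        raise ValueError("food_share must be in (0, 1]")
    if currency is not None and currency != dist.currency:
        raise CurrencyMismatchError(
            f"diet cost in {currency!r} vs distribution in {dist.currency!r}"
        )
    if diet_cost <= 0:
        warnings.warn("nonpositive diet cost; share unable set to 0",
                      stacklevel=2)
        return _result(indicator, "food_share", 0.0, dist, diet_cost,
                       food_share=food_share)
    threshold = diet_cost / food_share
    share = dist.share_below(threshold)
    return _result(indicator, "food_share", share, dist, diet_cost,
                   food_share=food_share, income_threshold=threshold)


def share_unable_fng_rule(
    cona_cost: float,
    dist: IncomeDistribution,
    indicator: str = "CoNA",
    currency: str | None = None,
) -> AffordabilityResult:
    """Share and headcount with food expenditure strictly below the cost of
    the nutrient-adequate diet."""
    if dist.measure != MEASURE_FOOD:
        raise ValueError("FNG rule requires a food-expenditure distribution")
    if currency is not None and currency != dist.currency:
        raise CurrencyMismatchError(
            f"diet cost in {currency!r} vs distribution in {dist.currency!r}"
        )
    if cona_cost <= 0:
        warnings.warn("nonpositive diet cost; share unable set to 0",
                      stacklevel=2)
        return _result(indicator, "food_expenditure", 0.0, dist, cona_cost)
    share = dist.share_below(cona_cost)
    return _result(indicator, "food_expenditure", share, dist, cona_cost)


def ladder_headcounts(
    ladder: LadderResult,
    dist: IncomeDistribution,
    food_share: float = DEFAULT_FOOD_SHARE,
) -> list[AffordabilityResult | None]:
    """One affordability result per ladder rung (global food-share rule).

    Infeasible rungs yield ``None`` in their slot; the others are still
    computed. Because the distribution function is monotone, shares are
    automatically nondecreasing in rung cost.
    """
    out: list[AffordabilityResult | None] = []
    for rung in ladder.rungs():
        if not rung.is_optimal:
            out.append(None)
            continue
        out.append(share_unable_food_share_rule(
            rung.total_cost, dist, food_share, indicator=rung.indicator))
    return out
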