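"""Convert source-granularity tables to the 1-year 0-100 grid.

National inputs arrive at mixed granularity: counts in 5-year age groups up
to 90+, rates in the same groups, blood pressure and costs in broad bands,
utilities in 10-year bands.  The lifetable needs everything per single year
of age to 100.  Three primitives cover all of it:

* :func:`disaggregate_counts` - temporal-disaggregation-style interpolation
  of grouped counts to single years.  Implemented as a monotone cubic
  (PCHIP) interpolation of the cumulative sum, differenced back to 1-year
  values: monotonicity of the cumulative guarantees non-negative outputs and
  every source group's total is conserved exactly.
* :func:`extrapolate_rates` - polynomial trend fitted on the oldest group
  midpoints, evaluated beyond the last observed group (91-100), clamped to
  [0, rate_cap].
* :func:`expand_bands` - piecewise-constant expansion of banded values
  (band lower edge inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .grids import MAX_AGE, N_AGES

Group = tuple[int, int, float]  # (age_lo, age_hi inclusive, value)


@dataclass
class GroupedSeries:
    """An ordered, contiguous, non-overlapping set of age groups."""

    groups: list[Group]
    value_kind: str = "count"  # "count" | "rate"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("empty grouped series")
        if self.value_kind not in ("count", "rate"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        prev_hi = None
        for lo, hi, value in self.groups:
            if hi < lo:
                raise ValueError(f"group ({lo}, {hi}) has hi < lo")
            if prev_hi is not None and lo != prev_hi + 1:
                raise ValueError(f"groups not contiguous at age {lo}")
            if value < 0:
                raise ValueError(f"negative value {value} in group ({lo}, {hi})")
            prev_hi = hi

    @property
    def age_lo(self) -> int:
        return self.groups[0][0]

    @property
    def age_hi(self) -> int:
        return self.groups[-1][1]

    def values(self) -> np.ndarray:
        return np.array([g[2] for g in self.groups], dtype=float)

    def midpoints(self, open_ended_width: float = 5.0) -> np.ndarray:
        """Group midpoints for trend fitting.

        Open-ended terminal groups (90+, 75+) are assigned midpoint
        lo + open_ended_width/2, i.e. lo + 2.5 by default.
        """
        mids = []
        for k, (lo, hi, _) in enumerate(self.groups):
            if k == len(self.groups) - 1 and hi >= MAX_AGE:
                mids.append(lo + open_ended_width / 2.0)
            else:
                mids.append((lo + hi) / 2.0)
        return np.array(mids)


def disaggregate_counts(series: GroupedSeries) -> np.ndarray:
    """Split grouped counts into smooth, non-negative 1-year counts.

    Returns an array of length ``age_hi - age_lo + 1`` (one value per single
    year of age spanned by the series) whose sum within each source group
    equals that group's value to 1e-9.
    """
    if series.value_kind != "count":
        raise ValueError("disaggregate_counts requires value_kind='count'")
    # Cumulative totals at group boundaries: x is the left edge of each age,
    # so the cumulative at x = hi+1 includes the whole group.
    edges = [series.age_lo] + [hi + 1 for _, hi, _ in series.groups]
    cum = np.concatenate([[0.0], np.cumsum(series.values())])
    interp = PchipInterpolator(edges, cum)
    ages_edges = np.arange(series.age_lo, series.age_hi + 2)
    cum_1y = interp(ages_edges)
    out = np.diff(cum_1y)
    # PCHIP through monotone data is monotone; clip fp dust.
    return np.clip(out, 0.0, None)


def extrapolate_rates(
    rates_1y: np.ndarray,
    groups: GroupedSeries,
    max_age: int = MAX_AGE,
    poly_order: int = 2,
    k_groups: int = 6,
    rate_cap: float = 1.0,
) -> np.ndarray:
    """Extend 1-year rates beyond the last observed group with a polynomial trend.

    ``rates_1y`` must cover ages 0..groups.age_hi (longer input is allowed
    and preserved below the extrapolation range).  A degree-``poly_order``
    polynomial is fitted to the (midpoint, value) pairs of the oldest
    ``k_groups`` groups and evaluated at ages ``groups.age_hi + 1 .. max_age``,
    clamped to ``[0, rate_cap]``.  Values at or below ``groups.age_hi`` are
    returned untouched.
    """
    if poly_order not in (1, 2, 3):
        raise ValueError("poly_order must be 1, 2 or 3")
    tail = groups.groups[-k_groups:]
    if len(tail) < poly_order + 1:
        raise ValueError(
            f"need at least {poly_order + 1} groups to fit order {poly_order}, have {len(tail)}"
        )
    mids = groups.midpoints()[-len(tail):]
    vals = groups.values()[-len(tail):]
    coeffs = np.polyfit(mids, vals, deg=poly_order)
    out = np.zeros(max_age + 1)
    n_keep = min(len(rates_1y), groups.age_hi + 1)
    out[:n_keep] = rates_1y[:n_keep]
    extra_ages = np.arange(groups.age_hi + 1, max_age + 1)
    out[extra_ages] = np.clip(np.polyval(coeffs, extra_ages), 0.0, rate_cap)
    return out


def expand_bands(bands: Sequence[Group], max_age: int = MAX_AGE) -> np.ndarray:
    """Piecewise-constant expansion of banded values to a 1-year grid.

    Bands are closed intervals with the lower edge inclusive and must cover
    every age 0..max_age.
    """
    out = np.full(max_age + 1, np.nan)
    for lo, hi, value in bands:
        out[lo : min(hi, max_age) + 1] = value
    if np.isnan(out).any():
        missing = int(np.flatnonzero(np.isnan(out))[0])
        raise ValueError(f"age {missing} not covered by any band")
    return out


def aggregate_to_groups(values_1y: np.ndarray, edges: Sequence[tuple[int, int]], weights: np.ndarray | None = None) -> list[Group]:
    """Aggregate a 1-year series into groups: sums for counts, weighted means for rates."""
    groups: list[Group] = []
    for lo, hi in edges:
        sl = slice(lo, hi + 1)
        if weights is None:
            groups.append((lo, hi, float(np.sum(values_1y[sl]))))
        else:
            w = weights[sl]
            tot = w.sum()
            mean = float(np.sum(values_1y[sl] * w) / tot) if tot > 0 else float(np.mean(values_1y[sl]))
            groups.append((lo, hi, mean))
    return groups


def group_rates_to_1y(
    rate_groups: GroupedSeries,
    population_1y: np.ndarray,
    max_age: int = MAX_AGE,
    poly_order: int = 2,
    k_groups: int = 6,
    rate_cap: float = 1.0,
) -> np.ndarray:
    """Full pipeline for a grouped rate series: counts-preserving disaggregation
    to single years plus polynomial tail extrapolation.

    Group rates are converted to event counts with the 1-year population,
    the counts are disaggregated (conserving each group total), divided back
    by population to give smooth 1-year rates, and ages beyond the last group
    are filled by the polynomial trend.  Ages below the first group get rate 0.
    """
    pop = np.asarray(population_1y, dtype=float)
    count_groups = []
    for lo, hi, rate in rate_groups.groups:
        grp_pop = pop[lo : hi + 1].sum()
        count_groups.append((lo, hi, rate * grp_pop))
    counts_1y = disaggregate_counts(GroupedSeries(count_groups, "count"))
    rates = np.zeros(N_AGES)
    span = slice(rate_groups.age_lo, rate_groups.age_hi + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(pop[span] > 0, counts_1y / np.where(pop[span] > 0, pop[span], 1.0), 0.0)
    rates[span] = np.clip(r, 0.0, rate_cap)
    if rate_groups.age_hi < max_age:
        rates = extrapolate_rates(rates, rate_groups, max_age, poly_order, k_groups, rate_cap)
    return rates
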