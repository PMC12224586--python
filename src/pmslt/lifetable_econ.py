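"""Lifetable, QALY and healthcare-cost accounting.

The lifetable combines the per-disease sub-models into population outcomes:
scenario changes in disease-specific mortality are subtracted from all-cause
mortality, survivors and trapezoid life-years are accumulated to age 100,
life-years are weighted into QALYs by a background utility times
multiplicative disease decrements, and per-prevalent-case healthcare costs
are accrued and discounted.

Cost construction mirrors burden-of-illness practice: attributable direct
costs per disease and band, a proportional allocation of unattributable
direct costs by each disease's share of the attributable total, division by
prevalent cases to get cost per case per year, and inflation to the
analysis currency year.

Discounting is (1 + r)^(-t) with t the year index since cohort start (year
0 undiscounted); QALYs and costs accruing in year t carry factor
(1 + r)^(-t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disease_model import rate_to_prob


@dataclass
class EconSettings:
    """Economic evaluation settings.

    ``discount_rate`` defaults to 1.5%/year with 0% and 3% as standard
    sensitivity values; ``horizon_years`` of None means lifetime (to age
    100).  ``cpi_factor`` inflates source-year costs to the analysis year.
    """

    discount_rate: float = 0.015
    horizon_years: int | None = None
    currency_year: int = 2019
    cpi_factor: float = 1.0

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        if self.horizon_years is not None and self.horizon_years <= 0:
            raise ValueError("horizon must be positive")


def discount_factor(years_from_start, rate: float):
    """Present-value factor (1 + r)^(-t)."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    return (1.0 + rate) ** (-np.asarray(years_from_start, dtype=float))


def adjusted_mortality(all_cause, disease_mortality_baseline, disease_mortality_scenario):
    """Scenario all-cause mortality: subtract per-disease mortality changes.

    ``disease_mortality_*`` are dicts disease -> array aligned with
    ``all_cause``.  The result is clamped to [0, 1]; the baseline lifetable
    uses ``all_cause`` unchanged.
    """
    m = np.asarray(all_cause, dtype=float)
    delta = np.zeros_like(m)
    for d in disease_mortality_baseline:
        delta = delta + (
            np.asarray(disease_mortality_baseline[d], dtype=float)
            - np.asarray(disease_mortality_scenario[d], dtype=float)
        )
    return np.clip(m - delta, 0.0, 1.0)


def build_lifetable(mortality):
    """Survivors and trapezoid life-years from annual mortality rates.

    ``mortality`` has shape (..., T); returns ``(l, L)`` with survivors
    ``l`` of shape (..., T+1) starting at 1 and life-years
    ``L = (l_t + l_{t+1}) / 2`` of shape (..., T).  Annual death
    probabilities are q = 1 - e^(-m).
    """
    m = np.asarray(mortality, dtype=float)
    q = rate_to_prob(m)
    l = np.concatenate(
        [np.ones(m.shape[:-1] + (1,)), np.cumprod(1.0 - q, axis=-1)], axis=-1
    )
    L = 0.5 * (l[..., :-1] + l[..., 1:])
    return l, L


def utility_weight(background, prevalence_by_disease: dict, decrement_by_disease: dict):
    """Per-year utility: background times multiplicative disease decrements,
    each disease contributing (1 - prevalence * decrement)."""
    w = np.asarray(background, dtype=float).copy()
    for d, prev in prevalence_by_disease.items():
        dec = decrement_by_disease[d]
        if not 0 <= dec <= 1:
            raise ValueError(f"utility decrement outside [0, 1] for {d}")
        w = w * (1.0 - np.asarray(prev, dtype=float) * dec)
    return w


def qalys(life_years, background_utility, prevalence_by_disease, decrement_by_disease, rate: float, horizon_years: int | None = None):
    """Discounted QALYs per cohort: sum over years of L * utility * factor.

    All year-indexed arrays have shape (..., T); returns per-cohort totals.
    """
    L = np.asarray(life_years, dtype=float)
    w = utility_weight(background_utility, prevalence_by_disease, decrement_by_disease)
    T = L.shape[-1]
    df = discount_factor(np.arange(T), rate)
    if horizon_years is not None:
        df = np.where(np.arange(T) < horizon_years, df, 0.0)
    return np.sum(L * w * df, axis=-1)


def cost_per_case(total_cost, prevalent_cases):
    """Annual cost per prevalent case: elementwise division."""
    cost = np.asarray(total_cost, dtype=float)
    cases = np.asarray(prevalent_cases, dtype=float)
    if np.any((cases == 0) & (cost > 0)):
        raise ValueError("nonzero cost with zero prevalent cases")
    out = np.zeros_like(cost)
    np.divide(cost, cases, out=out, where=cases > 0)
    return out


def allocate_unattributable(attributable_by_disease: dict, unattributable_total):
    """Split unattributable direct costs across diseases in proportion to
    each disease's share of the attributable total; additions sum to the
    unattributable total exactly."""
    total_attr = sum(np.asarray(a, dtype=float) for a in attributable_by_disease.values())
    unattr = np.asarray(unattributable_total, dtype=float)
    if np.any((total_attr == 0) & (unattr > 0)):
        raise ValueError("unattributable cost with all-zero attributable costs")
    out = {}
    for d, a in attributable_by_disease.items():
        share = np.zeros_like(total_attr)
        np.divide(np.asarray(a, dtype=float), total_attr, out=share, where=total_attr > 0)
        out[d] = share * unattr
    return out


def inflate(cost, cpi_factor: float):
    """Inflate costs to the analysis currency year."""
    if cpi_factor <= 0:
        raise ValueError("CPI factor must be positive")
    return np.asarray(cost, dtype=float) * cpi_factor


def healthcare_savings(
    prevalent_baseline,
    prevalent_scenario,
    cost_per_case_by_year,
    rate: float,
    horizon_years: int | None = None,
):
    """Discounted cost savings: sum of factor * cost-per-case * prevalent-case
    difference over years.  Arrays have shape (..., T) aligned by year."""
    cb = np.asarray(prevalent_baseline, dtype=float)
    cs = np.asarray(prevalent_scenario, dtype=float)
    cpc = np.asarray(cost_per_case_by_year, dtype=float)
    if cb.shape != cs.shape:
        raise ValueError("baseline and scenario prevalent-case grids are misaligned")
    T = cb.shape[-1]
    df = discount_factor(np.arange(T), rate)
    if horizon_years is not None:
        df = np.where(np.arange(T) < horizon_years, df, 0.0)
    return np.sum(df * cpc * (cb - cs), axis=-1)
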