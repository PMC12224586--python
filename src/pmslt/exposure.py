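"""Sodium counterfactual scenarios, the sodium->SBP->relative-risk pathway,
and potential impact fractions (PIF) on disease incidence.

Scenarios act on mean usual sodium intake per Dietary Reference Intake (DRI)
age/sex group, in one of three forms: reduce to a target level (one-sided -
intakes already below the target are untouched), subtract an absolute
amount, or scale down by a fraction.  The health pathway is mediated by
systolic blood pressure (SBP): a linear dose-response of mmHg per 1,000
mg/day sodium (age/sex-specific slope), then a log-linear relative risk per
20 mmHg of SBP per disease (age-banded).  Because the risk model is
log-linear, only the SBP *shift* matters; baseline SBP levels cancel.

The default ten scenarios mirror the sodium-reduction strategies commonly
evaluated for Canada: meeting the Adequate Intake (1,500 mg/day) and WHO
(2,000 mg/day) recommendations, fully meeting packaged-food reformulation
targets, three front-of-package-labelling purchase-shift scenarios
(proportional reductions), and four consumer food-substitution scenarios
(absolute reductions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np

from .age_prep import expand_bands
from .grids import DISEASES, DRI_BANDS, DRI_LABELS, MAX_AGE, N_AGES, SEXES

#: Grams of salt per gram of sodium used for salt-equivalent reporting.
SALT_PER_SODIUM = 2.5


@dataclass(frozen=True)
class Scenario:
    """A sodium counterfactual.

    ``kind`` is one of ``target_level`` (params are mg/day ceilings),
    ``absolute_delta`` (mg/day subtracted) or ``proportional`` (fraction
    removed).  ``params`` maps DRI group label -> parameter; a scalar
    applies to every group.
    """

    id: str
    kind: str
    params: dict | float
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("target_level", "absolute_delta", "proportional"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        for g, p in self.param_by_group().items():
            if self.kind == "target_level" and p <= 0:
                raise ValueError(f"target must be positive (group {g})")
            if self.kind == "absolute_delta" and p < 0:
                raise ValueError(f"delta must be non-negative (group {g})")
            if self.kind == "proportional" and not 0 <= p <= 1:
                raise ValueError(f"fraction must be in [0,1] (group {g})")

    def param_by_group(self) -> dict[str, float]:
        if isinstance(self.params, dict):
            return {g: float(self.params[g]) for g in DRI_LABELS}
        return {g: float(self.params) for g in DRI_LABELS}


def default_scenarios() -> list[Scenario]:
    """The ten shipped sodium-reduction scenarios (S1-S10)."""
    return [
        Scenario("S1", "target_level", 1500.0, "Meeting AI sodium intake recommendations (1,500 mg/day)"),
        Scenario("S2", "target_level", 2000.0, "Meeting WHO sodium intake recommendations (2,000 mg/day)"),
        Scenario("S3", "absolute_delta", 459.0, "Sodium reduction targets for packaged foods (reformulation)"),
        Scenario("S4", "proportional", 0.047, "FOPL: changes in food & beverage purchases (Chilean experience)"),
        Scenario("S5", "proportional", 0.064, "FOPL: WHO cost-effectiveness criteria"),
        Scenario("S6", "proportional", 0.078, "FOPL: systematic review and network meta-analysis"),
        Scenario("S7", "absolute_delta", 73.0, "FOPL: food substitution, 30% of adults"),
        Scenario("S8", "absolute_delta", 131.0, "FOPL: food substitution, 50% of adults"),
        Scenario("S9", "absolute_delta", 182.0, "FOPL: food substitution, 70% of adults"),
        Scenario("S10", "absolute_delta", 259.0, "FOPL: food substitution, all adults"),
    ]


def null_scenario() -> Scenario:
    """The business-as-usual comparator: no sodium change anywhere."""
    return Scenario("S0", "absolute_delta", 0.0, "Baseline (no intervention)")


@dataclass
class EffectModel:
    """Sodium -> SBP -> disease risk dose-response parameters.

    ``sbp_slope`` holds (age_lo, age_hi, {sex: mmHg per 1,000 mg/day}) bands;
    ``rr20`` holds, per disease, (age_lo, age_hi, relative risk per 20 mmHg
    of SBP) bands.  Shipped defaults are illustrative configuration values
    in the range reported by blood-pressure meta-analyses, not authoritative
    estimates; real applications should supply their own.
    """

    sbp_slope: list = field(default_factory=lambda: [
        (0, 19, {"male": 0.0, "female": 0.0}),
        (20, 39, {"male": 1.2, "female": 1.1}),
        (40, 59, {"male": 2.0, "female": 1.9}),
        (60, 79, {"male": 2.7, "female": 2.6}),
        (80, MAX_AGE, {"male": 3.0, "female": 2.9}),
    ])
    rr20: dict = field(default_factory=lambda: {
        "ihd": [(0, 49, 2.0), (50, 59, 1.8), (60, 69, 1.6), (70, 79, 1.4), (80, MAX_AGE, 1.3)],
        "stroke": [(0, 49, 2.4), (50, 59, 2.1), (60, 69, 1.8), (70, 79, 1.5), (80, MAX_AGE, 1.35)],
    })
    salt_factor: float = SALT_PER_SODIUM

    def __post_init__(self):
        if self.salt_factor <= 0:
            raise ValueError("salt_factor must be positive")
        for d, bands in self.rr20.items():
            for lo, hi, rr in bands:
                if rr < 1:
                    raise ValueError(f"rr20 must be >= 1 (disease {d}, band {lo}-{hi})")
        for lo, hi, by_sex in self.sbp_slope:
            for sex, s in by_sex.items():
                if s < 0:
                    raise ValueError(f"sbp_slope must be >= 0 ({sex}, band {lo}-{hi})")

    def slope_by_age(self, sex: str) -> np.ndarray:
        return expand_bands([(lo, hi, by_sex[sex]) for lo, hi, by_sex in self.sbp_slope])

    def rr20_by_age(self, disease: str) -> np.ndarray:
        return expand_bands(self.rr20[disease])

    def perturbed(self, rr20_mult: dict | None = None, slope_mult: float = 1.0) -> "EffectModel":
        """Copy with rr20 scaled per disease (floored at 1) and slopes scaled."""
        rr20 = {
            d: [(lo, hi, max(1.0, rr * (rr20_mult or {}).get(d, 1.0))) for lo, hi, rr in bands]
            for d, bands in self.rr20.items()
        }
        slope = [
            (lo, hi, {s: v * slope_mult for s, v in by_sex.items()})
            for lo, hi, by_sex in self.sbp_slope
        ]
        return EffectModel(slope, rr20, self.salt_factor)


# --- scenario arithmetic -------------------------------------------------

def required_reduction(baseline_mean: float, recommendation: float) -> float:
    """Sodium reduction (mg/day) needed to bring the mean to a recommendation."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return max(0.0, baseline_mean - recommendation)


def sodium_to_salt(delta_sodium_mg_day: float, salt_factor: float = SALT_PER_SODIUM) -> float:
    """Salt equivalent (g/day) of a sodium change (mg/day), at 2 decimals.

    Rounding is decimal half-even on the exact decimal product (plain float
    rounding would mis-round exact halves like 1258 * 2.5 / 1000 = 3.145).
    """
    if delta_sodium_mg_day < 0:
        raise ValueError("delta must be non-negative")
    grams = Decimal(str(delta_sodium_mg_day)) * Decimal(str(salt_factor)) / Decimal(1000)
    return float(grams.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def percent_reduction(delta_mg_day: float, baseline_mg_day: float) -> float:
    """Relative reduction, as a percentage of the baseline mean."""
    if baseline_mg_day <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * delta_mg_day / baseline_mg_day


def apply_scenario(group_means: dict, scenario: Scenario) -> dict:
    """Counterfactual mean sodium intake per (sex, DRI group).

    ``group_means`` maps (sex, group_label) -> mg/day.  Interventions are
    one-sided: no group's intake is ever increased.
    """
    params = scenario.param_by_group()
    out = {}
    for (sex, group), mean in group_means.items():
        p = params[group]
        if scenario.kind == "target_level":
            out[(sex, group)] = min(mean, p)
        elif scenario.kind == "absolute_delta":
            out[(sex, group)] = max(0.0, mean - p)
        else:  # proportional
            out[(sex, group)] = mean * (1.0 - p)
    return out


def sodium_delta_by_age(group_means: dict, scenario: Scenario, sex: str) -> np.ndarray:
    """Per-1-year-age sodium reduction (mg/day) for one sex.

    Ages below 19 receive zero intervention (adult-only cohort); adult ages
    take the delta of their DRI group.
    """
    cf = apply_scenario(group_means, scenario)
    delta = np.zeros(N_AGES)
    for (lo, hi), label in zip(DRI_BANDS, DRI_LABELS):
        delta[lo : hi + 1] = group_means[(sex, label)] - cf[(sex, label)]
    return delta


# --- dose-response -------------------------------------------------------

def sbp_shift(delta_sodium_mg_day, slope_mmHg_per_g):
    """SBP change (mmHg, negative for reductions) for a sodium reduction.

    ``slope_mmHg_per_g`` is mmHg per 1,000 mg/day of sodium.
    """
    delta = np.asarray(delta_sodium_mg_day, dtype=float)
    if np.any(delta < 0):
        raise ValueError("sodium reduction must be non-negative")
    return -np.asarray(slope_mmHg_per_g, dtype=float) * delta / 1000.0


def rr_multiplier(delta_sbp_mmHg, rr20):
    """Incidence rate ratio for an SBP shift under log-linear risk: rr20^(dSBP/20)."""
    rr20 = np.asarray(rr20, dtype=float)
    if np.any(rr20 < 1):
        raise ValueError("rr20 must be >= 1")
    return rr20 ** (np.asarray(delta_sbp_mmHg, dtype=float) / 20.0)


def pif_mean_shift(delta_sbp_mmHg, rr20):
    """Potential impact fraction for a uniform mean SBP shift: 1 - rr20^(dSBP/20)."""
    return 1.0 - rr_multiplier(delta_sbp_mmHg, rr20)


def pif_distributional(support, weights, support_cf, rr20, slope_mmHg_per_g):
    """PIF over a discretised sodium intake distribution.

    ``support``/``support_cf`` are baseline and counterfactual intake support
    points (mg/day) with shared ``weights`` summing to 1; risk at an intake x
    is rr20^(slope * x / 1000 / 20) up to a constant that cancels in the
    ratio.  Reduces to the mean-shift PIF when the shift is uniform.
    """
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    def rr(x):
        return rr20 ** (slope_mmHg_per_g * np.asarray(x, dtype=float) / 1000.0 / 20.0)
    return 1.0 - float(np.sum(weights * rr(support_cf)) / np.sum(weights * rr(support)))


def pif_table(group_means: dict, scenario: Scenario, effect: EffectModel) -> dict:
    """PIF per disease -> (101, 2) array over age x sex.

    Mean-shift mode: each 1-year age inherits its DRI group's sodium delta,
    mapped through the age/sex SBP slope and the disease's age-banded rr20.
    """
    out = {}
    for disease in DISEASES:
        rr = effect.rr20_by_age(disease)
        pif = np.zeros((N_AGES, len(SEXES)))
        for k, sex in enumerate(SEXES):
            delta = sodium_delta_by_age(group_means, scenario, sex)
            dsbp = sbp_shift(delta, effect.slope_by_age(sex))
            pif[:, k] = pif_mean_shift(dsbp, rr)
        out[disease] = pif
    return out
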