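"""Seeded generator of all model inputs.

Emulates the statistical structure of the national data sources a sodium
policy model would normally ingest - a 1-year population pyramid with
all-cause mortality, per-disease incidence/prevalence/cause-specific
mortality at 5-year source granularity (20 to 90+), usual sodium intake by
DRI age/sex group with a configurable population-weighted mean (2,758
mg/day by default), survey blood-pressure bands with the 80+ carry-forward,
burden-of-illness cost bands, and utility weights - so the whole pipeline
runs end to end with no download.

Two deliberate choices make the generator a test harness, not just a data
faker:

* all-cause mortality follows a Gompertz-Makeham hazard
  m(a) = min(1, alpha + beta * exp(gamma * a)), smooth and controllable by
  two parameters;
* disease prevalence and cause-specific mortality are produced by
  *forward-running* the three-state recursion of
  :mod:`pmslt.disease_model` from known ("true") incidence and case
  fatality, so the case-fatality back-calculation can be validated by
  parameter recovery against ground truth.

Identical seeds and configurations produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .age_prep import GroupedSeries, aggregate_to_groups
from .disease_model import rate_to_prob
from .grids import (
    AGES,
    AgeSexGrid,
    COST_BANDS,
    DISEASES,
    DRI_BANDS,
    DRI_LABELS,
    MAX_AGE,
    N_AGES,
    SBP_BANDS,
    SEXES,
    SEX_INDEX,
    UTILITY_BANDS,
)

#: 5-year groups used for source-granularity vital statistics (0 to 90+).
VITAL_GROUPS = tuple((lo, lo + 4) for lo in range(0, 90, 5)) + ((90, MAX_AGE),)
#: 5-year groups used for source-granularity disease epidemiology (20 to 90+).
EPI_GROUPS = tuple((lo, lo + 4) for lo in range(20, 90, 5)) + ((90, MAX_AGE),)

DEFAULT_TOTAL_POPULATION = 37_600_000
DEFAULT_SEX_RATIO = 0.497  # male share
DEFAULT_TARGET_SODIUM = 2758.0  # mg/day, population-weighted adult mean

#: Gompertz-Makeham all-cause mortality parameters (alpha, beta, gamma).
DEFAULT_GOMPERTZ = {"male": (3.0e-4, 4.5e-5, 0.088), "female": (2.5e-4, 3.0e-5, 0.088)}

#: Relative sodium intake profile by DRI group, rescaled to hit the target
#: population-weighted mean.  Every group stays above 2,000 mg/day so the
#: target-level recommendation scenarios bite in all groups.
DEFAULT_SODIUM_PROFILE = {
    ("male", "19-30"): 3400.0,
    ("male", "31-50"): 3500.0,
    ("male", "51-70"): 3200.0,
    ("male", "71+"): 2900.0,
    ("female", "19-30"): 2500.0,
    ("female", "31-50"): 2400.0,
    ("female", "51-70"): 2300.0,
    ("female", "71+"): 2100.0,
}

DEFAULT_SBP_BANDS = {
    "male": [(6, 11, 102.0), (12, 19, 110.0), (20, 39, 117.0), (40, 59, 124.0), (60, 79, 133.0)],
    "female": [(6, 11, 101.0), (12, 19, 107.0), (20, 39, 111.0), (40, 59, 120.0), (60, 79, 131.0)],
}

#: Average annual direct cost per prevalent case, 2010 CAD, before the
#: unattributable add-on and inflation.
DEFAULT_COST_PER_CASE = {"ihd": 4500.0, "stroke": 7500.0}
DEFAULT_UNATTRIBUTABLE_FRAC = 0.30
DEFAULT_CPI_FACTOR = 1.17  # healthcare CPI, 2010 -> 2019

DEFAULT_BACKGROUND_UTILITY = (0.95, 0.94, 0.93, 0.91, 0.89, 0.87, 0.84, 0.80, 0.75, 0.68)
DEFAULT_UTILITY_DECREMENT = {"ihd": 0.08, "stroke": 0.15}


# --- domain types --------------------------------------------------------

@dataclass
class PopulationInputs:
    population: AgeSexGrid  # counts per 1y age x sex
    all_cause_mortality: AgeSexGrid  # rate/year per 1y age x sex
    deaths_5y: dict = field(default_factory=dict)  # sex -> GroupedSeries of death counts


@dataclass
class TrueEpiParams:
    """Ground-truth disease parameters driving the forward simulation."""

    incidence: AgeSexGrid  # rate/year
    case_fatality: AgeSexGrid  # rate/year
    remission: float = 0.0

    def __post_init__(self):
        if self.remission != 0.0:
            raise ValueError("three-state model has no recovery; remission must be 0")
        if np.any(self.incidence.values < 0) or np.any(self.case_fatality.values < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class DiseaseEpiData:
    """Observed-style epidemiology for one disease, 1-year and grouped."""

    incidence: AgeSexGrid
    prevalence: AgeSexGrid
    cause_mortality: AgeSexGrid
    grouped: dict = field(default_factory=dict)  # (quantity, sex) -> GroupedSeries


@dataclass
class SodiumIntakeInputs:
    mean: dict  # (sex, dri_label) -> mg/day
    se: dict  # (sex, dri_label) -> mg/day
    weights: dict  # (sex, dri_label) -> population share among adults
    population_weighted_mean: float


@dataclass
class SBPInputs:
    bands: dict  # sex -> list of (lo, hi, mean mmHg), covering 6..100

    def __post_init__(self):
        for sex, bands in self.bands.items():
            last = {(lo, hi): v for lo, hi, v in bands}
            if (60, 79) in last and (80, MAX_AGE) in last:
                if last[(80, MAX_AGE)] != last[(60, 79)]:
                    raise ValueError(f"80+ SBP must equal the 60-79 value ({sex})")
            for _, _, v in bands:
                if v <= 0:
                    raise ValueError("SBP must be positive")


@dataclass
class CostUtilityInputs:
    attributable: dict  # disease -> array (n_cost_bands, n_sexes), CAD/year totals
    unattributable_total: np.ndarray  # (n_cost_bands, n_sexes), CAD/year
    background_utility: np.ndarray  # per 10-year utility band, in [0, 1]
    disease_utility_decrement: dict  # disease -> decrement in [0, 1]

    def __post_init__(self):
        for d, arr in self.attributable.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"negative attributable cost for {d}")
        if np.any(self.unattributable_total < 0):
            raise ValueError("negative unattributable cost")
        u = np.asarray(self.background_utility)
        if np.any((u < 0) | (u > 1)):
            raise ValueError("background utility outside [0, 1]")
        for d, dec in self.disease_utility_decrement.items():
            if not 0 <= dec <= 1:
                raise ValueError(f"utility decrement outside [0, 1] for {d}")


@dataclass
class SyntheticInputs:
    """Bundle of every model input at both native and source granularity."""

    seed: int
    population: PopulationInputs
    epi: dict  # disease -> DiseaseEpiData
    epi_params: dict  # disease -> TrueEpiParams (ground truth)
    sodium: SodiumIntakeInputs
    sbp: SBPInputs
    costs: CostUtilityInputs
    config: dict = field(default_factory=dict)


# --- generators ----------------------------------------------------------

def gompertz_makeham(ages, alpha: float, beta: float, gamma: float) -> np.ndarray:
    if alpha < 0 or beta < 0 or gamma <= 0:
        raise ValueError("require alpha >= 0, beta >= 0, gamma > 0")
    return np.minimum(1.0, alpha + beta * np.exp(gamma * np.asarray(ages, dtype=float)))


def generate_population(
    seed: int,
    total_size: float = DEFAULT_TOTAL_POPULATION,
    sex_ratio: float = DEFAULT_SEX_RATIO,
    gompertz_params: dict | None = None,
    pyramid_noise_sd: float = 0.02,
) -> PopulationInputs:
    """Population pyramid plus Gompertz-Makeham all-cause mortality.

    The pyramid is the stationary-population shape implied by the mortality
    schedule, perturbed by seeded log-normal noise, renormalised so counts
    sum to ``total_size`` exactly.  Deaths are also emitted as 5-year grouped
    counts (0 to 90+) to exercise the preprocessing stage.
    """
    if total_size <= 0:
        raise ValueError("total_size must be positive")
    gompertz_params = gompertz_params or DEFAULT_GOMPERTZ
    rng = np.random.default_rng(seed)

    mort = AgeSexGrid()
    pop = AgeSexGrid()
    for sex in SEXES:
        a, b, g = gompertz_params[sex]
        m = gompertz_makeham(AGES, a, b, g)
        mort.values[:, SEX_INDEX[sex]] = m
        # Stationary shape: survivorship to each age under this schedule.
        surv = np.concatenate([[1.0], np.cumprod(1.0 - rate_to_prob(m[:-1]))])
        noise = np.exp(rng.normal(0.0, pyramid_noise_sd, N_AGES))
        share = sex_ratio if sex == "male" else 1.0 - sex_ratio
        pop.values[:, SEX_INDEX[sex]] = share * surv * noise

    pop.values *= total_size / pop.values.sum()
    pop.values[0, 0] += total_size - pop.values.sum()  # conservation to the last ulp

    deaths_5y = {}
    for sex in SEXES:
        deaths = mort.sex(sex) * pop.sex(sex)
        deaths_5y[sex] = GroupedSeries(aggregate_to_groups(deaths, VITAL_GROUPS), "count")
    return PopulationInputs(pop, mort, deaths_5y)


def _ramped_exponential(age, zero_below, ramp_to, level, growth, cap):
    """0 below ``zero_below``, linear ramp to ``level`` at ``ramp_to``, then
    exponential growth, capped."""
    age = np.asarray(age, dtype=float)
    out = np.where(
        age < zero_below,
        0.0,
        np.where(
            age < ramp_to,
            level * (age - zero_below) / max(ramp_to - zero_below, 1),
            level * np.exp(growth * (age - ramp_to)),
        ),
    )
    return np.minimum(out, cap)


def default_epi_params(disease: str) -> TrueEpiParams:
    """Illustrative cardiovascular age patterns: incidence zero below 20,
    log-linear above 35; case fatality constant below 35, rising with age."""
    if disease == "ihd":
        inc = {"male": (6.0e-4, 0.060), "female": (3.6e-4, 0.062)}
        cf = (0.030, 0.020)
    elif disease == "stroke":
        inc = {"male": (3.0e-4, 0.065), "female": (2.4e-4, 0.066)}
        cf = (0.050, 0.025)
    else:
        raise ValueError(f"unknown disease {disease!r}")
    incidence = AgeSexGrid.from_columns(
        **{s: _ramped_exponential(AGES, 20, 35, lvl, k, 0.05) for s, (lvl, k) in inc.items()}
    )
    f_level, f_growth = cf
    f = np.where(AGES < 35, f_level, f_level * np.exp(f_growth * (AGES - 35)))
    case_fatality = AgeSexGrid.from_columns(male=f, female=f)
    return TrueEpiParams(incidence, case_fatality)


def generate_disease_epi(
    seed: int,
    params: TrueEpiParams,
    population: PopulationInputs,
    emit_grouped: bool = True,
) -> DiseaseEpiData:
    """Forward-run the three-state process to produce observed-style epidemiology.

    Prevalence and cause-specific mortality are exactly the quantities the
    recursion of :mod:`pmslt.disease_model` implies for the true incidence
    and case fatality, so the case-fatality solver has a recoverable ground
    truth.  Grouped (5-year, 20 to 90+) versions mimic source granularity.
    """
    prevalence = AgeSexGrid()
    cause_mortality = AgeSexGrid()
    for sex in SEXES:
        i = params.incidence.sex(sex)
        f = params.case_fatality.sex(sex)
        q_i, q_f = rate_to_prob(i), rate_to_prob(f)
        S, C = np.zeros(N_AGES), np.zeros(N_AGES)
        S[0] = 1.0
        prev = np.zeros(N_AGES)
        mort = np.zeros(N_AGES)
        for a in range(N_AGES):
            alive = S[a] + C[a]
            prev[a] = C[a] / alive if alive > 0 else 0.0
            die = C[a] * q_f[a]
            mort[a] = die / alive if alive > 0 else 0.0
            if a < MAX_AGE:
                new = S[a] * q_i[a]
                S[a + 1] = S[a] - new
                C[a + 1] = C[a] + new - die
        k = SEX_INDEX[sex]
        prevalence.values[:, k] = prev
        cause_mortality.values[:, k] = mort

    if np.any(prevalence.values > 1) or np.any(cause_mortality.values > 1):
        raise ValueError("generated rates left [0, 1] after discretisation")

    grouped = {}
    if emit_grouped:
        for sex in SEXES:
            w = population.population.sex(sex)
            for name, grid in (
                ("incidence", params.incidence),
                ("prevalence", prevalence),
                ("cause_mortality", cause_mortality),
            ):
                grouped[(name, sex)] = GroupedSeries(
                    aggregate_to_groups(grid.sex(sex), EPI_GROUPS, weights=w), "rate"
                )
    return DiseaseEpiData(params.incidence.copy(), prevalence, cause_mortality, grouped)


def adult_dri_weights(population: PopulationInputs) -> dict:
    """Share of the adult (19+) population in each DRI age/sex group."""
    pop = population.population
    total = sum(pop.sex(sex)[19:].sum() for sex in SEXES)
    weights = {}
    for sex in SEXES:
        for (lo, hi), label in zip(DRI_BANDS, DRI_LABELS):
            weights[(sex, label)] = pop.sex(sex)[lo : hi + 1].sum() / total
    return weights


def generate_sodium_intakes(
    seed: int,
    group_means: dict | None = None,
    group_weights: dict | None = None,
    target_mean: float | None = DEFAULT_TARGET_SODIUM,
    se_frac: float = 0.02,
) -> SodiumIntakeInputs:
    """Usual sodium intake means and SEs per DRI age/sex group.

    ``group_weights`` must sum to 1 (to 1e-9).  When ``target_mean`` is
    given, the relative profile in ``group_means`` is rescaled so the
    population-weighted mean equals the target; standard errors are a fixed
    fraction of each mean (the SE structure of usual-intake estimation is
    survey-specific, so it is free configuration here).
    """
    group_means = dict(group_means or DEFAULT_SODIUM_PROFILE)
    if group_weights is None:
        raise ValueError("group_weights are required (use adult_dri_weights)")
    wsum = sum(group_weights.values())
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"group weights must sum to 1, got {wsum}")
    if any(m <= 0 for m in group_means.values()):
        raise ValueError("group means must be positive")

    weighted = sum(group_weights[k] * group_means[k] for k in group_means)
    if target_mean is not None:
        factor = target_mean / weighted
        group_means = {k: m * factor for k, m in group_means.items()}
        weighted = sum(group_weights[k] * group_means[k] for k in group_means)
    se = {k: se_frac * m for k, m in group_means.items()}
    return SodiumIntakeInputs(group_means, se, dict(group_weights), weighted)


def generate_sbp(seed: int, band_means: dict | None = None) -> SBPInputs:
    """Mean SBP per survey band and sex, with the 80+ band filled by carrying
    the 60-79 value forward."""
    band_means = band_means or DEFAULT_SBP_BANDS
    out = {}
    for sex in SEXES:
        bands = sorted(band_means[sex])
        covered = {(lo, hi) for lo, hi, _ in bands}
        for lo, hi in SBP_BANDS[:-1]:
            if (lo, hi) not in covered:
                raise ValueError(f"missing SBP band {lo}-{hi} for {sex}")
        value_60_79 = [v for lo, hi, v in bands if (lo, hi) == (60, 79)][0]
        out[sex] = bands + [(80, MAX_AGE, value_60_79)]
    return SBPInputs(out)


def generate_costs_utilities(seed: int, config: dict) -> CostUtilityInputs:
    """Attributable cost totals per cost band x sex x disease, an
    unattributable total per band, and utility weights.

    ``config`` must contain ``prevalent_by_band`` (disease -> array of
    prevalent cases per (band, sex)); attributable totals are per-case cost
    scales times prevalent cases, with mild seeded log-normal jitter across
    bands so bands are not exact multiples of one another.
    """
    rng = np.random.default_rng(seed)
    prevalent = config["prevalent_by_band"]
    per_case = config.get("per_case_cost", DEFAULT_COST_PER_CASE)
    unattr_frac = config.get("unattributable_frac", DEFAULT_UNATTRIBUTABLE_FRAC)
    jitter_sd = config.get("cost_jitter_sd", 0.05)

    attributable = {}
    for disease in DISEASES:
        jitter = np.exp(rng.normal(0.0, jitter_sd, prevalent[disease].shape))
        attributable[disease] = per_case[disease] * prevalent[disease] * jitter
    unattributable = unattr_frac * sum(attributable.values())

    return CostUtilityInputs(
        attributable,
        unattributable,
        np.asarray(config.get("background_utility", DEFAULT_BACKGROUND_UTILITY), dtype=float),
        dict(config.get("utility_decrement", DEFAULT_UTILITY_DECREMENT)),
    )


def prevalent_cases_by_band(epi: DiseaseEpiData, population: PopulationInputs) -> np.ndarray:
    """Prevalent case counts aggregated to the cost bands, per (band, sex)."""
    out = np.zeros((len(COST_BANDS), len(SEXES)))
    for k, sex in enumerate(SEXES):
        cases = epi.prevalence.sex(sex) * population.population.sex(sex)
        for b, (lo, hi) in enumerate(COST_BANDS):
            out[b, k] = cases[lo : hi + 1].sum()
    return out


def generate_inputs(
    seed: int,
    total_size: float = DEFAULT_TOTAL_POPULATION,
    sex_ratio: float = DEFAULT_SEX_RATIO,
    target_sodium: float = DEFAULT_TARGET_SODIUM,
    cpi_factor: float = DEFAULT_CPI_FACTOR,
    cost_config: dict | None = None,
) -> SyntheticInputs:
    """Generate the complete, mutually consistent input bundle."""
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(4)
    population = generate_population(int(sub[0]), total_size, sex_ratio)

    epi_params = {d: default_epi_params(d) for d in DISEASES}
    epi = {
        d: generate_disease_epi(int(sub[1]) + k, epi_params[d], population)
        for k, d in enumerate(DISEASES)
    }

    sodium = generate_sodium_intakes(
        int(sub[2]), group_weights=adult_dri_weights(population), target_mean=target_sodium
    )
    sbp = generate_sbp(int(sub[2]))

    cfg = dict(cost_config or {})
    cfg.setdefault("prevalent_by_band", {d: prevalent_cases_by_band(epi[d], population) for d in DISEASES})
    costs = generate_costs_utilities(int(sub[3]) % (2**31), cfg)

    config = {
        "seed": seed,
        "total_size": total_size,
        "sex_ratio": sex_ratio,
        "target_sodium": target_sodium,
        "cpi_factor": cpi_factor,
    }
    return SyntheticInputs(seed, population, epi, epi_params, sodium, sbp, costs, config)


# --- CSV round trip ------------------------------------------------------

def write_inputs(inputs: SyntheticInputs, outdir: str | Path) -> None:
    """Write every input table as CSV plus a config JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs.population.population.to_frame("count").to_csv(outdir / "population.csv", index=False)
    inputs.population.all_cause_mortality.to_frame("rate").to_csv(outdir / "mortality_1y.csv", index=False)
    rows = [
        {"sex": sex, "age_lo": lo, "age_hi": hi, "count": v}
        for sex, gs in inputs.population.deaths_5y.items()
        for lo, hi, v in gs.groups
    ]
    pd.DataFrame(rows).to_csv(outdir / "deaths_5y.csv", index=False)

    epi_rows, epi1_rows = [], []
    for disease, data in inputs.epi.items():
        for (name, sex), gs in data.grouped.items():
            epi_rows += [
                {"disease": disease, "quantity": name, "sex": sex, "age_lo": lo, "age_hi": hi, "value": v}
                for lo, hi, v in gs.groups
            ]
        for name, grid in (
            ("incidence", data.incidence),
            ("prevalence", data.prevalence),
            ("cause_mortality", data.cause_mortality),
            ("case_fatality_true", inputs.epi_params[disease].case_fatality),
        ):
            frame = grid.to_frame("value")
            frame.insert(0, "disease", disease)
            frame.insert(1, "quantity", name)
            epi1_rows.append(frame)
    pd.DataFrame(epi_rows).to_csv(outdir / "epi_5y.csv", index=False)
    pd.concat(epi1_rows, ignore_index=True).to_csv(outdir / "epi_1y.csv", index=False)

    pd.DataFrame(
        [
            {
                "sex": sex,
                "dri_group": label,
                "mean_mg_day": inputs.sodium.mean[(sex, label)],
                "se_mg_day": inputs.sodium.se[(sex, label)],
                "weight": inputs.sodium.weights[(sex, label)],
            }
            for sex in SEXES
            for label in DRI_LABELS
        ]
    ).to_csv(outdir / "sodium.csv", index=False)

    pd.DataFrame(
        [
            {"sex": sex, "age_lo": lo, "age_hi": hi, "mean_sbp": v}
            for sex, bands in inputs.sbp.bands.items()
            for lo, hi, v in bands
        ]
    ).to_csv(outdir / "sbp.csv", index=False)

    cost_rows = []
    for b, (lo, hi) in enumerate(COST_BANDS):
        for sex in SEXES:
            k = SEX_INDEX[sex]
            row = {"age_lo": lo, "age_hi": hi, "sex": sex}
            for disease in DISEASES:
                row[f"attributable_{disease}"] = inputs.costs.attributable[disease][b, k]
            row["unattributable_total"] = inputs.costs.unattributable_total[b, k]
            cost_rows.append(row)
    pd.DataFrame(cost_rows).to_csv(outdir / "costs.csv", index=False)

    pd.DataFrame(
        [
            {"age_lo": lo, "age_hi": hi, "background_utility": u}
            for (lo, hi), u in zip(UTILITY_BANDS, inputs.costs.background_utility)
        ]
    ).to_csv(outdir / "utilities.csv", index=False)

    config = dict(inputs.config)
    config["utility_decrement"] = inputs.costs.disease_utility_decrement
    with open(outdir / "config.json", "w") as fh:
        json.dump(config, fh, indent=2)


def read_inputs(indir: str | Path) -> SyntheticInputs:
    """Reconstruct a :class:`SyntheticInputs` bundle from its CSV layout."""
    indir = Path(indir)
    with open(indir / "config.json") as fh:
        config = json.load(fh)

    pop = AgeSexGrid.from_frame(pd.read_csv(indir / "population.csv"), "count")
    mort = AgeSexGrid.from_frame(pd.read_csv(indir / "mortality_1y.csv"), "rate")
    d5 = pd.read_csv(indir / "deaths_5y.csv")
    deaths_5y = {
        sex: GroupedSeries(
            [
                (int(r.age_lo), int(r.age_hi), float(r["count"]))
                for _, r in d5[d5.sex == sex].sort_values("age_lo").iterrows()
            ],
            "count",
        )
        for sex in SEXES
    }
    population = PopulationInputs(pop, mort, deaths_5y)

    e5 = pd.read_csv(indir / "epi_5y.csv")
    e1 = pd.read_csv(indir / "epi_1y.csv")
    epi, epi_params = {}, {}
    for disease in DISEASES:
        grids = {}
        for name in ("incidence", "prevalence", "cause_mortality", "case_fatality_true"):
            sub = e1[(e1.disease == disease) & (e1.quantity == name)]
            grids[name] = AgeSexGrid.from_frame(sub, "value")
        grouped = {}
        for name in ("incidence", "prevalence", "cause_mortality"):
            for sex in SEXES:
                sub = e5[(e5.disease == disease) & (e5.quantity == name) & (e5.sex == sex)]
                grouped[(name, sex)] = GroupedSeries(
                    [(int(r.age_lo), int(r.age_hi), float(r.value)) for _, r in sub.sort_values("age_lo").iterrows()],
                    "rate",
                )
        epi[disease] = DiseaseEpiData(grids["incidence"], grids["prevalence"], grids["cause_mortality"], grouped)
        epi_params[disease] = TrueEpiParams(grids["incidence"].copy(), grids["case_fatality_true"])

    na = pd.read_csv(indir / "sodium.csv")
    sodium = SodiumIntakeInputs(
        {(r.sex, r.dri_group): r.mean_mg_day for _, r in na.iterrows()},
        {(r.sex, r.dri_group): r.se_mg_day for _, r in na.iterrows()},
        {(r.sex, r.dri_group): r.weight for _, r in na.iterrows()},
        float(sum(r.weight * r.mean_mg_day for _, r in na.iterrows())),
    )

    sb = pd.read_csv(indir / "sbp.csv")
    sbp = SBPInputs(
        {
            sex: [
                (int(r.age_lo), int(r.age_hi), float(r.mean_sbp))
                for _, r in sb[sb.sex == sex].sort_values("age_lo").iterrows()
            ]
            for sex in SEXES
        }
    )

    co = pd.read_csv(indir / "costs.csv")
    attributable = {d: np.zeros((len(COST_BANDS), len(SEXES))) for d in DISEASES}
    unattributable = np.zeros((len(COST_BANDS), len(SEXES)))
    for _, r in co.iterrows():
        b = [lo for lo, hi in COST_BANDS].index(int(r.age_lo))
        k = SEX_INDEX[r.sex]
        for disease in DISEASES:
            attributable[disease][b, k] = r[f"attributable_{disease}"]
        unattributable[b, k] = r.unattributable_total

    ut = pd.read_csv(indir / "utilities.csv").sort_values("age_lo")
    costs = CostUtilityInputs(
        attributable,
        unattributable,
        ut.background_utility.to_numpy(dtype=float),
        {d: float(v) for d, v in config.pop("utility_decrement").items()},
    )
    return SyntheticInputs(int(config["seed"]), population, epi, epi_params, sodium, sbp, costs, config)
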