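"""Pipeline orchestration: preprocessing, scenario runs, Monte Carlo, sensitivity.

The full pipeline is preprocessing (age disaggregation, tail extrapolation,
band expansion, cost construction) -> case-fatality back-calculation ->
exposure (scenario -> PIF) -> per-disease cohort simulation -> lifetable and
economic accounting.  A deterministic scenario run returns prevented
incident cases, QALY gains and discounted cost savings by disease and sex;
Monte Carlo reruns the pipeline with perturbed parameters to produce
empirical 95% uncertainty intervals.

The modelled population is a closed adult cohort: everyone aged 19+ at
baseline, simulated until age 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .age_prep import expand_bands, group_rates_to_1y
from .case_fatality import solve_case_fatality
from .disease_model import prevented_incident_cases, run_cohorts
from .exposure import EffectModel, Scenario, pif_table
from .grids import AgeSexGrid, COST_BANDS, DISEASES, MAX_AGE, SEXES, SEX_INDEX, UTILITY_BANDS
from .lifetable_econ import (
    EconSettings,
    adjusted_mortality,
    allocate_unattributable,
    build_lifetable,
    cost_per_case,
    healthcare_savings,
    inflate,
    qalys,
)
from .synthetic import SyntheticInputs, prevalent_cases_by_band

START_AGE = 19

OUTCOMES = ("prevented_cases", "qalys", "savings_cad")


@dataclass
class ModelInputs:
    """All inputs on the 1-year grid, ready for simulation."""

    population: AgeSexGrid  # counts
    mortality: AgeSexGrid  # all-cause rate/year
    incidence: dict  # disease -> AgeSexGrid
    prevalence: dict  # disease -> AgeSexGrid
    case_fatality: dict  # disease -> AgeSexGrid
    sodium: object  # SodiumIntakeInputs
    sbp: AgeSexGrid  # mean SBP per age (carried input; cancels in log-linear RR)
    cost_per_case_1y: dict  # disease -> AgeSexGrid, analysis-year CAD per case-year
    background_utility: np.ndarray  # per 1-year age
    utility_decrement: dict  # disease -> decrement
    effect: EffectModel = field(default_factory=EffectModel)


def prepare_inputs(
    inputs: SyntheticInputs,
    effect: EffectModel | None = None,
    poly_order: int = 2,
    refine_case_fatality: bool = False,
) -> ModelInputs:
    """Run the preprocessing stage on a source-granularity input bundle.

    Grouped death counts are disaggregated to 1-year mortality rates;
    grouped disease rates are disaggregated (conserving group event counts)
    and extrapolated to age 100; case fatality is back-calculated per
    disease and sex; banded SBP, cost and utility inputs are expanded to the
    1-year grid, with costs converted to inflation-adjusted cost per
    prevalent case per year.

    Case fatality defaults to the direct deaths-over-prevalent-cases
    estimator: it is local in age and therefore robust to the small wiggles
    the group-to-1-year interpolation leaves in prevalence.  The exact
    consistency refinement (``refine_case_fatality=True``) reproduces the
    generating rates to machine precision on consistent 1-year data, but on
    interpolated data it fits year-over-year prevalence differences and so
    amplifies interpolation noise.
    """
    pop = inputs.population.population

    from .age_prep import disaggregate_counts  # local import to keep top tidy

    mortality = AgeSexGrid()
    for sex in SEXES:
        deaths_1y = disaggregate_counts(inputs.population.deaths_5y[sex])
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(pop.sex(sex) > 0, deaths_1y / np.where(pop.sex(sex) > 0, pop.sex(sex), 1.0), 0.0)
        mortality.values[:, SEX_INDEX[sex]] = np.clip(m, 0.0, 1.0)

    incidence, prevalence, cause_mortality = {}, {}, {}
    for d in DISEASES:
        incidence[d], prevalence[d], cause_mortality[d] = AgeSexGrid(), AgeSexGrid(), AgeSexGrid()
        for sex in SEXES:
            k = SEX_INDEX[sex]
            g = inputs.epi[d].grouped
            incidence[d].values[:, k] = group_rates_to_1y(g[("incidence", sex)], pop.sex(sex), poly_order=poly_order)
            prevalence[d].values[:, k] = group_rates_to_1y(g[("prevalence", sex)], pop.sex(sex), poly_order=poly_order)
            cause_mortality[d].values[:, k] = group_rates_to_1y(
                g[("cause_mortality", sex)], pop.sex(sex), poly_order=poly_order
            )

    case_fatality = {}
    for d in DISEASES:
        case_fatality[d] = AgeSexGrid()
        for sex in SEXES:
            sol = solve_case_fatality(
                incidence[d].sex(sex),
                prevalence[d].sex(sex),
                cause_mortality[d].sex(sex),
                pop.sex(sex),
                refine=refine_case_fatality,
            )
            case_fatality[d].values[:, SEX_INDEX[sex]] = sol.case_fatality

    sbp = AgeSexGrid()
    for sex in SEXES:
        bands = list(inputs.sbp.bands[sex])
        lo0, hi0, v0 = min(bands)
        if lo0 > 0:
            bands = [(0, lo0 - 1, v0)] + bands  # children below the first survey band
        sbp.values[:, SEX_INDEX[sex]] = expand_bands(bands)

    additions = allocate_unattributable(inputs.costs.attributable, inputs.costs.unattributable_total)
    prevalent_by_band = {d: prevalent_cases_by_band(inputs.epi[d], inputs.population) for d in DISEASES}
    cpi = inputs.config.get("cpi_factor", 1.0)
    cpc_1y = {}
    for d in DISEASES:
        total = inputs.costs.attributable[d] + additions[d]
        cases = prevalent_by_band[d]
        # Bands with no prevalent cases carry no disease cost.
        total = np.where(cases > 0, total, 0.0)
        cpc_band = inflate(cost_per_case(total, cases), cpi)
        cpc_1y[d] = AgeSexGrid()
        for sex in SEXES:
            k = SEX_INDEX[sex]
            cpc_1y[d].values[:, k] = expand_bands(
                [(lo, hi, cpc_band[b, k]) for b, (lo, hi) in enumerate(COST_BANDS)]
            )

    bg_1y = expand_bands(
        [(lo, hi, u) for (lo, hi), u in zip(UTILITY_BANDS, inputs.costs.background_utility)]
    )

    return ModelInputs(
        population=pop,
        mortality=mortality,
        incidence=incidence,
        prevalence=prevalence,
        case_fatality=case_fatality,
        sodium=inputs.sodium,
        sbp=sbp,
        cost_per_case_1y=cpc_1y,
        background_utility=bg_1y,
        utility_decrement=inputs.costs.disease_utility_decrement,
        effect=effect or EffectModel(),
    )


def _aggregate(values: dict) -> pd.Series:
    """Add disease and sex totals and return a (outcome, disease, sex) Series."""
    out = dict(values)
    for outcome in OUTCOMES:
        diseases = sorted({d for (o, d, s) in values if o == outcome and d != "all"})
        sexes = sorted({s for (o, d, s) in values if o == outcome and s != "all"})
        if diseases:  # outcomes without a disease split already carry 'all'
            for s in sexes:
                out[(outcome, "all", s)] = sum(values[(outcome, d, s)] for d in diseases)
        for d in diseases + ["all"]:
            out[(outcome, d, "all")] = sum(out[(outcome, d, s)] for s in sexes)
    idx = pd.MultiIndex.from_tuples(sorted(out), names=["outcome", "disease", "sex"])
    return pd.Series([out[k] for k in idx], index=idx)


def run_scenario(
    mi: ModelInputs,
    scenario: Scenario,
    settings: EconSettings | None = None,
    effect: EffectModel | None = None,
    intake_means: dict | None = None,
    cf_scale: dict | None = None,
    cost_scale: dict | None = None,
) -> pd.Series:
    """Deterministic scenario-vs-baseline outcomes by disease and sex.

    Returns a Series indexed by (outcome, disease, sex) with outcomes
    ``prevented_cases`` (undiscounted incident-case differences from the
    closed disease sub-models), ``qalys`` (discounted QALY gains; disease
    dimension is 'all' since mortality and morbidity combine in the
    lifetable) and ``savings_cad`` (discounted healthcare cost savings per
    disease).  The keyword overrides exist for Monte Carlo perturbation.
    """
    settings = settings or EconSettings()
    effect = effect or mi.effect
    group_means = intake_means if intake_means is not None else mi.sodium.mean
    cf_scale = cf_scale or {}
    cost_scale = cost_scale or {}

    pifs = pif_table(group_means, scenario, effect)
    start_ages = np.arange(START_AGE, MAX_AGE)
    horizon = settings.horizon_years
    rate = settings.discount_rate

    values = {}
    for sex in SEXES:
        ks = SEX_INDEX[sex]
        pop_w = mi.population.sex(sex)[start_ages]

        traj_b, traj_s = {}, {}
        for d in DISEASES:
            f = mi.case_fatality[d].sex(sex) * cf_scale.get(d, 1.0)
            i = mi.incidence[d].sex(sex)
            p0 = mi.prevalence[d].sex(sex)
            traj_b[d] = run_cohorts(i, f, p0, start_ages)
            traj_s[d] = run_cohorts(i, f, p0, start_ages, pif=pifs[d][:, ks])

        any_traj = traj_b[DISEASES[0]]
        T = any_traj.n_years
        active = any_traj.active
        ages_mat = np.clip(start_ages[:, None] + np.arange(T)[None, :], 0, MAX_AGE)

        m_mat = mi.mortality.sex(sex)[ages_mat] * active
        mx_b = {d: traj_b[d].mortality_rate() for d in DISEASES}
        mx_s = {d: traj_s[d].mortality_rate() for d in DISEASES}
        m_scen = adjusted_mortality(m_mat, mx_b, mx_s) * active

        l_b, L_b = build_lifetable(m_mat)
        l_s, L_s = build_lifetable(m_scen)
        L_b = L_b * active
        L_s = L_s * active

        bg = mi.background_utility[ages_mat]
        prev_b = {d: traj_b[d].prevalence() for d in DISEASES}
        prev_s = {d: traj_s[d].prevalence() for d in DISEASES}

        q_b = qalys(L_b, bg, prev_b, mi.utility_decrement, rate, horizon)
        q_s = qalys(L_s, bg, prev_s, mi.utility_decrement, rate, horizon)
        values[("qalys", "all", sex)] = float(np.dot(pop_w, q_s - q_b))

        for d in DISEASES:
            values[("prevented_cases", d, sex)] = prevented_incident_cases(
                traj_b[d], traj_s[d], pop_w, horizon
            )
            cpc_mat = mi.cost_per_case_1y[d].sex(sex)[ages_mat] * cost_scale.get(d, 1.0)
            cases_b = pop_w[:, None] * l_b[:, :-1] * prev_b[d] * active
            cases_s = pop_w[:, None] * l_s[:, :-1] * prev_s[d] * active
            values[("savings_cad", d, sex)] = float(
                healthcare_savings(cases_b, cases_s, cpc_mat, rate, horizon).sum()
            )

    return _aggregate(values)


def run_all(
    mi: ModelInputs, scenarios: list[Scenario], settings: EconSettings | None = None
) -> pd.DataFrame:
    """Deterministic runs for a list of scenarios, stacked long."""
    frames = []
    for sc in scenarios:
        s = run_scenario(mi, sc, settings).rename("value").reset_index()
        s.insert(0, "scenario", sc.id)
        frames.append(s)
    return pd.concat(frames, ignore_index=True)


@dataclass
class McSettings:
    """Monte Carlo uncertainty settings.

    Per iteration the pipeline reruns with: relative risks per 20 mmHg
    scaled by a log-normal factor per disease, sodium->SBP slopes by a
    truncated-normal factor, DRI-group intake means drawn normal around
    their means with their standard errors, per-case costs scaled by a
    unit-mean gamma factor per disease, and case fatality scaled by a
    log-normal factor per disease.  Setting every spread to zero makes each
    iteration identical to the deterministic run.
    """

    n_iterations: int = 5000
    seed: int = 0
    rr20_log_sd: float = 0.10
    slope_rel_sd: float = 0.10
    intake_se_scale: float = 1.0
    cost_cv: float = 0.20
    cf_log_sd: float = 0.10

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        for name in ("rr20_log_sd", "slope_rel_sd", "intake_se_scale", "cost_cv", "cf_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _draw_iteration(mi: ModelInputs, mc: McSettings, iteration: int):
    """Parameter draws for one iteration from an order-independent substream."""
    rng = np.random.default_rng([mc.seed, iteration])
    rr20_mult = {d: float(np.exp(rng.normal(0.0, mc.rr20_log_sd))) for d in DISEASES}
    slope_mult = max(0.0, float(rng.normal(1.0, mc.slope_rel_sd)))
    effect = mi.effect.perturbed(rr20_mult, slope_mult)
    intake_means = {
        k: max(1.0, float(rng.normal(m, mi.sodium.se[k] * mc.intake_se_scale)))
        for k, m in mi.sodium.mean.items()
    }
    cf_scale = {d: float(np.exp(rng.normal(0.0, mc.cf_log_sd))) for d in DISEASES}
    if mc.cost_cv > 0:
        shape = 1.0 / mc.cost_cv**2
        cost_scale = {d: float(rng.gamma(shape, 1.0 / shape)) for d in DISEASES}
    else:
        cost_scale = {d: 1.0 for d in DISEASES}
    return effect, intake_means, cf_scale, cost_scale


def monte_carlo(
    mi: ModelInputs,
    scenario: Scenario,
    mc: McSettings,
    settings: EconSettings | None = None,
) -> pd.DataFrame:
    """Monte Carlo uncertainty intervals for one scenario.

    Returns a frame indexed by (outcome, disease, sex) with the
    deterministic ``point`` estimate, the Monte Carlo mean, and the
    empirical 2.5th/97.5th percentiles (95% UI).  Iterations use
    independent substreams derived from (seed, iteration), so results do
    not depend on execution order.
    """
    if mc.n_iterations < 2:
        raise ValueError("need n >= 2 iterations for percentiles")
    settings = settings or EconSettings()
    point = run_scenario(mi, scenario, settings)

    draws = np.empty((mc.n_iterations, len(point)))
    for it in range(mc.n_iterations):
        effect, intake_means, cf_scale, cost_scale = _draw_iteration(mi, mc, it)
        s = run_scenario(
            mi, scenario, settings,
            effect=effect, intake_means=intake_means,
            cf_scale=cf_scale, cost_scale=cost_scale,
        )
        draws[it] = s.to_numpy()

    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    out = pd.DataFrame(
        {
            "point": point.to_numpy(),
            "mc_mean": draws.mean(axis=0),
            "lo95": lo,
            "hi95": hi,
        },
        index=point.index,
    )
    return out


SENSITIVITY_RATES = (0.0, 0.015, 0.03)
SENSITIVITY_HORIZONS = (10, 50, None)


def sensitivity_suite(
    mi: ModelInputs, scenario: Scenario, settings: EconSettings | None = None
) -> pd.DataFrame:
    """Outcomes over discount rates {0, 1.5%, 3%} x horizons {10y, 50y, lifetime}.

    ``share_of_lifetime`` gives each horizon's fraction of the same-rate
    lifetime total (where the lifetime total is nonzero).
    """
    base = settings or EconSettings()
    rows = []
    for rate in SENSITIVITY_RATES:
        by_horizon = {}
        for horizon in SENSITIVITY_HORIZONS:
            s = run_scenario(
                mi,
                scenario,
                EconSettings(rate, horizon, base.currency_year, base.cpi_factor),
            )
            by_horizon[horizon] = s
        lifetime = by_horizon[None]
        for horizon, s in by_horizon.items():
            frame = s.rename("value").reset_index()
            frame.insert(0, "scenario", scenario.id)
            frame.insert(1, "discount_rate", rate)
            frame.insert(2, "horizon", "lifetime" if horizon is None else horizon)
            with np.errstate(divide="ignore", invalid="ignore"):
                share = np.where(lifetime.to_numpy() != 0, s.to_numpy() / lifetime.to_numpy(), np.nan)
            frame["share_of_lifetime"] = share
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def write_results(frame: pd.DataFrame, outdir: str | Path, metadata: dict | None = None) -> None:
    """Write a results CSV plus a run-metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / "results.csv", index=False)
    meta = {"pmslt_version": __version__}
    meta.update(metadata or {})
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
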