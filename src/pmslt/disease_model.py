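"""Three-state Markov disease sub-model (disease-free, diseased, dead from disease).

Each disease is simulated separately per sex as a closed cohort process on
proportions: within the sub-model there is no remission and no other-cause
death, so S + C + D is conserved (other-cause mortality enters in the
lifetable, which rescales sub-model outputs by survivorship - the
"proportional" separation of the multi-state lifetable).

Annual cycles convert rates to probabilities with q = 1 - exp(-rate), which
keeps transition probabilities in [0, 1] for any non-negative rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import MAX_AGE


def rate_to_prob(rate):
    """Annual transition probability for a constant hazard: q = 1 - e^(-rate)."""
    return -np.expm1(-np.asarray(rate, dtype=float))


def step(S, C, incidence, case_fatality):
    """One annual cycle of the three-state recursion.

    Parameters are the disease-free count ``S``, diseased count ``C`` and the
    annual incidence and case-fatality *rates*.  Returns
    ``(S', C', new_cases, disease_deaths)``.
    """
    i = np.asarray(incidence, dtype=float)
    f = np.asarray(case_fatality, dtype=float)
    if np.any(i < 0) or np.any(f < 0):
        raise ValueError("rates must be non-negative")
    q_i = rate_to_prob(i)
    q_f = rate_to_prob(f)
    new_cases = S * q_i
    disease_deaths = C * q_f
    return S - new_cases, C + new_cases - disease_deaths, new_cases, disease_deaths


@dataclass
class DiseaseTrajectory:
    """Cohort-by-year trajectories of one disease sub-model.

    All state arrays have shape (n_cohorts, T+1); flow arrays (new_cases,
    disease_deaths) have shape (n_cohorts, T).  States are proportions of
    the initial cohort (S+C+D = 1).  ``active[j, t]`` is True while cohort j
    is still inside the simulation window (age < 100 at the start of year t).
    """

    start_ages: np.ndarray
    S: np.ndarray
    C: np.ndarray
    D: np.ndarray
    new_cases: np.ndarray
    disease_deaths: np.ndarray
    active: np.ndarray

    @property
    def n_years(self) -> int:
        return self.new_cases.shape[1]

    def alive(self) -> np.ndarray:
        """Proportion still alive within the sub-model, per (cohort, year)."""
        return self.S + self.C

    def prevalence(self) -> np.ndarray:
        """Diseased proportion among the sub-model alive, start of year."""
        alive = self.alive()[:, :-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(alive > 0, self.C[:, :-1] / np.where(alive > 0, alive, 1.0), 0.0)

    def mortality_rate(self) -> np.ndarray:
        """Per-capita disease death risk among the sub-model alive, per year."""
        alive = self.alive()[:, :-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(alive > 0, self.disease_deaths / np.where(alive > 0, alive, 1.0), 0.0)


def run_cohorts(
    incidence: np.ndarray,
    case_fatality: np.ndarray,
    initial_prevalence: np.ndarray,
    start_ages: np.ndarray,
    pif: np.ndarray | None = None,
    max_age: int = MAX_AGE,
) -> DiseaseTrajectory:
    """Run the three-state recursion for a set of closed cohorts.

    ``incidence``, ``case_fatality`` and ``initial_prevalence`` are arrays
    over single ages 0..100.  Each cohort starts at its ``start_age`` with
    diseased proportion taken from observed prevalence at that age, and runs
    until age ``max_age``.  When ``pif`` (potential impact fraction per age)
    is given, incidence is scaled to i(a) * (1 - pif(a)) - the counterfactual
    run; both runs share the same case fatality.
    """
    start_ages = np.asarray(start_ages, dtype=int)
    i_eff = np.asarray(incidence, dtype=float)
    if pif is not None:
        i_eff = i_eff * (1.0 - np.asarray(pif, dtype=float))
    f = np.asarray(case_fatality, dtype=float)
    if np.any(i_eff < 0) or np.any(f < 0):
        raise ValueError("effective rates must be non-negative")

    n = len(start_ages)
    T = int(max_age - start_ages.min())
    S = np.zeros((n, T + 1))
    C = np.zeros((n, T + 1))
    D = np.zeros((n, T + 1))
    nc = np.zeros((n, T))
    dd = np.zeros((n, T))
    active = np.zeros((n, T), dtype=bool)

    C[:, 0] = initial_prevalence[start_ages]
    S[:, 0] = 1.0 - C[:, 0]

    q_i_by_age = rate_to_prob(i_eff)
    q_f_by_age = rate_to_prob(f)

    for t in range(T):
        ages = start_ages + t
        act = ages < max_age
        a = np.clip(ages, 0, max_age)
        q_i = np.where(act, q_i_by_age[a], 0.0)
        q_f = np.where(act, q_f_by_age[a], 0.0)
        new = S[:, t] * q_i
        die = C[:, t] * q_f
        S[:, t + 1] = S[:, t] - new
        C[:, t + 1] = C[:, t] + new - die
        D[:, t + 1] = D[:, t] + die
        nc[:, t] = new
        dd[:, t] = die
        active[:, t] = act

    return DiseaseTrajectory(start_ages, S, C, D, nc, dd, active)


def prevented_incident_cases(
    baseline: DiseaseTrajectory,
    scenario: DiseaseTrajectory,
    cohort_weights: np.ndarray | None = None,
    horizon_years: int | None = None,
) -> float:
    """Total prevented incident cases: sum over cohorts and years of
    (baseline new cases - scenario new cases), weighted by cohort size.
    """
    if baseline.new_cases.shape != scenario.new_cases.shape or not np.array_equal(
        baseline.start_ages, scenario.start_ages
    ):
        raise ValueError("baseline and scenario trajectories are misaligned")
    diff = baseline.new_cases - scenario.new_cases
    if horizon_years is not None:
        diff = diff[:, :horizon_years]
    per_cohort = diff.sum(axis=1)
    if cohort_weights is None:
        return float(per_cohort.sum())
    return float(np.dot(per_cohort, np.asarray(cohort_weights, dtype=float)))
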