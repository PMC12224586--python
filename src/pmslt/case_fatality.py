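"""Back-calculate case fatality from incidence, prevalence and cause-specific mortality.

Case fatality (the annual death rate from a disease among those who have it)
is rarely observed directly.  Under the three-state model it is identified
by the observed triple (incidence, prevalence, cause-specific mortality):

* a direct estimator divides cause-specific deaths by prevalent cases, with
  a small-count floor and the convention that case fatality is constant at
  ages below 35 (the ratio is too unstable in the young);
* a consistency refinement then adjusts case fatality age by age so that
  forward-running the three-state recursion of :mod:`pmslt.disease_model`
  from age 0 with the observed incidence reproduces the observed prevalence.

Because the forward recursion is triangular in age (states at age a+1 depend
only on rates at ages <= a), each sweep solves the annual case-fatality
probability in closed form given the current states; sweeps are iterated to
a residual tolerance so the solver is also well-behaved on data that are not
exactly consistent (e.g. after group aggregation round-trips).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .disease_model import rate_to_prob
from .grids import MAX_AGE

CONSTANT_BELOW_AGE = 35


@dataclass
class CaseFatalitySolution:
    """Solved case fatality with per-age prevalence fit diagnostics."""

    case_fatality: np.ndarray  # rate/year per age 0..100
    fit_residual: np.ndarray  # relative prevalence discrepancy per age
    converged: bool
    n_iter: int


def _carry_nearest(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid entries from the nearest valid age (ties -> younger)."""
    out = values.copy()
    idx_valid = np.flatnonzero(valid)
    if len(idx_valid) == 0:
        return out
    for k in np.flatnonzero(~valid):
        nearest = idx_valid[np.argmin(np.abs(idx_valid - k))]
        out[k] = values[nearest]
    return out


def _apply_constancy(f: np.ndarray, prevalent_weights: np.ndarray, below: int = CONSTANT_BELOW_AGE) -> np.ndarray:
    """Replace ages < ``below`` by their prevalence-weighted mean."""
    out = f.copy()
    w = prevalent_weights[:below]
    if w.sum() > 0:
        out[:below] = np.average(f[:below], weights=w)
    else:
        out[:below] = np.mean(f[:below])
    return out


def estimate_case_fatality_direct(
    prevalence: np.ndarray,
    cause_mortality: np.ndarray,
    population: np.ndarray,
    case_floor: float = 5.0,
    constant_below: int = CONSTANT_BELOW_AGE,
) -> np.ndarray:
    """Direct deaths-over-prevalent-cases estimator on the 1-year grid.

    ``prevalence`` and ``cause_mortality`` are per-capita proportions/risks;
    ``population`` is the count per age.  Ages with fewer than ``case_floor``
    prevalent cases borrow the estimate from the nearest valid age; ages
    below ``constant_below`` are then replaced by their prevalence-weighted
    mean.
    """
    prevalence = np.asarray(prevalence, dtype=float)
    cause_mortality = np.asarray(cause_mortality, dtype=float)
    population = np.asarray(population, dtype=float)

    deaths = cause_mortality * population
    prevalent = prevalence * population
    if deaths.sum() > 0 and prevalent.sum() == 0:
        raise ValueError("cause-specific deaths observed with zero prevalence everywhere")

    valid = prevalent >= case_floor
    f = np.zeros_like(prevalence)
    np.divide(deaths, prevalent, out=f, where=valid)
    f = _carry_nearest(f, valid) if valid.any() else f
    f = np.clip(f, 0.0, None)
    return _apply_constancy(f, prevalent, constant_below)


def _forward_prevalence(incidence: np.ndarray, f: np.ndarray, max_age: int = MAX_AGE):
    """Run the three-state recursion from age 0; return per-age (S, C, prevalence)."""
    q_i = rate_to_prob(incidence)
    q_f = rate_to_prob(f)
    S = np.zeros(max_age + 1)
    C = np.zeros(max_age + 1)
    S[0] = 1.0
    for a in range(max_age):
        new = S[a] * q_i[a]
        die = C[a] * q_f[a]
        S[a + 1] = S[a] - new
        C[a + 1] = C[a] + new - die
    alive = S + C
    with np.errstate(divide="ignore", invalid="ignore"):
        prev = np.where(alive > 0, C / np.where(alive > 0, alive, 1.0), 0.0)
    return S, C, prev


def refine_case_fatality(
    initial_f: np.ndarray,
    incidence: np.ndarray,
    prevalence: np.ndarray,
    population: np.ndarray,
    max_iter: int = 20,
    tol: float = 1e-12,
    constant_below: int = CONSTANT_BELOW_AGE,
    max_rate: float = 5.0,
) -> CaseFatalitySolution:
    """Adjust case fatality so model-implied prevalence matches observation.

    Each sweep forward-runs the recursion and, at every age with a diseased
    population, solves the annual case-fatality probability that makes next
    year's model prevalence equal the observed value (clamped to a valid
    probability); sweeps repeat until the summed squared relative prevalence
    residual stops improving by ``tol`` or ``max_iter`` is reached.  Ages
    where the solve is uninformative (no modelled cases) keep their initial
    value, and the constancy-below-35 convention is re-imposed on the result.
    Non-convergence is flagged with a warning, never an exception.
    """
    f = np.clip(np.asarray(initial_f, dtype=float).copy(), 0.0, max_rate)
    incidence = np.asarray(incidence, dtype=float)
    p_obs = np.asarray(prevalence, dtype=float)
    population = np.asarray(population, dtype=float)

    q_max = rate_to_prob(max_rate)

    def residual(prev_model):
        denom = np.maximum(p_obs, 1e-9)
        return (prev_model - p_obs) / denom

    last_rss = np.inf
    converged = False
    n_iter = 0
    prev_model = _forward_prevalence(incidence, f)[2]
    if incidence.max() == 0:
        # No information: the model can never produce cases.
        res = residual(prev_model)
        return CaseFatalitySolution(f, res, True, 0)

    for n_iter in range(1, max_iter + 1):
        q_i = rate_to_prob(incidence)
        q_f = rate_to_prob(f)
        S = 1.0
        C = 0.0
        new_f = f.copy()
        for a in range(MAX_AGE):
            new = S * q_i[a]
            target = p_obs[a + 1]
            if C > 1e-15 and target < 1.0:
                # Solve C' / (S' + C') = target for this age's q_f.
                q = (C + new - target * (S + C)) / (C * (1.0 - target))
                q = min(max(q, 0.0), q_max)
                new_f[a] = -np.log1p(-q)
            q_fa = rate_to_prob(new_f[a])
            die = C * q_fa
            S = S - new
            C = C + new - die
        f = np.clip(new_f, 0.0, max_rate)
        prev_model = _forward_prevalence(incidence, f)[2]
        rss = float(np.sum(residual(prev_model) ** 2))
        if abs(last_rss - rss) < tol:
            converged = True
            break
        last_rss = rss

    if not converged:
        warnings.warn(
            f"case-fatality refinement did not converge in {max_iter} sweeps "
            f"(residual sum of squares {last_rss:.3e})",
            RuntimeWarning,
        )

    prevalent = p_obs * population
    f = _apply_constancy(f, prevalent, constant_below)
    prev_model = _forward_prevalence(incidence, f)[2]
    return CaseFatalitySolution(f, residual(prev_model), converged, n_iter)


def solve_case_fatality(
    incidence: np.ndarray,
    prevalence: np.ndarray,
    cause_mortality: np.ndarray,
    population: np.ndarray,
    refine: bool = True,
    **kwargs,
) -> CaseFatalitySolution:
    """Direct estimate followed (optionally) by the consistency refinement."""
    f0 = estimate_case_fatality_direct(prevalence, cause_mortality, population)
    if not refine:
        prev_model = _forward_prevalence(incidence, f0)[2]
        denom = np.maximum(prevalence, 1e-9)
        return CaseFatalitySolution(f0, (prev_model - prevalence) / denom, True, 0)
    return refine_case_fatality(f0, incidence, prevalence, population, **kwargs)
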