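"""pmslt: proportional multi-state lifetable simulation of sodium-reduction
policy impacts on ischemic heart disease and stroke.

The package couples a population lifetable to per-disease three-state
Markov models (disease-free, diseased, dead from the disease).  Sodium
counterfactuals shift systolic blood pressure, blood pressure shifts
disease incidence through log-linear relative risks, and the lifetable
turns incidence changes into prevented cases, QALYs gained and discounted
healthcare-cost savings, with Monte Carlo uncertainty intervals.
"""

__version__ = "0.1.0"

from .exposure import (  # noqa: F401
    EffectModel,
    Scenario,
    default_scenarios,
    null_scenario,
    percent_reduction,
    pif_mean_shift,
    required_reduction,
    sodium_to_salt,
)
from .grids import AgeSexGrid, DISEASES, SEXES  # noqa: F401
from .lifetable_econ import EconSettings, discount_factor  # noqa: F401
from .synthetic import SyntheticInputs, generate_inputs  # noqa: F401


def __getattr__(name):
    # engine imports pull in the whole stack; keep the base import light.
    if name in ("ModelInputs", "McSettings", "prepare_inputs", "run_scenario",
                "run_all", "monte_carlo", "sensitivity_suite"):
        from . import engine

        return getattr(engine, name)
    raise AttributeError(name)
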