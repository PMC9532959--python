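import numpy as np
import pytest

from ckdhmm.likelihood import LikelihoodOptions
from ckdhmm.presets import preset_parameters, preset_population
from ckdhmm.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def unmeasured_params():
    return preset_parameters("unmeasured")


@pytest.fixture(scope="session")
def macro_params():
    return preset_parameters("macro")


@pytest.fixture(scope="session")
def macro_pi0():
    return np.asarray(preset_population("macro")["initial_distribution"])


@pytest.fixture(scope="session")
def macro_options(macro_pi0):
    """Correctly specified options for cohorts from the macro generator."""
    return LikelihoodOptions(initial="distribution",
                             initial_distribution=macro_pi0,
                             age_update="exact")


@pytest.fixture(scope="session")
def macro_cohort_small():
    """~120 patients, macro preset, no retention filter (all records kept)."""
    cfg = GeneratorConfig(n_patients=120, stratum="macro", min_obs=1,
                          window=6.0)
    return generate_cohort(cfg, seed=101)


@pytest.fixture(scope="session")
def macro_cohort_medium():
    cfg = GeneratorConfig(n_patients=900, stratum="macro", min_obs=1)
    return generate_cohort(cfg, seed=202)


def perturbed_parameters(base, seed: int):
    """A seeded random valid parameter set near (but not equal to) *base*."""
    from ckdhmm.parameters import ModelParameters, Multiplier, \
        emission_support
    rng = np.random.default_rng(seed)
    prog = base.progression_rates * rng.lognormal(0.0, 0.35, 4)
    death = base.death_rates * rng.lognormal(0.0, 0.35, 5)
    mults = {
        "age": Multiplier(float(np.exp(rng.normal(0.07, 0.02))),
                          float(np.exp(rng.normal(0.08, 0.02)))),
        "male": Multiplier(*np.exp(rng.normal(0.2, 0.15, 2))),
        "heart_failure": Multiplier(*np.exp(rng.normal(0.3, 0.2, 2))),
        "cancer": Multiplier(*np.exp(rng.normal(0.2, 0.2, 2))),
    }
    support = emission_support(2)
    E = np.zeros((6, 6))
    E[5, 5] = 1.0
    for r in range(5):
        w = rng.uniform(0.01, 0.1, 5) * support[r, :5]
        w[r] = rng.uniform(2.0, 6.0)
        E[r, :5] = w / w.sum()
    return ModelParameters(progression_rates=prog, death_rates=death,
                           multipliers=mults, emission=E, cohort=base.cohort)
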