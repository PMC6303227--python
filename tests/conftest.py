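import numpy as np
import pytest

from saltphenome.simulate import (
    GenotypeParams,
    ObservationModel,
    SimulationConfig,
    TreatmentSchedule,
    simulate_experiment,
    simulate_growth,
)


@pytest.fixture(scope="session")
def control_genotype():
    return GenotypeParams("ctrl", r0=0.12, K=450, beta_osm=0.0, beta_ion=0.0,
                          exclusion=0.5)


@pytest.fixture(scope="session")
def no_salt():
    return TreatmentSchedule.from_target(0.0)


@pytest.fixture(scope="session")
def salt_100():
    return TreatmentSchedule.from_target(100.0)


@pytest.fixture(scope="session")
def logistic_latents(control_genotype, no_salt):
    """Noiseless control trajectory, DAS 0..30."""
    return simulate_growth(control_genotype, no_salt, days=30, seed=0,
                           transp_cv=0.0)


def small_config(**overrides) -> SimulationConfig:
    """A compact experiment (3 lines x 2 treatments x 3 reps) for fast tests."""
    defaults = dict(
        genotypes=[
            GenotypeParams("tol", r0=0.12, K=450, exclusion=0.85),
            GenotypeParams("mid", r0=0.11, K=420, exclusion=0.55),
            GenotypeParams("sen", r0=0.12, K=450, beta_ion=0.16, exclusion=0.30),
        ],
        treatments=[TreatmentSchedule.from_target(t) for t in (0.0, 80.0)],
        n_reps=3,
        days=30,
        observation=ObservationModel(),
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_experiment():
    return simulate_experiment(small_config())


@pytest.fixture(scope="session")
def default_experiment():
    """The full 7-line x 4-treatment x 6-replicate synthetic screening."""
    return simulate_experiment(SimulationConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
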