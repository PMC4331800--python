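import numpy as np
import pytest

from strategykit.sigma70_pwm import build_promoter_model
from strategykit.synthetic_fixtures import (
    SimConfig,
    simulate_phage_genome,
    simulate_training_promoters,
)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def sim_genome():
    """One deterministic simulated phage genome shared across tests."""
    return simulate_phage_genome(SimConfig(seed=2))


@pytest.fixture(scope="session")
def sigma70_model():
    return build_promoter_model(simulate_training_promoters(500, seed=77))

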