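import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from msbind import Peptide, ReferenceProfile, SimConfig, simulate
from msbind.energy_models import EnergyParams, MSModel
from msbind.sequence_space import SLOTS_PER_POSITION


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120322)


@pytest.fixture(scope="session")
def small_ms_dataset():
    """A small MS-truth array: 300 length-10 peptides, true S=4, noise 0.1 RT."""
    return simulate(
        SimConfig(
            n_peptides=300,
            lengths=((10, 1.0),),
            true_S=4,
            noise_sd=0.1,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def random_ms_model(rng):
    """An arbitrary MS model with S=3 and alanine reference."""
    profile = ReferenceProfile(("A", "A", "A"))
    J = rng.normal(0.0, 1.0, size=(3, SLOTS_PER_POSITION))
    return MSModel(EnergyParams(profile, J, 0.0), alpha=2.5)
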