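import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from phylotrait.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-genome, 50-feature synthetic dataset shared across tests."""
    return simulate_dataset(SimulationConfig(n_genomes=60, n_features=50, seed=11))


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The 200-genome benchmark-condition dataset (heavier; session-cached)."""
    return simulate_dataset(SimulationConfig(seed=1))
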