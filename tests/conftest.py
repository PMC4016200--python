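import pytest

from cdseq.models import default_contrasts
from cdseq.quantify import merge_by_condition
from cdseq.synthetic import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_transcripts=400, library_size_mean=500_000, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One simulated Cd time course shared across tests (read-only)."""
    libraries, models, truth = simulate_counts(small_config)
    return libraries, models, truth


@pytest.fixture(scope="session")
def merged_small(small_dataset):
    libraries, models, truth = small_dataset
    return merge_by_condition(libraries), models, truth


@pytest.fixture(scope="session")
def contrasts():
    return default_contrasts()
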