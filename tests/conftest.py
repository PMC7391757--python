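import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ampmine.pipeline import PipelineConfig, mine
from ampmine.synthdata import generate_dataset

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_dataset():
    """The reference study conditions: 20 planted genes, 80 decoys, seed 1."""
    return generate_dataset(1)


@pytest.fixture(scope="session")
def default_candidates(default_dataset):
    contigs, refs, _counts, _truth = default_dataset
    return mine(contigs, refs, PipelineConfig())


@pytest.fixture(scope="session")
def small_dataset():
    """A lighter dataset for unit-level pipeline tests."""
    return generate_dataset(7, n_planted=10, n_decoys=20)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
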