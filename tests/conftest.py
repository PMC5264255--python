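import numpy as np
import pytest

from minimeta.config import PipelineConfig
from minimeta.mock import generate_community, unitigs_and_truth


@pytest.fixture(scope="session")
def small_community():
    """Six 30 kb genomes, one strain pair, deterministic."""
    com = generate_community(
        n_genomes=6,
        length=30000,
        n_strain_pairs=1,
        ani=0.98,
        repeat_count=12,
        repeat_length=150,
        seed=11,
    )
    return unitigs_and_truth(com, k=41, seed=11)


@pytest.fixture(scope="session")
def clean_community():
    """Four 60 kb genomes, no strain pairs: every component genome-pure."""
    com = generate_community(
        n_genomes=4,
        length=60000,
        n_strain_pairs=0,
        ani=0.98,
        repeat_count=10,
        repeat_length=150,
        seed=7,
    )
    return unitigs_and_truth(com, k=41, seed=7)


@pytest.fixture()
def cfg():
    return PipelineConfig.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
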