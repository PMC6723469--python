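import numpy as np
import pytest

from annoconcord.pipeline import PipelineConfig, run_in_memory
from annoconcord.simulate import SimulationConfig, clean_corruption, generate

TREE10 = (
    "(((s01:0.1,s02:0.1):0.1,(s03:0.1,s04:0.1):0.1):0.1,"
    "((s05:0.1,s06:0.1):0.1,(s07:0.1,s08:0.1):0.1):0.05,"
    "(s09:0.15,s10:0.15):0.1);"
)

TREE6 = "(((s1:0.1,s2:0.1):0.1,(s3:0.1,s4:0.1):0.1):0.05,(s5:0.2,s6:0.2):0.05);"


@pytest.fixture(scope="session")
def tree10() -> str:
    return TREE10


@pytest.fixture(scope="session")
def tree6() -> str:
    return TREE6


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """Seven families, ten species, no corruption (the clean-channel setting)."""
    return SimulationConfig(
        species_tree_newick=TREE10,
        duplication_rate=3.0,
        loss_rate=0.5,
        corruption=clean_corruption(),
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return generate(clean_config)


@pytest.fixture(scope="session")
def clean_results(clean_config, clean_dataset):
    """Full pipeline output on the clean-channel dataset (shared: ~20 s)."""
    return run_in_memory(PipelineConfig(simulation=clean_config, seed=42), clean_dataset)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
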