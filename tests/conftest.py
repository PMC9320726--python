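import numpy as np
import pytest

from tssatlas.core import Feature, FeatureTable, GenomeSet
from tssatlas.synthetic_data import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def default_sim():
    """One 100-kb simulated genome + annotation shared across tests."""
    cfg = SimulationConfig(genome_length=(100_000,), seed=11)
    genome, features = simulate_genome(cfg)
    return cfg, genome, features


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return GenomeSet({"chr": seq})


@pytest.fixture()
def toy_features():
    return FeatureTable(
        [
            Feature("chr", 1000, 2000, "+", "gene", "gA"),
            Feature("chr", 2500, 3200, "-", "gene", "gB"),
            Feature("chr", 4000, 4075, "+", "tRNA", "tC"),
        ]
    )
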