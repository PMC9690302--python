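import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from chloronet.grn import EngineConfig, center_expression, infer_network
from chloronet.synthetic_data import (
    SynthGenomeConfig,
    simulate_expression,
    simulate_genomes,
)


@pytest.fixture(scope="session")
def genomes():
    """Six synthetic quadripartite genomes plus planted truth."""
    return simulate_genomes(SynthGenomeConfig(rng_seed=1))


@pytest.fixture(scope="session")
def expression():
    """Planted modular expression data (centered) plus truth."""
    matrix, truth = simulate_expression()
    return center_expression(matrix), truth


@pytest.fixture(scope="session")
def inferred(expression):
    matrix, truth = expression
    return infer_network(matrix, EngineConfig(rng_seed=7)), truth
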