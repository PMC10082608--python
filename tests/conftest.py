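import numpy as np
import pytest

from agrn.data_io import ExpressionMatrix, GoldStandard, RegulatorSet
from agrn.synthetic import SyntheticConfig, generate_network, simulate_expression


@pytest.fixture(scope="session")
def small_fixture():
    """A 20-gene / 5-TF synthetic network with recoverable structure."""
    config = SyntheticConfig(seed=7)
    network = generate_network(config)
    expression = simulate_expression(network, config)
    tfs = RegulatorSet(tf_ids=network.tf_ids)
    gold = GoldStandard(labeled_pairs={pair: 1 for pair in network.edges})
    return config, network, expression, tfs, gold


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_expression():
    values = np.array([
        [0.1, 0.2, 0.3],
        [1.0, 1.1, 1.2],
        [0.5, 0.4, 0.9],
        [0.0, 0.7, 0.2],
    ])
    return ExpressionMatrix(gene_ids=("G1", "G2", "G3"), values=values)
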