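import numpy as np
import pytest

from qeqnet import ChargeModel, FeaturizationConfig, GNNConfig, parse_molecule
from qeqnet.synth import generate_toy_molecules


@pytest.fixture(scope="session")
def scheme():
    return FeaturizationConfig()


@pytest.fixture(scope="session")
def small_model():
    """Seeded, untrained model: charges are uncalibrated but every structural
    contract (conservation, symmetry, batching) must already hold."""
    return ChargeModel.initialize(
        seed=1234, gnn_config=GNNConfig(n_layers=3, hidden_dim=32), head_hidden=16
    )


@pytest.fixture(scope="session")
def methane():
    return parse_molecule("C", "smiles", name="methane")


@pytest.fixture(scope="session")
def acetate():
    return parse_molecule("CC(=O)[O-]", "smiles", name="acetate")


@pytest.fixture(scope="session")
def toy_molecules():
    return generate_toy_molecules(60, seed=2024, max_heavy_atoms=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
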