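import numpy as np
import pytest

from temponet.dynet import MultilayerNetwork
from temponet.io_core import Parcellation
from temponet.synth import default_parcellation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def parc20() -> Parcellation:
    """20 nodes round-robin over the nine default subnetworks."""
    return default_parcellation(20)


@pytest.fixture
def two_group_parcellation() -> Parcellation:
    node_ids = ("a", "b", "c", "d")
    return Parcellation(
        node_ids=node_ids,
        node_labels=("A", "B", "C", "D"),
        subnetwork_of={"a": "g1", "b": "g1", "c": "g2", "d": "g2"},
        subnetwork_set=("g1", "g2"),
    )


def random_multilayer(rng, n_nodes: int, n_layers: int, p: float = 0.4) -> MultilayerNetwork:
    """Random binary symmetric layer stack with zero diagonal."""
    layers = np.zeros((n_layers, n_nodes, n_nodes), dtype=np.int8)
    iu, ju = np.triu_indices(n_nodes, k=1)
    for w in range(n_layers):
        edges = rng.random(len(iu)) < p
        layers[w, iu[edges], ju[edges]] = 1
        layers[w, ju[edges], iu[edges]] = 1
    return MultilayerNetwork(layers=layers, density=p)
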