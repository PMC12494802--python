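import numpy as np
import pytest

from grnembed.gae import GAEConfig, train_gae
from grnembed.graph_prep import one_hot_features, split_edges
from grnembed.regnet_io import build_graph
from grnembed.synthetic_data import NetworkGenConfig, generate_network

TABLE1 = """\
TF\tTarget_Gene\tRegulation\tPMID
AHR\tIL13\tUnknown\t22981205
AHR\tIL1B\tUnknown\t23349129
AHR\tIL6\tActivation\t20511231
AHR\tIL6\tUnknown\t18483242; 23349129
AIP\tNFKB2\tRepression\t21984905
"""


@pytest.fixture
def table1_text() -> str:
    return TABLE1


@pytest.fixture(scope="session")
def small_net_config() -> NetworkGenConfig:
    return NetworkGenConfig(n_tf=15, n_target=40, n_overlap=5, n_rows=150,
                            duplicate_fraction=0.2, n_modules=3, seed=7)


@pytest.fixture(scope="session")
def small_graph(small_net_config):
    return build_graph(generate_network(small_net_config))


@pytest.fixture(scope="session")
def default_graph():
    """The default ~200-node / ~600-edge synthetic fixture."""
    return build_graph(generate_network(NetworkGenConfig(seed=5)))


@pytest.fixture(scope="session")
def trained_gae(default_graph):
    """One trained autoencoder shared across model/metric tests."""
    graph = default_graph
    split = split_edges(graph, seed=11)
    params, history, z = train_gae(graph, one_hot_features(graph), split,
                                   GAEConfig(seed=11))
    return {"graph": graph, "split": split, "params": params,
            "history": history, "z": z}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
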