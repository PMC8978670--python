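import pytest

from sgii import (
    MOUSE_COEFFICIENTS,
    SyntheticConfig,
    compute_centralities,
    generate_tables,
    mark_overlength,
    merge_networks,
    score_all,
)

# allow "from oracles import ..." in test modules
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def toy_network():
    """lpi={(L1,P1),(L2,P1)}, ppi={(P1,P2)}: 4 nodes, 3 edges, P1 is the hub."""
    return merge_networks([("L1", "P1"), ("L2", "P1")], [("P1", "P2")])


@pytest.fixture(scope="session")
def small_config():
    """A fast fixture for unit tests (the benchmark defaults stay in SyntheticConfig)."""
    return SyntheticConfig(n_lncrna=250, n_protein=60, n_essential=8,
                           essential_degree_range=(20, 30), seed=424242)


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_tables(small_config)


@pytest.fixture(scope="session")
def small_network(small_data):
    net = merge_networks(small_data.lpi_pairs, small_data.ppi_pairs)
    return mark_overlength(net, small_data.sequences)


@pytest.fixture(scope="session")
def default_pipeline():
    """Full benchmark fixture run end to end once per session.

    Returns (config, data, network, centralities, gic results).
    """
    config = SyntheticConfig()
    data = generate_tables(config)
    net = merge_networks(data.lpi_pairs, data.ppi_pairs)
    mark_overlength(net, data.sequences)
    centralities = compute_centralities(net)
    results = score_all(data.sequences, MOUSE_COEFFICIENTS)
    return config, data, net, centralities, results
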