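import numpy as np
import pytest

import gdalink as g


@pytest.fixture
def toy_records():
    return g.graph_io.records_from_pairs([("g1", "d1"), ("g1", "d2"), ("g2", "d1")])


@pytest.fixture
def toy_graph(toy_records):
    return g.build_bipartite_graph(toy_records)


@pytest.fixture(scope="session")
def small_block_graph():
    """A 60x50 planted-block graph, dense enough to split and train quickly."""
    spec = g.BlockModelSpec(
        n_genes=60, n_diseases=50, k_blocks=3, p_in=0.3, p_out=0.02, seed=11
    )
    graph, blocks = g.generate_block_bipartite(spec)
    return graph, blocks


@pytest.fixture(scope="session")
def small_split(small_block_graph):
    graph, _ = small_block_graph
    return g.split_edges(graph, val_frac=0.05, test_frac=0.10, seed=5)


@pytest.fixture(scope="session")
def trained_small(small_block_graph, small_split):
    """One short training run shared across tests that only need embeddings."""
    graph, _ = small_block_graph
    config = g.ModelConfig(feature_size=16, epochs=40, seed=3)
    weights, z, history = g.train(graph, small_split, config)
    return graph, small_split, config, weights, z, history
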