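import numpy as np
import pytest
import scipy.sparse as sp

import gdalink as g
from gdalink.errors import ConvergenceError, ValidationError
from gdalink.gcn_autoencoder import (
    ModelWeights,
    _loss_grad_z,
    encode,
    init_weights,
    sigmoid,
)
from gdalink.graph_io import records_from_pairs


class TestNormalizeAdjacency:
    def test_single_edge_hand_computed(self):
        # two nodes, one edge: d-tilde = 2 for both, every entry 1/2
        graph = g.build_bipartite_graph(records_from_pairs([("g1", "d1")]))
        a = g.normalize_adjacency(graph).toarray()
        assert np.allclose(a, [[0.5, 0.5], [0.5, 0.5]])

    def test_path_graph_hand_computed(self):
        # g1 - d1 - g2: d-tilde(d1) = 3, d-tilde(g1) = d-tilde(g2) = 2
        graph = g.build_bipartite_graph(records_from_pairs([("g1", "d1"), ("g2", "d1")]))
        a = g.normalize_adjacency(graph).toarray()
        d1 = graph.node_index["d1"]
        g1 = graph.node_index["g1"]
        assert a[d1, d1] == pytest.approx(1 / 3)
        assert a[g1, d1] == pytest.approx(1 / np.sqrt(6))

    def test_isolated_node_keeps_unit_self_loop(self):
        graph = g.build_bipartite_graph(records_from_pairs([("g1", "d1"), ("g2", "d2")]))
        # restrict message passing to one train edge; g2/d2 become isolated
        train = graph.edges[:1]
        a = g.normalize_adjacency(graph, train).toarray()
        g2 = graph.node_index["g2"]
        assert a[g2, g2] == pytest.approx(1.0)
        assert a[g2].sum() == pytest.approx(1.0)

    def test_symmetric_with_unit_spectral_radius(self, small_block_graph):
        graph, _ = small_block_graph
        a = g.normalize_adjacency(graph)
        assert abs(a - a.T).max() < 1e-14
        eigs = np.linalg.eigvalsh(a.toarray())
        assert eigs.max() <= 1 + 1e-10

    def test_foreign_train_edge_rejected(self, small_block_graph):
        graph, _ = small_block_graph
        bogus = np.array([[0, graph.n_genes]])
        if tuple(bogus[0]) in graph.edge_set():
            bogus = np.array([[1, graph.n_genes]])
        with pytest.raises(ValidationError):
            g.normalize_adjacency(graph, bogus)


class TestActivations:
    def test_relu(self):
        x = np.array([-3.0, 0.0, 2.5])
        assert np.array_equal(g.relu(x), [0.0, 0.0, 2.5])

    def test_dropout_identity_cases(self):
        x = np.ones((4, 4))
        assert g.dropout(x, 0.0, training=True, rng=0) is x
        assert g.dropout(x, 0.5, training=False) is x

    def test_dropout_invalid_p(self):
        with pytest.raises(ValidationError):
            g.dropout(np.ones(3), 1.0, training=True)

    def test_dropout_unbiased_mean(self):
        # E[dropout(x)] = x: mean over 1e5 draws within 3 standard errors
        n = 100_000
        out = g.dropout(np.ones(n), 0.5, training=True, rng=99)
        se = np.sqrt(0.5 / (1 - 0.5) / n)  # var of Bernoulli/(1-p) estimator
        assert abs(out.mean() - 1.0) < 3 * se
        surviving = out[out > 0]
        assert np.allclose(surviving, 2.0)  # survivors scaled by 1/(1-p)


class TestEncodeDecode:
    def test_zero_weights_give_zero_embeddings(self, small_block_graph):
        graph, _ = small_block_graph
        cfg = g.ModelConfig(feature_size=4, hidden_size=6, dropout_p=0.0)
        w = ModelWeights(
            W1=np.zeros((graph.n, 6)), W2=np.zeros((6, 4))
        )
        z = encode(g.normalize_adjacency(graph), w, cfg)
        assert np.array_equal(z, np.zeros((graph.n, 4)))

    def test_first_layer_preactivation_on_single_edge_graph(self):
        # 2-node graph, W1 = I: layer-1 pre-activation rows are [0.5, 0.5]
        graph = g.build_bipartite_graph(records_from_pairs([("g1", "d1")]))
        cfg = g.ModelConfig(feature_size=2, hidden_size=2, dropout_p=0.0)
        w = ModelWeights(W1=np.eye(2), W2=np.eye(2))
        _, cache = encode(g.normalize_adjacency(graph), w, cfg, return_cache=True)
        assert np.allclose(cache["s"], [[0.5, 0.5], [0.5, 0.5]])

    def test_permutation_equivariance(self):
        """Relabeling nodes (and permuting W1 rows to match) permutes Z rows."""
        rng = np.random.default_rng(4)
        pairs = [("g1", "d1"), ("g1", "d2"), ("g2", "d1"), ("g3", "d3"), ("g2", "d3")]
        graph = g.build_bipartite_graph(records_from_pairs(pairs))
        cfg = g.ModelConfig(feature_size=3, hidden_size=4, dropout_p=0.0)
        w = init_weights(graph.n, cfg, rng)
        z = encode(g.normalize_adjacency(graph), w, cfg)

        # present the same records in a different order => permuted indexing
        graph2 = g.build_bipartite_graph(records_from_pairs(pairs[::-1]))
        perm = np.array([graph2.node_index[nid] for nid in graph.node_ids])
        w2 = ModelWeights(W1=np.empty_like(w.W1), W2=w.W2.copy())
        w2.W1[perm] = w.W1
        z2 = encode(g.normalize_adjacency(graph2), w2, cfg)
        assert np.allclose(z2[perm], z, atol=1e-12)

    def test_encode_pure_function_without_dropout(self, trained_small):
        graph, split, cfg, weights, z, _ = trained_small
        a = g.normalize_adjacency(graph, split.train_pos)
        assert np.array_equal(encode(a, weights, cfg), encode(a, weights, cfg))

    def test_shape_mismatch_rejected(self, small_block_graph):
        graph, _ = small_block_graph
        cfg = g.ModelConfig(feature_size=4, hidden_size=6)
        w = ModelWeights(W1=np.zeros((3, 6)), W2=np.zeros((6, 4)))
        with pytest.raises(ValidationError):
            encode(g.normalize_adjacency(graph), w, cfg)

    def test_decode_pair_closed_form_and_symmetry(self):
        z = np.zeros((3, 4))
        z[0, 0] = 1.0
        z[1, 0] = 1.0
        raw, prob = g.decode_pair(z, 0, 1)
        assert raw == 1.0
        assert prob == pytest.approx(1 / (1 + np.exp(-1)))
        assert g.decode_pair(z, 0, 1) == g.decode_pair(z, 1, 0)
        raw02, prob02 = g.decode_pair(z, 0, 2)
        assert (raw02, prob02) == (0.0, 0.5)

    def test_decode_pair_index_errors(self):
        z = np.zeros((2, 2))
        with pytest.raises(ValidationError):
            g.decode_pair(z, 0, 5)
        with pytest.raises(ValidationError):
            g.decode_pair(z, 1, 1)


class TestLoss:
    def test_uninformative_probabilities_give_two_ln_two(self):
        z = np.zeros((4, 3))  # all dot products 0 => p = 0.5 everywhere
        loss = g.reconstruction_loss(z, np.array([[0, 2]]), np.array([[1, 3]]))
        assert loss == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_confident_correct_predictions_drive_loss_to_zero(self):
        z = np.zeros((4, 2))
        z[0] = [20.0, 0.0]
        z[2] = [20.0, 0.0]   # positive pair scores huge
        z[1] = [0.0, 20.0]
        z[3] = [0.0, -20.0]  # negative pair scores hugely negative
        loss = g.reconstruction_loss(z, np.array([[0, 2]]), np.array([[1, 3]]))
        assert loss < 1e-6

    def test_empty_sets_rejected(self):
        with pytest.raises(ValidationError):
            g.reconstruction_loss(np.zeros((2, 2)), np.empty((0, 2)), np.array([[0, 1]]))

    def test_gradient_matches_finite_differences(self, small_block_graph):
        graph, _ = small_block_graph
        rng = np.random.default_rng(8)
        z = rng.normal(size=(graph.n, 3))
        pos = graph.edges[:20]
        neg = np.array([[0, graph.n_genes], [1, graph.n_genes + 1]])
        grad = _loss_grad_z(z, pos, neg)
        eps = 1e-6
        for i, j in [(0, 0), (5, 2), (graph.n - 1, 1)]:
            zp, zm = z.copy(), z.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            num = (
                g.reconstruction_loss(zp, pos, neg) - g.reconstruction_loss(zm, pos, neg)
            ) / (2 * eps)
            assert grad[i, j] == pytest.approx(num, abs=1e-6)


class TestTraining:
    def test_history_length_matches_epochs(self, small_block_graph, small_split):
        graph, _ = small_block_graph
        _, _, hist = g.train(graph, small_split, g.ModelConfig(feature_size=8, epochs=1, seed=0))
        assert len(hist.loss) == len(hist.val_auc) == len(hist.val_ap) == 1

    def test_loss_decreases_on_structured_graph(self, trained_small):
        *_, history = trained_small
        assert history.loss[-1] < history.loss[0]

    def test_validation_auc_improves_over_training(self, trained_small):
        *_, history = trained_small
        assert history.val_auc[-1] > history.val_auc[0]

    def test_same_seed_bitwise_identical(self, small_block_graph, small_split):
        graph, _ = small_block_graph
        cfg = g.ModelConfig(feature_size=8, epochs=5, seed=21)
        w1, z1, h1 = g.train(graph, small_split, cfg)
        w2, z2, h2 = g.train(graph, small_split, cfg)
        assert np.array_equal(z1, z2)
        assert np.array_equal(w1.W1, w2.W1)
        assert h1.loss == h2.loss and h1.test_auc == h2.test_auc

    def test_divergence_aborts_with_diagnostic(
        self, small_block_graph, small_split, monkeypatch
    ):
        graph, _ = small_block_graph
        import gdalink.gcn_autoencoder as mod

        monkeypatch.setattr(mod, "reconstruction_loss", lambda *a, **k: float("nan"))
        cfg = g.ModelConfig(feature_size=8, epochs=3, seed=0)
        with pytest.raises(ConvergenceError, match="epoch 1"):
            g.train(graph, small_split, cfg)

    def test_sigmoid_stable_at_extremes(self):
        assert sigmoid(np.array([-800.0]))[0] == 0.0
        assert sigmoid(np.array([800.0]))[0] == 1.0


class TestConfig:
    def test_hidden_defaults_to_twice_feature_size(self):
        assert g.ModelConfig(feature_size=50).hidden_size == 100

    @pytest.mark.parametrize(
        "kwargs", [{"dropout_p": 1.0}, {"epochs": 0}, {"feature_size": 0}, {"n_layers": 3}]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            g.ModelConfig(**kwargs)

    def test_model_roundtrip_save_load(self, trained_small, tmp_path):
        graph, _, cfg, weights, z, _ = trained_small
        from gdalink.gcn_autoencoder import load_model, save_model

        save_model(weights, z, cfg, graph, tmp_path)
        w2, z2, sidecar = load_model(tmp_path)
        assert np.array_equal(z2, z)
        assert np.array_equal(w2.W1, weights.W1)
        assert sidecar["config"]["feature_size"] == cfg.feature_size
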