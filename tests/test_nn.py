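import numpy as np
import pytest
import scipy.sparse as sp

from cgsig.nn.layers import (
    GNNConfig,
    _topk_select,
    gcn_conv,
    gcn_normalize,
    gin_conv,
    init_params,
    load_checkpoint,
    make_batch,
    model_forward,
    predict_proba,
    sag_pool,
    save_checkpoint,
    topk_pool,
)
from cgsig.nn.tensor import Tensor, segment_max, segment_mean, softmax_cross_entropy, spmm

from conftest import random_graph


def identity_mlp(d):
    """Weights making the GIN 2-layer ReLU MLP the identity on x >= 0."""
    eye = np.eye(d)
    zero = np.zeros(d)
    return Tensor(eye), Tensor(zero), Tensor(eye), Tensor(zero)


def adj_from_edges(n, edges, weights):
    a = np.zeros((n, n))
    for (i, j), w in zip(edges, weights):
        a[i, j] = a[j, i] = w
    return sp.csr_matrix(a)


class TestGINConv:
    def test_isolated_node_identity(self):
        x = Tensor(np.array([[0.5]]))
        out = gin_conv(x, sp.csr_matrix((1, 1)), 0.0, *identity_mlp(1))
        np.testing.assert_allclose(out.data, [[0.5]])

    def test_two_node_hand_evaluation(self):
        x = Tensor(np.array([[1.0], [2.0]]))
        adj = adj_from_edges(2, [(0, 1)], [1.0])
        out = gin_conv(x, adj, 0.0, *identity_mlp(1))
        np.testing.assert_allclose(out.data, [[3.0], [3.0]])
        out = gin_conv(x, adj, 1.0, *identity_mlp(1))
        np.testing.assert_allclose(out.data, [[4.0], [5.0]])  # (1+1)*1+2, (1+1)*2+1

    def test_sparse_aggregation_matches_dense_rule(self, rng):
        """(A + (1+eps) I) X via sparse ops equals the dense evaluation."""
        g = random_graph(rng, n_nodes=10, n_features=4)
        adj = adj_from_edges(10, g.edges, g.weights)
        x = Tensor(g.features[:, :4])
        eps = 0.3
        w1, b1, w2, b2 = identity_mlp(4)
        out = gin_conv(x, adj, eps, w1, b1, w2, b2)
        dense = (adj.toarray() + (1 + eps) * np.eye(10)) @ g.features[:, :4]
        np.testing.assert_allclose(out.data, np.maximum(dense, 0), atol=1e-6)


class TestGCNConv:
    def test_single_node_self_loop_identity(self):
        x = Tensor(np.array([[0.7, 0.2]]))
        norm = gcn_normalize(sp.csr_matrix((1, 1)))
        out = gcn_conv(x, norm, Tensor(np.eye(2)), Tensor(np.zeros(2)))
        np.testing.assert_allclose(out.data, [[0.7, 0.2]])

    def test_two_node_unit_edge_averages(self):
        x = np.array([[1.0], [3.0]])
        norm = gcn_normalize(adj_from_edges(2, [(0, 1)], [1.0]))
        out = gcn_conv(Tensor(x), norm, Tensor(np.eye(1)), Tensor(np.zeros(1)))
        np.testing.assert_allclose(out.data, [[2.0], [2.0]])  # (x_i + x_j)/2

    def test_zero_features_zero_output(self, rng):
        g = random_graph(rng, n_nodes=6, n_features=3)
        norm = gcn_normalize(adj_from_edges(6, g.edges, g.weights))
        out = gcn_conv(Tensor(np.zeros((6, 3))), norm, Tensor(np.eye(3)), Tensor(np.zeros(3)))
        assert (out.data == 0).all()


class TestPooling:
    def test_ratio_one_keeps_everything(self, rng):
        x = Tensor(rng.uniform(0, 1, (5, 3)))
        adj = sp.identity(5, format="csr") * 0
        p = Tensor(rng.normal(size=(3, 1)))
        x2, adj2, batch2, perm = topk_pool(x, adj.tocsr(), np.zeros(5, int), p, 1.0)
        assert list(perm) == list(range(5))

    def test_half_ratio_keeps_two_of_four(self, rng):
        x = Tensor(rng.uniform(0, 1, (4, 3)))
        p = Tensor(rng.normal(size=(3, 1)))
        _, _, _, perm = topk_pool(x, sp.csr_matrix((4, 4)), np.zeros(4, int), p, 0.5)
        assert len(perm) == 2

    def test_equal_scores_keep_lowest_indices(self):
        x = Tensor(np.ones((4, 2)))
        p = Tensor(np.ones((2, 1)))
        _, _, _, perm = topk_pool(x, sp.csr_matrix((4, 4)), np.zeros(4, int), p, 0.5)
        assert list(perm) == [0, 1]

    def test_selection_is_per_graph(self):
        scores = np.array([3.0, 1.0, 2.0, 9.0, 8.0, 7.0])
        batch = np.array([0, 0, 0, 1, 1, 1])
        perm = _topk_select(scores, batch, 0.34)  # ceil(0.34*3) = 2 per graph
        assert list(perm) == [0, 2, 3, 4]

    def test_sag_single_node_always_kept(self, rng):
        x = Tensor(rng.uniform(0, 1, (1, 3)))
        w, b = Tensor(rng.normal(size=(3, 1))), Tensor(np.zeros(1))
        _, _, _, perm = sag_pool(x, sp.csr_matrix((1, 1)), np.zeros(1, int), w, b, 0.25)
        assert list(perm) == [0]

    def test_sag_scores_match_dense_attention_oracle(self, rng):
        g = random_graph(rng, n_nodes=5, n_features=3)
        adj = adj_from_edges(5, g.edges, g.weights)
        x = g.features[:, :3]
        w = rng.normal(size=(3, 1))
        # dense evaluation of the one-layer attention convolution
        a_tilde = adj.toarray() + np.eye(5)
        d = 1.0 / np.sqrt(a_tilde.sum(1))
        dense_scores = ((d[:, None] * a_tilde * d[None, :]) @ x @ w).ravel()
        _, _, _, perm = sag_pool(Tensor(x), adj, np.zeros(5, int), Tensor(w),
                                 Tensor(np.zeros(1)), 0.4)
        expected = np.sort(np.argsort(-dense_scores, kind="stable")[:2])
        assert list(perm) == list(expected)


class TestSegmentOps:
    def test_mean_and_max_per_graph(self):
        x = Tensor(np.array([[0.0], [2.0], [5.0]]))
        seg = np.array([0, 0, 1])
        np.testing.assert_allclose(segment_mean(x, seg, 2).data, [[1.0], [5.0]])
        np.testing.assert_allclose(segment_max(x, seg, 2).data, [[2.0], [5.0]])

    def test_empty_segment_contributes_zeros(self):
        x = Tensor(np.array([[3.0]]))
        seg = np.array([1])
        np.testing.assert_allclose(segment_mean(x, seg, 2).data, [[0.0], [3.0]])
        np.testing.assert_allclose(segment_max(x, seg, 2).data, [[0.0], [3.0]])


@pytest.fixture
def tiny_batch(rng):
    graphs = [
        random_graph(rng, n_nodes=4, n_features=6, label=0, patient_id="A"),
        random_graph(rng, n_nodes=3, n_features=6, label=1, patient_id="B"),
    ]
    return make_batch(graphs)


class TestModelForward:
    @pytest.mark.parametrize("arch", ["gin_topk", "gin_sag", "gcn_topk", "gcn_sag"])
    def test_probabilities_sum_to_one(self, rng, tiny_batch, arch):
        conv, pool = arch.split("_")
        cfg = GNNConfig(conv_type=conv, pool_type=pool, in_features=6, hidden_units=8)
        params = init_params(cfg, rng)
        probs = predict_proba(params, tiny_batch, cfg)
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_deterministic(self, rng, tiny_batch):
        cfg = GNNConfig(in_features=6, hidden_units=8)
        params = init_params(cfg, rng)
        a = predict_proba(params, tiny_batch, cfg)
        b = predict_proba(params, tiny_batch, cfg)
        np.testing.assert_array_equal(a, b)

    def test_node_permutation_invariance(self, rng):
        g = random_graph(rng, n_nodes=12, n_features=6, label=0)
        cfg = GNNConfig(in_features=6, hidden_units=16)
        params = init_params(cfg, rng)
        p0 = predict_proba(params, make_batch([g]), cfg)
        perm = rng.permutation(12)
        inv = np.argsort(perm)
        g2 = random_graph(rng, n_nodes=12, n_features=6, label=0)
        g2.features = g.features[perm]
        g2.coords = g.coords[perm]
        e = inv[g.edges]
        order = np.lexsort((e.max(1), e.min(1)))
        g2.edges = np.sort(e, axis=1)[order]
        g2.weights = g.weights[order]
        p1 = predict_proba(params, make_batch([g2]), cfg)
        np.testing.assert_allclose(p0, p1, atol=1e-5)

    def test_reference_configuration_instantiates_on_100_node_graph(self, rng):
        """Best-model hyperparameters (512 hidden, ratio 0.5, 4 blocks)."""
        g = random_graph(rng, n_nodes=100, n_features=35, edge_p=0.1)
        cfg = GNNConfig(hidden_units=512, pooling_ratio=0.5, n_blocks=4)
        params = init_params(cfg, rng)
        probs = predict_proba(params, make_batch([g]), cfg)
        np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-6)

    def test_pooling_halves_node_count_each_block(self, rng):
        n = 64
        scores = rng.normal(size=n)
        batch = np.zeros(n, int)
        kept = _topk_select(scores, batch, 0.5)
        assert len(kept) == 32  # ceil(0.5 * 64)
        kept2 = _topk_select(scores[kept], batch[:32], 0.5)
        assert len(kept2) == 16

    def test_checkpoint_round_trip(self, rng, tiny_batch, tmp_path):
        cfg = GNNConfig(in_features=6, hidden_units=8)
        params = init_params(cfg, rng)
        save_checkpoint(tmp_path / "m.ckpt", params, cfg)
        params2, cfg2 = load_checkpoint(tmp_path / "m.ckpt")
        assert cfg2 == cfg
        np.testing.assert_array_equal(
            predict_proba(params, tiny_batch, cfg),
            predict_proba(params2, tiny_batch, cfg2),
        )


class TestGradients:
    @pytest.mark.parametrize("arch", ["gin_topk", "gcn_sag"])
    def test_analytic_gradients_match_finite_differences(self, arch):
        """End-to-end gradient check of the full model loss."""
        rng = np.random.default_rng(7)
        conv, pool = arch.split("_")
        cfg = GNNConfig(conv_type=conv, pool_type=pool, in_features=5,
                        hidden_units=6, n_blocks=2)
        graphs = [
            random_graph(rng, n_nodes=5, n_features=5, label=0, patient_id="A"),
            random_graph(rng, n_nodes=4, n_features=5, label=1, patient_id="B"),
        ]
        batch = make_batch(graphs)
        params = init_params(cfg, rng)

        def loss_value():
            logits = model_forward(params, batch, cfg)
            loss, _ = softmax_cross_entropy(logits, batch.labels)
            return loss

        loss = loss_value()
        loss.backward()
        grads = {k: v.grad.copy() for k, v in params.items()}
        h = 1e-6
        checked = 0
        for name, tensor in params.items():
            flat = tensor.data.reshape(-1)
            idxs = rng.choice(flat.size, size=min(3, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + h
                up = float(loss_value().data)
                flat[i] = orig - h
                down = float(loss_value().data)
                flat[i] = orig
                fd = (up - down) / (2 * h)
                an = grads[name].reshape(-1)[i]
                assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd)), (name, i, fd, an)
                checked += 1
        assert checked > 20
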