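"""Histogram features, JSD, adjacency, and the GCN forward/training."""

import numpy as np
import pytest
from scipy import sparse

from canopy_wsss.attention import NodeGrid
from canopy_wsss.graph import (
    GCNConfig,
    GCNModel,
    GraphStructure,
    NodeFeatures,
    build_adjacency,
    build_node_features,
    flat_to_grid,
    gcn_forward,
    grid_to_flat,
    jsd,
    make_pseudo_labels,
    node_histogram,
    node_histograms,
    node_index,
    pairwise_jsd,
    refine,
    train_gcn,
)


def make_node_grid(rng, shape=(4, 5)):
    images = rng.random((*shape, 8, 8, 3))
    probs = rng.random(shape)
    return NodeGrid(images=images, probs=probs)


class TestNodeFeatures:
    def test_feature_dim_and_count(self, rng):
        nodes = make_node_grid(rng)
        feats = build_node_features(nodes)
        assert feats.matrix.shape == (20, 192)

    def test_index_is_bijection(self):
        w, v = 6, 7
        seen = {node_index(r, c, w) for r in range(w) for c in range(v)}
        assert seen == set(range(w * v))

    def test_row_unflattens_to_block(self, rng):
        nodes = make_node_grid(rng)
        feats = build_node_features(nodes)
        w = nodes.grid_shape[0]
        row = feats.matrix[node_index(2, 3, w)]
        np.testing.assert_array_equal(row.reshape(8, 8, 3), nodes.images[2, 3])

    def test_grid_flat_round_trip(self, rng):
        grid = rng.random((5, 4))
        np.testing.assert_array_equal(flat_to_grid(grid_to_flat(grid), (5, 4)), grid)


class TestHistograms:
    def test_sums_to_one(self, rng):
        h = node_histogram(rng.random((8, 8, 3)))
        assert abs(h.sum() - 1.0) < 1e-12
        assert h.shape == (64,)

    def test_constant_gray_concentrates(self):
        block = np.full((8, 8, 3), 0.5)
        h = node_histogram(block)
        # RGB values all 0.5; HSV of gray is (0, 0, 0.5): two value clusters
        assert (h > 0).sum() <= 2

    def test_matches_explicit_bin_loop(self, rng):
        from skimage.color import rgb2hsv

        block = rng.random((8, 8, 3))
        values = np.concatenate([block.ravel(), rgb2hsv(block).ravel()])
        counts = np.zeros(64)
        for val in values:
            counts[min(int(val * 64), 63)] += 1
        np.testing.assert_allclose(node_histogram(block), counts / counts.sum())

    def test_batch_matches_per_node(self, rng):
        nodes = make_node_grid(rng, (3, 4))
        feats = build_node_features(nodes)
        batch = node_histograms(feats)
        w = nodes.grid_shape[0]
        for r in range(3):
            for c in range(4):
                np.testing.assert_allclose(
                    batch[node_index(r, c, w)], node_histogram(nodes.images[r, c])
                )


class TestJSD:
    def test_identical_is_zero(self, rng):
        q = rng.random(64)
        q /= q.sum()
        assert jsd(q, q) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_point_masses_reach_ln2(self):
        q1 = np.zeros(64)
        q2 = np.zeros(64)
        q1[0] = 1.0
        q2[63] = 1.0
        assert jsd(q1, q2) == pytest.approx(np.log(2), abs=1e-6)

    def test_symmetric(self, rng):
        q1, q2 = rng.random(64), rng.random(64)
        q1 /= q1.sum()
        q2 /= q2.sum()
        assert abs(jsd(q1, q2) - jsd(q2, q1)) < 1e-12
        assert 0.0 <= jsd(q1, q2) <= np.log(2)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            jsd(np.ones(64), np.ones(64) / 64)

    def test_pairwise_matches_scalar(self, rng):
        q = rng.random((20, 64))
        q /= q.sum(axis=1, keepdims=True)
        mat = pairwise_jsd(q, chunk=7)
        for i in range(20):
            for j in range(20):
                assert mat[i, j] == pytest.approx(jsd(q[i], q[j]), abs=1e-9)


class TestAdjacency:
    def test_identical_nodes_complete_graph(self):
        q = np.tile(np.full(64, 1 / 64), (10, 1))
        g = build_adjacency(q, beta=0.005)
        adj = g.adj.toarray()
        assert adj.sum() == 10 * 9  # complete, zero diagonal
        # complete graph: every entry of the normalised propagator is 1/n
        np.testing.assert_allclose(g.a_hat.toarray(), 1 / 10)

    def test_tiny_beta_isolates(self, rng):
        q = rng.random((8, 64))
        q /= q.sum(axis=1, keepdims=True)
        g = build_adjacency(q, beta=1e-12)
        assert g.adj.nnz == 0
        np.testing.assert_allclose(g.a_hat.toarray(), np.eye(8))

    def test_matches_brute_force_loop(self, rng):
        q = rng.random((60, 64)) ** 3
        q /= q.sum(axis=1, keepdims=True)
        beta = 0.05
        g = build_adjacency(q, beta)
        expected = np.zeros((60, 60))
        for i in range(60):
            for j in range(60):
                if i != j and jsd(q[i], q[j]) < beta:
                    expected[i, j] = 1
        np.testing.assert_array_equal(g.adj.toarray(), expected)
        a_hat = g.a_hat.toarray()
        np.testing.assert_allclose(a_hat, a_hat.T, atol=1e-12)
        assert np.all(a_hat >= 0)

    def test_invalid_beta(self, rng):
        q = rng.random((4, 64))
        q /= q.sum(axis=1, keepdims=True)
        with pytest.raises(ValueError):
            build_adjacency(q, 0.0)


def two_node_graph():
    adj = sparse.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
    a_hat = sparse.csr_matrix(np.full((2, 2), 0.5))
    return GraphStructure(adj=adj, a_hat=a_hat, beta=1.0)


class TestGCNForward:
    def test_rows_stochastic_any_weights(self, rng):
        n, k = 12, 192
        feats = NodeFeatures(matrix=rng.random((n, k)), grid_shape=(3, 4))
        hists = rng.random((n, 64))
        hists /= hists.sum(axis=1, keepdims=True)
        graph = build_adjacency(hists, beta=0.1)
        model = GCNModel.init(k, GCNConfig(seed=3))
        z = gcn_forward(feats, graph, model)
        assert z.shape == (n, 2)
        np.testing.assert_allclose(z.sum(axis=1), 1.0, atol=1e-5)

    def test_dimension_chain(self, rng):
        cfg = GCNConfig(hidden=(5, 3), n_classes=2)
        model = GCNModel.init(7, cfg)
        assert [w.shape for w in model.weights] == [(7, 5), (5, 3), (3, 2)]
        feats = NodeFeatures(matrix=rng.random((4, 7)), grid_shape=(2, 2))
        hists = np.tile(np.full(64, 1 / 64), (4, 1))
        z = gcn_forward(feats, build_adjacency(hists, 0.01), model)
        assert z.shape == (4, 2)

    def test_single_node_zero_weights_uniform(self):
        graph = GraphStructure(
            adj=sparse.csr_matrix((1, 1)), a_hat=sparse.identity(1, format="csr"), beta=1.0
        )
        model = GCNModel(
            weights=[np.zeros((3, 4)), np.zeros((4, 4)), np.zeros((4, 2))],
            config=GCNConfig(),
        )
        z = gcn_forward(NodeFeatures(np.ones((1, 3)), (1, 1)), graph, model)
        np.testing.assert_allclose(z, [[0.5, 0.5]])

    def test_two_node_hand_computed(self):
        """Frozen hand computation of the 3-layer propagation on 2 nodes.

        A_hat = [[.5,.5],[.5,.5]]; X = [[0.2,0],[0,0.4]];
        A_hat X = [[.1,.2],[.1,.2]]; after W0=[[1,2],[3,4]] -> [0.7, 1.0];
        propagate, W1=[[1,0],[1,-1]] -> [1.7, -1.0] -> ReLU [1.7, 0];
        propagate, W2=[[2,-1],[0,1]] -> logits [3.4, -1.7];
        softmax -> [0.993940, 0.006060] on both rows.
        """
        model = GCNModel(
            weights=[
                np.array([[1.0, 2.0], [3.0, 4.0]]),
                np.array([[1.0, 0.0], [1.0, -1.0]]),
                np.array([[2.0, -1.0], [0.0, 1.0]]),
            ],
            config=GCNConfig(hidden=(2, 2)),
        )
        feats = NodeFeatures(np.array([[0.2, 0.0], [0.0, 0.4]]), (2, 1))
        z = gcn_forward(feats, two_node_graph(), model)
        np.testing.assert_allclose(
            z, [[0.993940, 0.006060], [0.993940, 0.006060]], atol=1e-5
        )


def clustered_fixture(rng, n_per=30, flip_frac=0.1):
    """Two feature clusters with point-mass-like histograms and noisy labels.

    Cluster means differ in direction, not just scale: the bias-free GCN is
    positively homogeneous, so parallel feature vectors are inseparable for
    it (colour classes differ in channel ratios, which this mimics).
    """
    mean0 = np.tile([0.8, 0.2], 4)
    mean1 = np.tile([0.2, 0.8], 4)
    f0 = mean0 + rng.normal(0, 0.01, size=(n_per, 8))
    f1 = mean1 + rng.normal(0, 0.01, size=(n_per, 8))
    feats = NodeFeatures(np.vstack([f0, f1]), (n_per, 2))
    hists = np.zeros((2 * n_per, 64))
    hists[:n_per, 10] = 0.9
    hists[:n_per, 11] = 0.1
    hists[n_per:, 50] = 0.9
    hists[n_per:, 51] = 0.1
    jitter = rng.uniform(0, 1e-4, size=hists.shape)
    hists = (hists + jitter) / (hists + jitter).sum(axis=1, keepdims=True)
    clean = np.repeat([0, 1], n_per)
    noisy = clean.copy()
    flips = rng.choice(2 * n_per, int(flip_frac * 2 * n_per), replace=False)
    noisy[flips] = 1 - noisy[flips]
    return feats, hists, clean, noisy


class TestTrainGCN:
    def test_recovers_clean_labels_under_noise(self, rng):
        feats, hists, clean, noisy = clustered_fixture(rng)
        graph = build_adjacency(hists, beta=0.01)
        cfg = GCNConfig(hidden=(16, 8), seed=0)
        model = train_gcn(feats, graph, noisy, cfg)
        pred = gcn_forward(feats, graph, model).argmax(axis=1)
        assert np.mean(pred == clean) >= 0.95

    def test_loss_decreases(self, rng):
        from canopy_wsss._nnet import cross_entropy

        feats, hists, clean, noisy = clustered_fixture(rng)
        graph = build_adjacency(hists, beta=0.01)
        cfg = GCNConfig(hidden=(16, 8), seed=0)
        onehot = np.eye(2)[noisy]
        z0 = gcn_forward(feats, graph, GCNModel.init(8, cfg))
        model = train_gcn(feats, graph, noisy, cfg)
        z1 = gcn_forward(feats, graph, model)
        assert cross_entropy(z1, onehot) <= cross_entropy(z0, onehot)

    def test_single_class_labels_passthrough(self, rng):
        feats, hists, _, _ = clustered_fixture(rng)
        graph = build_adjacency(hists, beta=0.01)
        cfg = GCNConfig(hidden=(16, 8), seed=0)
        model = train_gcn(feats, graph, np.zeros(feats.n_nodes, int), cfg)
        init = GCNModel.init(8, cfg)
        for w_trained, w_init in zip(model.weights, init.weights):
            np.testing.assert_array_equal(w_trained, w_init)


class TestPseudoLabels:
    def test_threshold(self):
        labels = make_pseudo_labels(np.array([0.1, 0.5, 0.9]))
        np.testing.assert_array_equal(labels, [0, 1, 1])

    def test_doubling_admits_next_most_probable(self):
        probs = np.array([0.9, 0.8, 0.4, 0.3, 0.2, 0.1])
        labels = make_pseudo_labels(probs, double_positives=True)
        np.testing.assert_array_equal(labels, [1, 1, 1, 1, 0, 0])


class TestRefine:
    def test_zero_epochs_is_passthrough(self, rng):
        nodes = make_node_grid(rng)
        refined = refine(nodes, GCNConfig(max_epochs=0))
        np.testing.assert_array_equal(refined.probs, nodes.probs)

    def test_isolated_positive_pulled_toward_neighbors(self):
        """A lone positive node among identical, connected negatives loses
        its positive score: the graph context overrides the noisy label."""
        images = np.full((3, 3, 8, 8, 3), 0.5)
        probs = np.zeros((3, 3))
        probs[1, 1] = 1.0
        nodes = NodeGrid(images=images, probs=probs)
        refined = refine(nodes, GCNConfig(hidden=(32, 16), beta=0.01, seed=0))
        assert refined.probs[1, 1] < probs[1, 1]
        assert refined.probs[1, 1] < 0.5

    def test_edgeless_graph_fits_labels_per_node(self, rng):
        """With no edges and separable features the GCN reproduces the
        pseudo-labels' one-hot probabilities node by node."""
        images = np.empty((2, 4, 8, 8, 3))
        probs = np.zeros((2, 4))
        for r in range(2):
            for c in range(4):
                positive = (r + c) % 2 == 0
                images[r, c] = [0.6, 0.4, 0.15] if positive else [0.2, 0.65, 0.3]
                images[r, c] += rng.normal(0, 0.005, size=(8, 8, 3))
                probs[r, c] = 0.95 if positive else 0.05
        nodes = NodeGrid(images=np.clip(images, 0, 1), probs=probs)
        refined = refine(nodes, GCNConfig(hidden=(32, 16), beta=1e-9, seed=0))
        np.testing.assert_allclose(refined.probs, probs.round(), atol=0.1)

    def test_deterministic_under_seed(self, rng):
        nodes = make_node_grid(rng, (4, 4))
        cfg = GCNConfig(hidden=(8, 4), seed=11, max_epochs=30)
        a = refine(nodes, cfg)
        b = refine(nodes, cfg)
        np.testing.assert_array_equal(a.probs, b.probs)
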