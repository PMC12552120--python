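"""Attention convolution correctness, autodiff gradients and training loop."""

import numpy as np
import pytest

from gems.fixtures import make_toy_graphs
from gems.graphs import InteractionGraph
from gems.nn import (
    GEMSModel,
    GraphBatch,
    ModelConfig,
    NodeConv,
    Tensor,
    TrainConfig,
    ensemble_predict,
    rmse_loss,
    train_cv,
    train_model,
)
from gems.nn.layers import AttentionHead, EdgeConv, GlobalUpdate


def _graph_with_self_loops(n_nodes, undirected_edges):
    src, dst = [], []
    for i, j in undirected_edges:
        src += [i, j]
        dst += [j, i]
    src += list(range(n_nodes))
    dst += list(range(n_nodes))
    return np.asarray([src, dst], dtype=np.int64)


def brute_force_attention_update(x, edge_index, theta_s, theta_t, att, slope=0.2):
    """Direct per-node evaluation of the attention update equations."""
    n = x.shape[0]
    src, dst = edge_index
    neighbours = {i: [] for i in range(n)}
    for s, d in zip(src, dst):
        if s != d:
            neighbours[d].append(s)
    out = np.zeros((n, theta_s.shape[1]))
    for i in range(n):
        members = neighbours[i] + [i]
        scores = []
        for k in members:
            z = theta_s.T @ x[i] + theta_t.T @ x[k]
            z = np.where(z > 0, z, slope * z)
            scores.append(float(att[:, 0] @ z))
        weights = np.exp(scores - np.max(scores))
        weights = weights / weights.sum()
        alpha = dict(zip(members, weights))
        out[i] = alpha[i] * (theta_s.T @ x[i])
        for j in neighbours[i]:
            out[i] += alpha[j] * (theta_t.T @ x[j])
    return out


class TestAttention:
    def test_isolated_node_attention_is_one(self):
        head = AttentionHead(3, 2, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).standard_normal((1, 3)))
        edge_index = np.asarray([[0], [0]])
        alpha = head.attention(x, edge_index, None)
        assert alpha.data[0, 0] == pytest.approx(1.0)

    def test_identical_neighbours_share_attention_equally(self):
        head = AttentionHead(3, 2, np.random.default_rng(0))
        row = np.random.default_rng(2).standard_normal(3)
        x = Tensor(np.stack([row, row, row]))
        edge_index = _graph_with_self_loops(3, [(0, 1), (0, 2)])
        alpha = head.attention(x, edge_index, None)
        incoming_to_0 = alpha.data[edge_index[1] == 0, 0]
        assert np.allclose(incoming_to_0, 1.0 / 3.0, atol=1e-12)

    def test_attention_sums_to_one_per_node(self, rng):
        head = AttentionHead(4, 3, np.random.default_rng(5))
        x = Tensor(rng.standard_normal((6, 4)))
        edge_index = _graph_with_self_loops(6, [(0, 1), (1, 2), (2, 3), (3, 4), (1, 5)])
        alpha = head.attention(x, edge_index, None)
        sums = np.zeros(6)
        np.add.at(sums, edge_index[1], alpha.data[:, 0])
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_node_update_matches_brute_force(self, rng):
        conv = NodeConv(4, 3, heads=1, rng=np.random.default_rng(9))
        head = conv.heads[0]
        x_data = rng.standard_normal((5, 4))
        edge_index = _graph_with_self_loops(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        out = conv(Tensor(x_data), edge_index).data
        expected = brute_force_attention_update(
            x_data, edge_index, head.theta_s.data, head.theta_t.data, head.att.data
        )
        assert np.allclose(out, expected, atol=1e-6)

    def test_zero_weights_give_zero_update(self):
        conv = NodeConv(3, 2, heads=1, rng=np.random.default_rng(0))
        for p in conv.parameters():
            p.data[:] = 0.0
        x = Tensor(np.ones((3, 3)))
        out = conv(x, _graph_with_self_loops(3, [(0, 1)]))
        assert np.allclose(out.data, 0.0)

    def test_isolated_node_identity_transform(self):
        conv = NodeConv(3, 3, heads=1, rng=np.random.default_rng(0))
        head = conv.heads[0]
        head.theta_s.data = np.eye(3)
        x_data = np.array([[0.3, -1.2, 0.7]])
        out = conv(Tensor(x_data), np.asarray([[0], [0]]))
        assert np.allclose(out.data, x_data, atol=1e-12)


class TestEdgeConv:
    def test_permutation_equivariance_and_direct_evaluation(self, rng):
        conv = EdgeConv(node_dim=3, edge_dim=2, n_out=4, rng=np.random.default_rng(1))
        x = Tensor(rng.standard_normal((4, 3)))
        edge_index = np.asarray([[0, 1, 2, 3], [1, 2, 3, 0]])
        edge_attr = Tensor(rng.standard_normal((4, 2)))
        out = conv(x, edge_index, edge_attr).data
        perm = np.array([2, 0, 3, 1])
        out_perm = conv(x, edge_index[:, perm], Tensor(edge_attr.data[perm])).data
        assert np.allclose(out_perm, out[perm], atol=1e-12)
        # direct two-layer evaluation
        stacked = np.concatenate(
            [x.data[edge_index[0]], x.data[edge_index[1]], edge_attr.data], axis=1
        )
        hidden = stacked @ conv.fc1.weight.data + conv.fc1.bias.data
        hidden = np.maximum(hidden, 0.0)
        assert np.allclose(
            out, hidden @ conv.fc2.weight.data + conv.fc2.bias.data, atol=1e-12
        )


class TestGlobalUpdate:
    def test_single_node_pooling(self, rng):
        upd = GlobalUpdate(global_dim=2, node_dim=3, rng=np.random.default_rng(0))
        g = Tensor(rng.standard_normal((1, 2)))
        x = Tensor(rng.standard_normal((1, 3)))
        out = upd(g, x, np.array([0]), 1).data
        direct = np.concatenate([g.data, x.data], axis=1) @ upd.fc.weight.data + upd.fc.bias.data
        assert np.allclose(out, np.maximum(direct, 0.0), atol=1e-12)

    def test_duplicating_nodes_keeps_mean_pool(self, rng):
        upd = GlobalUpdate(global_dim=2, node_dim=3, rng=np.random.default_rng(0))
        g = Tensor(rng.standard_normal((1, 2)))
        x_data = rng.standard_normal((3, 3))
        once = upd(g, Tensor(x_data), np.zeros(3, dtype=int), 1).data
        twice = upd(g, Tensor(np.vstack([x_data, x_data])), np.zeros(6, dtype=int), 1).data
        assert np.allclose(once, twice, atol=1e-12)


def _tiny_graph(seed=0, label=5.0):
    rng = np.random.default_rng(seed)
    return InteractionGraph(
        id=f"tiny{seed}",
        node_features=rng.standard_normal((3, 4)),
        edge_index=_graph_with_self_loops(3, [(0, 1), (1, 2)]),
        edge_features=rng.standard_normal((7, 3)),
        global_features=rng.standard_normal(2),
        node_roles=np.zeros(3, dtype=np.int64),
        label=label,
    )


TINY_CONFIG = ModelConfig(node_in=4, edge_in=3, global_in=2,
                          hidden=4, heads=2, head_hidden=4, dropout=0.0)


class TestForward:
    def test_deterministic_without_dropout(self):
        model = GEMSModel(TINY_CONFIG, seed=1)
        graph = _tiny_graph()
        a = model.predict([graph])
        b = model.predict([graph])
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))

    def test_batch_equals_per_graph(self):
        model = GEMSModel(TINY_CONFIG, seed=1)
        graphs = [_tiny_graph(seed=s) for s in range(4)]
        batched = model.predict(graphs)
        singles = np.concatenate([model.predict([g]) for g in graphs])
        assert np.allclose(batched, singles, atol=1e-10)

    def test_ablated_graph_accepted(self):
        from gems.graphs import ablate_protein

        graphs = make_toy_graphs(3, seed=0)
        model = GEMSModel(ModelConfig(node_in=10, edge_in=6, global_in=4,
                                      hidden=8, heads=2, head_hidden=8), seed=0)
        out = model.predict([ablate_protein(g) for g in graphs])
        assert out.shape == (3,) and np.all(np.isfinite(out))

    def test_schema_mismatch_rejected(self):
        model = GEMSModel(TINY_CONFIG, seed=1)
        bad = _tiny_graph()
        bad.node_features = np.zeros((3, 9))
        with pytest.raises(ValueError, match="width"):
            model.predict([bad])


def finite_difference_worst_error(model, batch, per_param=4, seed=0):
    """Worst |FD - backprop| over sampled coordinates, skipping coordinates
    where two step sizes disagree (the loss has a ReLU/LeakyReLU kink there,
    so a finite difference is not an estimate of the one-sided gradient)."""
    params = model.parameters()
    for p in params:
        p.grad = None
    loss = rmse_loss(model.forward(batch), batch.y)
    loss.backward()
    rng = np.random.default_rng(seed)
    worst = 0.0
    checked = 0
    for p in params:
        flat = p.data.reshape(-1)
        grad = p.grad.reshape(-1) if p.grad is not None else np.zeros_like(flat)
        for idx in rng.choice(flat.size, size=min(per_param, flat.size), replace=False):
            original = flat[idx]

            def fd(eps):
                flat[idx] = original + eps
                up = rmse_loss(model.forward(batch), batch.y).data
                flat[idx] = original - eps
                down = rmse_loss(model.forward(batch), batch.y).data
                flat[idx] = original
                return (up - down) / (2 * eps)

            estimate, check = fd(1e-6), fd(2e-6)
            if abs(estimate - check) > 1e-6:
                continue  # non-smooth point
            worst = max(worst, abs(estimate - grad[idx]))
            checked += 1
    assert checked > 0
    return worst


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        model = GEMSModel(TINY_CONFIG, seed=3)
        batch = GraphBatch.from_graphs([_tiny_graph(seed=7)])
        assert finite_difference_worst_error(model, batch) < 1e-4


class TestTraining:
    def test_constant_labels_early_stop_to_mean(self):
        graphs = make_toy_graphs(20, seed=1)
        for g in graphs:
            g.label = 6.0
        config = ModelConfig(node_in=10, edge_in=6, global_in=4,
                             hidden=8, heads=2, head_hidden=8, dropout=0.0)
        model = GEMSModel(config, seed=0)
        result = train_model(
            model, graphs[:16], graphs[16:],
            TrainConfig(max_epochs=300, patience=1, learning_rate=0.02, seed=0,
                        dropout_in_training=False),
        )
        assert result.epochs_run <= 300
        preds = model.predict(graphs[16:])
        assert np.allclose(preds, 6.0, atol=0.2)

    def test_same_seed_reproduces_folds_and_history(self):
        graphs = make_toy_graphs(20, seed=2)
        config = ModelConfig(node_in=10, edge_in=6, global_in=4,
                             hidden=8, heads=2, head_hidden=8, dropout=0.0)
        train_config = TrainConfig(folds=2, max_epochs=5, patience=5,
                                   seed=11, dropout_in_training=False)
        first = train_cv(graphs, config, train_config)
        second = train_cv(graphs, config, train_config)
        for a, b in zip(first, second):
            assert a.history == b.history

    def test_dataset_too_small_rejected(self):
        graphs = make_toy_graphs(5, seed=0)
        config = ModelConfig(node_in=10, edge_in=6, global_in=4)
        with pytest.raises(ValueError, match="too small"):
            train_cv(graphs, config, TrainConfig(folds=5))


class TestEnsemble:
    def test_copies_equal_single_model(self):
        model = GEMSModel(TINY_CONFIG, seed=2)
        graphs = [_tiny_graph(seed=s) for s in range(3)]
        single = model.predict(graphs)
        assert np.allclose(ensemble_predict([model] * 5, graphs), single, atol=1e-12)

    def test_mean_of_model_outputs(self):
        graphs = [_tiny_graph()]
        models = [GEMSModel(TINY_CONFIG, seed=s) for s in range(5)]
        preds = [m.predict(graphs)[0] for m in models]
        assert ensemble_predict(models, graphs)[0] == pytest.approx(np.mean(preds))

    def test_empty_graph_list(self):
        model = GEMSModel(TINY_CONFIG, seed=2)
        assert ensemble_predict([model], []).size == 0
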