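"""GNN cores: oracle equivalence, equivariance, loss, optimiser, init."""

import numpy as np
import pytest

from alngraph import gnn_core as gc
from alngraph.gnn_core import (
    AdamState, ModelConfig, ModelError, adam_step, gat_attention, gat_forward,
    gcn_forward, gin_forward, init_adam_state, init_params, load_checkpoint,
    loss_and_grads, normalize_adjacency, propagation_matrix, save_checkpoint,
    softmax_cross_entropy,
)


def leaky(z, s=0.2):
    return z if z > 0 else s * z


def gcn_loop_oracle(A_hat, X, params, config):
    """Explicit per-node message-passing recomputation of the GCN stack."""
    n = A_hat.shape[0]
    H = X.copy()
    for l in range(config.n_layers):
        W, b = params[f"W{l}"], params[f"b{l}"]
        out = np.zeros((n, W.shape[1]))
        for i in range(n):
            m = sum(A_hat[i, j] * H[j] for j in range(n))
            z = m @ W + b
            out[i] = np.maximum(z, 0) if l < config.n_layers - 1 else z
        H = out
    return H


def gat_loop_oracle(A, X, params, config):
    """Explicit attention recomputation over closed neighbourhoods."""
    n = A.shape[0]
    H = X.copy()
    for l in range(config.n_layers):
        W, a = params[f"W{l}"], params[f"a{l}"]
        do = W.shape[1]
        Z = H @ W
        out = np.zeros((n, do))
        for i in range(n):
            nbrs = [j for j in range(n) if A[i, j] > 0 or j == i]
            e = [leaky(a[:do] @ Z[i] + a[do:] @ Z[j], config.leaky_slope)
                 for j in nbrs]
            e = np.asarray(e)
            alpha = np.exp(e - e.max())
            alpha /= alpha.sum()
            h = sum(w * Z[j] for w, j in zip(alpha, nbrs))
            out[i] = np.maximum(h, 0) if l < config.n_layers - 1 else h
        H = out
    return H


def gin_loop_oracle(A, X, params, config):
    """Explicit sum-aggregation + MLP recomputation of the GIN stack."""
    n = A.shape[0]
    H = X.copy()
    for l in range(config.n_layers):
        eps = float(params[f"eps{l}"])
        out = []
        for i in range(n):
            p = (1 + eps) * H[i] + sum(H[j] for j in range(n) if A[i, j] > 0)
            u = np.maximum(p @ params[f"Wa{l}"] + params[f"ba{l}"], 0)
            out.append(u @ params[f"Wb{l}"] + params[f"bb{l}"])
        H = np.asarray(out)
    return H @ params["W_out"] + params["b_out"]


class TestNormalizeAdjacency:
    def test_edgeless_graph_gives_identity(self):
        assert np.allclose(normalize_adjacency(np.zeros((4, 4))), np.eye(4))

    def test_two_node_single_edge(self):
        A = np.array([[0.0, 1], [1, 0]])
        assert np.allclose(normalize_adjacency(A), 0.5 * np.ones((2, 2)))

    def test_symmetric_output(self, toy_graph):
        A, _, _ = toy_graph
        A_hat = normalize_adjacency(A)
        assert np.abs(A_hat - A_hat.T).max() < 1e-12

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ModelError):
            normalize_adjacency(np.eye(3))


class TestForwardOracles:
    def test_gcn_matches_loop_oracle_on_path_graph(self):
        n, d = 4, 3
        A = np.zeros((n, n))
        for i in range(n - 1):
            A[i, i + 1] = A[i + 1, i] = 1.0
        rng = np.random.default_rng(2)
        X = rng.normal(size=(n, d))
        cfg = ModelConfig("gcn", init_seed=4, hidden_dim=5)
        params = init_params(cfg, d)
        A_hat = normalize_adjacency(A)
        assert np.abs(gcn_forward(A_hat, X, params, cfg)
                      - gcn_loop_oracle(A_hat, X, params, cfg)).max() < 1e-10

    def test_gcn_edgeless_reduces_to_rowwise_mlp(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 3))
        cfg = ModelConfig("gcn", init_seed=1, hidden_dim=4)
        params = init_params(cfg, 3)
        logits = gcn_forward(np.eye(5), X, params, cfg)
        mlp = np.maximum(X @ params["W0"] + params["b0"], 0) @ params["W1"] + params["b1"]
        assert np.abs(logits - mlp).max() < 1e-12

    def test_gat_matches_loop_oracle(self, toy_graph):
        A, X, _ = toy_graph
        cfg = ModelConfig("gat", init_seed=5, hidden_dim=5)
        params = init_params(cfg, X.shape[1])
        assert np.abs(gat_forward(A, X, params, cfg)
                      - gat_loop_oracle(A, X, params, cfg)).max() < 1e-10

    def test_gat_attention_rows_sum_to_one(self, toy_graph):
        A, X, _ = toy_graph
        cfg = ModelConfig("gat", init_seed=5)
        params = init_params(cfg, X.shape[1])
        alpha = gat_attention(A, X, params, cfg, layer=0)
        assert np.abs(alpha.sum(axis=1) - 1.0).max() < 1e-12
        # support is the closed neighbourhood
        assert np.all((alpha > 0) == ((A + np.eye(len(A))) > 0))

    def test_gat_zero_attention_is_mean_aggregation(self, toy_graph):
        A, X, _ = toy_graph
        cfg = ModelConfig("gat", n_layers=1, init_seed=6)
        params = init_params(cfg, X.shape[1])
        params["a0"] = np.zeros_like(params["a0"])
        logits = gat_forward(A, X, params, cfg)
        Z = X @ params["W0"]
        M = A + np.eye(len(A))
        mean_pool = (M / M.sum(axis=1, keepdims=True)) @ Z
        assert np.abs(logits - mean_pool).max() < 1e-12

    def test_gat_singleton_node_self_attention(self):
        cfg = ModelConfig("gat", n_layers=1, init_seed=7)
        X = np.array([[1.0, -2.0]])
        params = init_params(cfg, 2)
        alpha = gat_attention(np.zeros((1, 1)), X, params, cfg)
        assert alpha[0, 0] == pytest.approx(1.0)
        logits = gat_forward(np.zeros((1, 1)), X, params, cfg)
        assert np.abs(logits - X @ params["W0"]).max() < 1e-12

    def test_gin_matches_loop_oracle(self, toy_graph):
        A, X, _ = toy_graph
        cfg = ModelConfig("gin", init_seed=8, hidden_dim=5)
        params = init_params(cfg, X.shape[1])
        params["eps0"] = np.asarray(0.3)
        assert np.abs(gin_forward(A, X, params, cfg)
                      - gin_loop_oracle(A, X, params, cfg)).max() < 1e-10

    def test_gin_edgeless_reduces_to_rowwise_mlp(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(4, 3))
        cfg = ModelConfig("gin", n_layers=1, init_seed=10, hidden_dim=6)
        params = init_params(cfg, 3)
        logits = gin_forward(np.zeros((4, 4)), X, params, cfg)
        V = np.maximum(X @ params["Wa0"] + params["ba0"], 0)
        mlp = (V @ params["Wb0"] + params["bb0"]) @ params["W_out"] + params["b_out"]
        assert np.abs(logits - mlp).max() < 1e-12

    def test_sum_aggregation_distinguishes_where_mean_collides(self):
        """Degree-different neighbourhoods with identical means: the GIN
        sum aggregate separates them, mean aggregation does not."""
        X = np.ones((4, 1))
        A_path = np.zeros((4, 4))           # 0-1-2 path, node 3 isolated
        A_path[0, 1] = A_path[1, 0] = A_path[1, 2] = A_path[2, 1] = 1.0
        A_edge = np.zeros((4, 4))           # single 0-1 edge
        A_edge[0, 1] = A_edge[1, 0] = 1.0
        eps = 0.0
        sum_path = (1 + eps) * X[1] + A_path[1] @ X
        sum_edge = (1 + eps) * X[1] + A_edge[1] @ X
        assert sum_path != sum_edge          # sums: 3 vs 2
        M1 = (A_path + np.eye(4))[1]
        M2 = (A_edge + np.eye(4))[1]
        mean_path = (M1 @ X) / M1.sum()
        mean_edge = (M2 @ X) / M2.sum()
        assert mean_path == mean_edge        # means collide at 1

    @pytest.mark.parametrize("arch", ["gcn", "gat", "gin"])
    def test_permutation_equivariance(self, toy_graph, arch):
        A, X, _ = toy_graph
        cfg = ModelConfig(arch, init_seed=11)
        params = init_params(cfg, X.shape[1])
        mat = propagation_matrix(A, cfg)
        logits = gc.model_forward(mat, X, params, cfg)
        rng = np.random.default_rng(12)
        perm = rng.permutation(len(A))
        mat_p = propagation_matrix(A[np.ix_(perm, perm)], cfg)
        logits_p = gc.model_forward(mat_p, X[perm], params, cfg)
        assert np.abs(logits_p - logits[perm]).max() < 1e-10

    def test_gcn_isolated_node_leaves_other_rows_unchanged(self, toy_graph):
        A, X, _ = toy_graph
        cfg = ModelConfig("gcn", init_seed=13)
        params = init_params(cfg, X.shape[1])
        logits = gcn_forward(normalize_adjacency(A), X, params, cfg)
        n = len(A)
        A2 = np.zeros((n + 1, n + 1))
        A2[:n, :n] = A
        X2 = np.vstack([X, np.zeros(X.shape[1])])
        logits2 = gcn_forward(normalize_adjacency(A2), X2, params, cfg)
        assert np.abs(logits2[:n] - logits).max() < 1e-12

    def test_feature_width_mismatch_raises(self, toy_graph):
        A, X, _ = toy_graph
        cfg = ModelConfig("gcn", init_seed=1)
        params = init_params(cfg, X.shape[1] + 2)
        with pytest.raises(ModelError, match="d_in"):
            gcn_forward(normalize_adjacency(A), X, params, cfg)


class TestLoss:
    def test_uniform_logits_loss_is_ln2(self):
        logits = np.zeros((7, 2))
        Y = np.tile([1.0, 0.0], (7, 1))
        loss, _ = softmax_cross_entropy(logits, Y)
        assert loss == pytest.approx(np.log(2.0), abs=1e-12)

    def test_saturated_correct_logits_near_zero_loss(self):
        Y = np.tile([0.0, 1.0], (5, 1))
        logits = np.tile([0.0, 30.0], (5, 1))
        loss, _ = softmax_cross_entropy(logits, Y)
        assert loss < 1e-9

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(14)
        logits = rng.normal(size=(5, 2))
        labels = rng.integers(0, 2, 5)
        Y = np.zeros((5, 2))
        Y[np.arange(5), labels] = 1.0
        _, grad = softmax_cross_entropy(logits, Y)
        h = 1e-6
        for i in range(5):
            for c in range(2):
                lp, lm = logits.copy(), logits.copy()
                lp[i, c] += h
                lm[i, c] -= h
                num = (softmax_cross_entropy(lp, Y)[0]
                       - softmax_cross_entropy(lm, Y)[0]) / (2 * h)
                assert grad[i, c] == pytest.approx(num, abs=1e-6)


class TestAdam:
    def test_zero_gradient_leaves_parameters_unchanged(self):
        params = {"w": np.array([1.0, -2.0])}
        state = init_adam_state(params, lr=0.1)
        new, _ = adam_step(params, {"w": np.zeros(2)}, state)
        assert np.array_equal(new["w"], params["w"])

    def test_constant_gradient_update_magnitude_approaches_lr(self):
        """With a constant gradient, bias-corrected Adam's step size
        converges to the learning rate (sign-like normalisation)."""
        lr = 0.01
        params = {"w": np.array(0.0)}
        grads = {"w": np.array(0.37)}
        state = init_adam_state(params, lr=lr)
        for _ in range(1000):
            prev = params["w"].copy()
            params, state = adam_step(params, grads, state)
        assert abs(abs(params["w"] - prev) - lr) < 0.01 * lr

    def test_quadratic_bowl_minimisation(self):
        params = {"x": np.array(1.0)}
        state = init_adam_state(params, lr=0.01)
        for step in range(5000):
            params, state = adam_step(params, {"x": params["x"].copy()}, state)
            if abs(params["x"]) < 1e-3:
                break
        assert abs(params["x"]) < 1e-3


class TestInit:
    @pytest.mark.parametrize("arch", ["gcn", "gat", "gin"])
    def test_same_seed_identical_parameters(self, arch):
        cfg = ModelConfig(arch, init_seed=21)
        p1 = init_params(cfg, 7)
        p2 = init_params(cfg, 7)
        assert p1.keys() == p2.keys()
        for k in p1:
            assert np.array_equal(p1[k], p2[k])

    def test_glorot_scale_statistics(self):
        cfg = ModelConfig("gcn", hidden_dim=100, init_seed=22)
        W = init_params(cfg, 200)["W0"]
        limit = np.sqrt(6.0 / (200 + 100))
        assert abs(W.std() - limit / np.sqrt(3.0)) < 0.1 * limit / np.sqrt(3.0)
        assert np.abs(W).max() <= limit

    def test_checkpoint_round_trip(self, tmp_path, toy_graph):
        A, X, _ = toy_graph
        cfg = ModelConfig("gin", init_seed=23)
        params = init_params(cfg, X.shape[1])
        path = tmp_path / "ckpt.json"
        save_checkpoint(path, params, cfg)
        params2, cfg2 = load_checkpoint(path)
        assert cfg2 == cfg
        for k in params:
            assert np.allclose(params[k], params2[k], atol=0, rtol=0)


@pytest.mark.parametrize("arch", ["gcn", "gat", "gin"])
def test_minibatch_loss_restricts_gradient_support(toy_graph, arch):
    """Restricting the loss to a node subset changes gradients but keeps
    them finite and nonzero; full-graph forward still used."""
    A, X, Y = toy_graph
    cfg = ModelConfig(arch, init_seed=30)
    params = init_params(cfg, X.shape[1])
    mat = propagation_matrix(A, cfg)
    loss_full, grads_full, _ = loss_and_grads(mat, X, Y, params, cfg)
    loss_sub, grads_sub, _ = loss_and_grads(mat, X, Y, params, cfg,
                                            node_idx=np.array([0, 1]))
    assert np.isfinite(loss_sub) and loss_sub != loss_full
    key = next(iter(grads_sub))
    assert np.any(grads_sub[key] != grads_full[key])
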