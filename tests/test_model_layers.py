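"""Layer-by-layer checks of the graph model against brute-force oracles."""

import numpy as np
import pytest

import oracles
from connpool.autodiff import Tensor, leaky_relu
from connpool.model import (
    ModelConfig,
    PooledGraphState,
    attention_scores,
    e2e_forward,
    e2n_forward,
    embed_adjacency,
    forward_batch,
    gcn_forward,
    load_checkpoint,
    model_forward,
    readout,
    save_checkpoint,
    topk_indices,
    topk_pool,
)
from connpool.trainer import init_params


def test_leaky_relu_slope_third():
    vals = [(2.0, 2.0), (-3.0, -1.0), (0.0, 0.0)]
    for x, expect in vals:
        assert leaky_relu(Tensor(np.array(x)), 1.0 / 3.0).data == pytest.approx(expect)


class TestE2E:
    def test_hand_example_all_ones_kernels(self):
        f = np.array([[[0.0, 1.0], [1.0, 0.0]]])  # (1, 2, 2)
        r = np.ones((1, 2, 1))
        c = np.ones((1, 2, 1))
        out = e2e_forward(f, r, c).data
        np.testing.assert_allclose(out, np.full((1, 2, 2), 2.0))

    def test_zero_input_zero_output(self):
        out = e2e_forward(np.zeros((2, 4, 4)), np.ones((2, 4, 3)),
                          np.ones((2, 4, 3))).data
        assert np.all(out == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.standard_normal((2, 5, 5))
        r = rng.standard_normal((2, 5, 3))
        c = rng.standard_normal((2, 5, 3))
        out = e2e_forward(f, r, c).data
        np.testing.assert_allclose(out, oracles.e2e_oracle(f, r, c), atol=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="E2E"):
            e2e_forward(np.zeros((1, 4, 4)), np.ones((2, 4, 1)), np.ones((2, 4, 1)))


class TestE2N:
    def test_hand_example_row_sums(self):
        f = np.array([[[0.0, 1.0], [1.0, 0.0]]])
        w = np.ones((1, 2, 1))
        out = e2n_forward(f, w).data
        np.testing.assert_allclose(out, np.ones((2, 1)))

    def test_zero_kernel_zero_features(self, rng):
        f = rng.standard_normal((2, 3, 3))
        assert np.all(e2n_forward(f, np.zeros((2, 3, 4))).data == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        f = rng.standard_normal((3, 6, 6))
        w = rng.standard_normal((3, 6, 2))
        np.testing.assert_allclose(e2n_forward(f, w).data,
                                   oracles.e2n_oracle(f, w), atol=1e-6)


class TestAdjacencyEmbedding:
    def test_identity_mode_nonnegativity_indicator(self):
        f1 = np.array([[0.3, -0.2], [-0.2, 0.0]])
        a = embed_adjacency(f1, None, mode="identity").data
        np.testing.assert_array_equal(a, [[1.0, 0.0], [0.0, 1.0]])

    def test_averaging_of_identical_maps_equals_map(self, rng):
        m = rng.standard_normal((4, 4))
        fl = np.stack([m, m])
        a = embed_adjacency(np.zeros((4, 4)), fl, mode="averaging").data
        expect = np.maximum((m >= 0).astype(float), (m >= 0).astype(float).T)
        np.testing.assert_array_equal(a, expect)

    def test_e2e_mode_zero_kernel_all_ones(self, rng):
        fl = rng.standard_normal((2, 3, 3))
        params = {"adj_r": np.zeros((2, 3, 1)), "adj_c": np.zeros((2, 3, 1))}
        a = embed_adjacency(np.zeros((3, 3)), fl, params, mode="e2e").data
        np.testing.assert_array_equal(a, np.ones((3, 3)))

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError, match="mode"):
            embed_adjacency(np.zeros((2, 2)), None, mode="spectral")

    def test_straight_through_passes_gradient_detach_blocks(self, rng):
        f1 = Tensor(rng.standard_normal((3, 3)), requires_grad=True)
        a = embed_adjacency(f1, None, mode="identity", grad="straight_through")
        (a * rng.standard_normal((3, 3))).sum().backward()
        assert f1.grad is not None and np.any(f1.grad != 0)
        f2 = Tensor(rng.standard_normal((3, 3)), requires_grad=True)
        a2 = embed_adjacency(f2, None, mode="identity", grad="detach")
        assert not a2.requires_grad


class TestGCN:
    def test_isolated_nodes_reduce_to_xw(self, rng):
        x = rng.standard_normal((2, 3))
        w = rng.standard_normal((3, 2))
        out = gcn_forward(x, np.zeros((2, 2)), w).data
        np.testing.assert_allclose(out, x @ w, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_path_graph_matches_matrix_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        a = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
        x = rng.standard_normal((3, 4))
        w = rng.standard_normal((4, 2))
        np.testing.assert_allclose(gcn_forward(x, a, w).data,
                                   oracles.gcn_oracle(x, a, w), atol=1e-7)


class TestAttentionScores:
    def test_zero_weights_give_half(self, rng):
        x = rng.standard_normal((5, 3))
        a = (rng.random((5, 5)) > 0.5).astype(float)
        a = np.maximum(a, a.T)
        s = attention_scores(x, a, np.zeros((3, 2)), np.zeros((2, 1))).data
        np.testing.assert_allclose(s, 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_composed_gcn_oracle_and_range(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = 6
        a = (rng.random((n, n)) > 0.4).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        x = rng.standard_normal((n, 4))
        w0 = rng.standard_normal((4, 2))
        w1 = rng.standard_normal((2, 1))
        s = attention_scores(x, a, w0, w1).data
        np.testing.assert_allclose(s, oracles.attention_oracle(x, a, w0, w1),
                                   atol=1e-7)
        assert np.all((s > 0) & (s < 1))


class TestTopKPool:
    @staticmethod
    def _state(rng, n, m):
        a = (rng.random((n, n)) > 0.5).astype(float)
        a = np.maximum(a, a.T)
        return PooledGraphState(Tensor(rng.standard_normal((n, m))),
                                Tensor(a), None, np.arange(n))

    def test_half_ratio_keeps_two_of_four(self, rng):
        state = self._state(rng, 4, 3)
        out = topk_pool(state, Tensor(np.array([0.9, 0.1, 0.5, 0.2])), 0.5)
        assert out.n_nodes == 2
        np.testing.assert_array_equal(out.node_ids, [0, 2])

    @pytest.mark.parametrize("seed", range(5))
    def test_kept_set_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(400 + seed)
        n = rng.integers(4, 9)
        scores = rng.random(n)
        np.testing.assert_array_equal(topk_indices(scores, 0.5),
                                      oracles.topk_oracle(scores, 0.5))

    def test_uniform_scores_tie_break_and_residual(self, rng):
        state = self._state(rng, 4, 2)
        s = 0.7
        out = topk_pool(state, Tensor(np.full(4, s)), 0.5)
        np.testing.assert_array_equal(out.node_ids, [0, 1])  # lowest indices
        np.testing.assert_allclose(out.x.data, (1 + s) * state.x.data[:2],
                                   atol=1e-12)


class TestReadout:
    def test_singleton_mean_equals_max(self, rng):
        x = rng.standard_normal((1, 3))
        st = PooledGraphState(Tensor(x), Tensor(np.zeros((1, 1))), None,
                              np.array([0]))
        z = readout([st]).data
        np.testing.assert_allclose(z, np.concatenate([x[0], x[0]]))
        assert z.shape == (6,)  # 2 * feature width

    def test_two_layer_sum_matches_loop_oracle(self, rng):
        xs = [rng.standard_normal((4, 3)), rng.standard_normal((2, 3))]
        states = [PooledGraphState(Tensor(x), Tensor(np.zeros((len(x),) * 2)),
                                   None, np.arange(len(x))) for x in xs]
        np.testing.assert_array_equal(readout(states).data,
                                      oracles.readout_oracle(xs))

    def test_permutation_invariance_within_layer(self, rng):
        x = rng.standard_normal((5, 3))
        perm = rng.permutation(5)
        mk = lambda arr: PooledGraphState(Tensor(arr), Tensor(np.zeros((5, 5))),
                                          None, np.arange(5))
        np.testing.assert_allclose(readout([mk(x)]).data,
                                   readout([mk(x[perm])]).data, atol=1e-12)


class TestModelForward:
    def test_zero_weights_predict_zero_bias(self, rng):
        mc = ModelConfig(n=6, d=2)
        params = {k: np.zeros(s) for k, s in mc.param_shapes().items()}
        g = rng.standard_normal((6, 6))
        g = (g + g.T) / 2
        pred, _ = model_forward(g, params, mc)
        assert pred.data[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_monolithic_oracle(self, seed):
        rng = np.random.default_rng(500 + seed)
        mc = ModelConfig(n=8, d=2)
        params = {k: rng.standard_normal(s) * 0.5
                  for k, s in mc.param_shapes().items()}
        g = rng.standard_normal((8, 8))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        pred, _ = model_forward(g, params, mc)
        expect = oracles.model_oracle(g, params, n=8, d=2)
        assert abs(pred.data[0] - expect) < 1e-5

    def test_node_permutation_equivariance(self, rng):
        """Permuting nodes AND every node-indexed kernel leaves the
        prediction unchanged (the model is not permutation-invariant for
        fixed kernels, but it is equivariant)."""
        mc = ModelConfig(n=7, d=2)
        params = init_params(mc, 3)
        g = rng.standard_normal((7, 7))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        perm = rng.permutation(7)
        g_p = g[np.ix_(perm, perm)]
        params_p = {
            k: (v[:, perm, :] if k.startswith(("e2e", "adj")) or k == "e2n_w"
                else v.copy())
            for k, v in params.items()
        }
        p1, _ = model_forward(g, params, mc)
        p2, _ = model_forward(g_p, params_p, mc)
        assert abs(p1.data[0] - p2.data[0]) < 1e-6

    def test_pooled_node_counts_follow_ceiling(self, rng):
        for n in (5, 8, 11):
            mc = ModelConfig(n=n, d=2)
            params = init_params(mc, 0)
            g = rng.standard_normal((n, n))
            g = (g + g.T) / 2
            _, inter = model_forward(g, params, mc, collect=True)
            states = inter["pooled_states"][0]
            assert states[0].n_nodes == int(np.ceil(n / 2))
            assert states[1].n_nodes == int(np.ceil(np.ceil(n / 2) / 2))

    def test_finite_for_finite_inputs(self, rng):
        mc = ModelConfig(n=6, d=3, adjacency_mode="averaging")
        params = init_params(mc, 1)
        g = rng.standard_normal((6, 6)) * 100
        g = (g + g.T) / 2
        pred, _ = model_forward(g, params, mc)
        assert np.isfinite(pred.data[0])

    def test_checkpoint_round_trip(self, tmp_path, rng):
        mc = ModelConfig(n=5, d=2, adjacency_mode="e2e")
        params = init_params(mc, 9)
        path = tmp_path / "ckpt.json"
        save_checkpoint(path, params, mc)
        back, mc2 = load_checkpoint(path)
        assert mc2 == mc
        for k in params:
            np.testing.assert_array_equal(params[k], back[k])


def test_model_config_loads_from_yaml_and_json(tmp_path):
    from connpool.model import load_model_config
    (tmp_path / "cfg.yaml").write_text(
        "n: 30\nd: 8\nadjacency_mode: averaging\nmlp_sizes: [128, 64]\n")
    cfg = load_model_config(tmp_path / "cfg.yaml")
    assert (cfg.n, cfg.d, cfg.adjacency_mode) == (30, 8, "averaging")
    assert cfg.mlp_sizes == (128, 64)
    assert cfg.pool_ratio == 0.5  # defaults fill the rest
    (tmp_path / "cfg.json").write_text('{"n": 12}')
    assert load_model_config(tmp_path / "cfg.json").n == 12
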