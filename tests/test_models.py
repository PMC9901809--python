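"""Model layers against literal node-wise oracles, and parameter accounting."""

import numpy as np
import pytest

from ncgex.graph import ConnectivityMask, build_mask, degree_and_normalize
from ncgex.models import (
    GCNLayer,
    NCLayer,
    allocate_hidden,
    build_gcn_model,
    build_mlp,
    build_ncnn,
    count_parameters,
    fit_linear_regression,
    flatten,
    gcn_forward,
    nc_forward,
    ncnn_predict,
    unflatten,
)
from ncgex.simulate import generate_random_graph


# ---------------------------------------------------------------------------
# independent node-wise oracles

def nc_oracle(x, w, b, mask, act=np.tanh):
    """Literal double-loop neighbour-connection sum per node and feature."""
    n, d, h_in = x.shape
    h_out = w.shape[0]
    out = np.zeros((n, d, h_out))
    for s in range(n):
        for i in range(d):
            for m in range(h_out):
                z = b[i, m]
                for k in range(h_in):
                    for j in range(d):
                        if mask[i, j]:
                            z += w[m, k, i, j] * x[s, j, k]
                out[s, i, m] = act(z)
    return out


def gcn_oracle(x, w1, w2, graph, act=np.tanh):
    """Node-wise normalized-neighbourhood sum: neighbour path + self paths."""
    deg, _ = degree_and_normalize(graph)
    n, d, _ = x.shape
    out = np.zeros((n, d, w1.shape[1]))
    for s in range(n):
        for i in range(d):
            z = x[s, i] @ w1 / deg[i] + x[s, i] @ w2
            for j in graph.neighbor_sets[i]:
                z = z + x[s, j] @ w1 / np.sqrt(deg[i] * deg[j])
            out[s, i] = act(z)
    return out


def _random_nc_layer(graph, h_in, h_out, seed, activation="tanh"):
    rng = np.random.default_rng(seed)
    layer = NCLayer(build_mask(graph), h_in, h_out, activation=activation, rng=rng)
    return layer


class TestAllocateHidden:
    @pytest.mark.parametrize(
        "H,d,expected", [(9000, 943, 9), (943, 943, 1), (40, 10, 4), (100, 30, 3)]
    )
    def test_floor(self, H, d, expected):
        assert allocate_hidden(H, d) == expected

    def test_undersized_budget_errors(self):
        with pytest.raises(ValueError):
            allocate_hidden(5, 10)


class TestFlatten:
    def test_feature_block_order(self):
        h = np.array([[1.0, 2.0], [3.0, 4.0]])  # nodes x features
        np.testing.assert_array_equal(flatten(h), [1.0, 3.0, 2.0, 4.0])

    def test_single_feature_is_identity(self):
        h = np.arange(5.0)[:, None]
        np.testing.assert_array_equal(flatten(h), np.arange(5.0))

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((7, 6, 3))
        np.testing.assert_array_equal(unflatten(flatten(x), 6, 3), x)
        assert flatten(x).shape == (7, 18)


class TestNCForward:
    def test_self_connection_identity(self):
        g = generate_random_graph(5, 0.0, seed=0)
        layer = _random_nc_layer(g, 1, 1, 0, activation="identity")
        layer.params["W"][...] = 0.0
        for i in range(5):
            layer.params["W"][0, 0, i, i] = 1.0
        layer.params["b"][...] = 0.0
        x = np.random.default_rng(1).standard_normal((4, 5, 1))
        np.testing.assert_array_equal(nc_forward(x, layer), x)

    def test_zero_weights_give_bias(self):
        g = generate_random_graph(5, 0.5, seed=2)
        layer = _random_nc_layer(g, 1, 2, 0, activation="identity")
        layer.params["W"][...] = 0.0
        b = np.random.default_rng(3).standard_normal((5, 2))
        layer.params["b"][...] = b
        x = np.random.default_rng(4).standard_normal((3, 5, 1))
        out = nc_forward(x, layer)
        for s in range(3):
            np.testing.assert_array_equal(out[s], b)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(3, 21))
        h_in = int(rng.integers(1, 4))
        h_out = int(rng.integers(1, 5))
        g = generate_random_graph(d, float(rng.uniform(0.1, 0.8)), seed=seed)
        layer = _random_nc_layer(g, h_in, h_out, seed + 100)
        x = rng.standard_normal((3, d, h_in))
        expected = nc_oracle(x, layer.params["W"], layer.params["b"],
                             layer.mask, np.tanh)
        np.testing.assert_allclose(nc_forward(x, layer), expected, atol=1e-6)

    def test_path_graph_oracle(self, path_graph):
        layer = _random_nc_layer(path_graph, 1, 2, 11)
        x = np.random.default_rng(12).standard_normal((5, 3, 1))
        expected = nc_oracle(x, layer.params["W"], layer.params["b"],
                             layer.mask, np.tanh)
        np.testing.assert_allclose(nc_forward(x, layer), expected, atol=1e-6)

    def test_shape_mismatch_errors(self, path_graph):
        layer = _random_nc_layer(path_graph, 1, 2, 0)
        with pytest.raises(ValueError, match="expects"):
            nc_forward(np.zeros((2, 4, 1)), layer)

    def test_locality_bitwise(self):
        """Perturbing a landmark outside N(i)|{i} leaves row i unchanged."""
        g = generate_random_graph(10, 0.3, seed=6)
        layer = _random_nc_layer(g, 1, 3, 7)
        rng = np.random.default_rng(8)
        x = rng.standard_normal((4, 10, 1))
        base = nc_forward(x, layer).copy()
        mask = layer.mask.astype(bool)
        for i in range(10):
            outside = np.nonzero(~mask[i])[0]
            if outside.size == 0:
                continue
            x2 = x.copy()
            x2[:, outside, :] = rng.standard_normal((4, outside.size, 1))
            out2 = nc_forward(x2, layer)
            np.testing.assert_array_equal(out2[:, i, :], base[:, i, :])

    @pytest.mark.parametrize("integer_valued", [True, False])
    def test_permutation_equivariance(self, integer_valued):
        """Joint node relabeling permutes outputs; with integer-valued inputs
        and weights the sums are exact in float64, so equality is bitwise."""
        g = generate_random_graph(8, 0.4, seed=13)
        layer = _random_nc_layer(g, 1, 2, 14)
        rng = np.random.default_rng(15)
        if integer_valued:
            layer.params["W"] = (
                rng.integers(-5, 6, size=layer.params["W"].shape).astype(float)
                * layer.mask
            )
            layer.params["b"] = rng.integers(-5, 6, size=(8, 2)).astype(float)
            x = rng.integers(-5, 6, size=(3, 8, 1)).astype(float)
        else:
            x = rng.standard_normal((3, 8, 1))
        base = nc_forward(x, layer)
        for _ in range(5):
            perm = rng.permutation(8)
            pg = type(g)([g.gene_ids[p] for p in perm],
                         g.adjacency[np.ix_(perm, perm)])
            permed = NCLayer(build_mask(pg), 1, 2, activation="tanh")
            permed.params["W"] = layer.params["W"][:, :, perm][:, :, :, perm]
            permed.params["b"] = layer.params["b"][perm]
            out = nc_forward(x[:, perm, :], permed)
            if integer_valued:
                np.testing.assert_array_equal(out, base[:, perm, :])
            else:
                np.testing.assert_allclose(out, base[:, perm, :], atol=1e-12)


class TestGCNForward:
    def test_isolated_node_scalar(self):
        g = generate_random_graph(1, 0.0, seed=0, gene_ids=["x"])
        layer = GCNLayer(g, 1, 1, activation="identity")
        w1 = float(layer.params["W1"][0, 0])
        w2 = float(layer.params["W2"][0, 0])
        x = np.array([[[2.0]]])
        np.testing.assert_allclose(gcn_forward(x, layer), [[[2.0 * (w1 + w2)]]])

    def test_two_node_mean(self):
        g = generate_random_graph(2, 1.0, seed=0)
        layer = GCNLayer(g, 1, 2, activation="identity")
        layer.params["W2"][...] = 0.0
        w1 = layer.params["W1"]
        x = np.array([[[1.0], [3.0]]])
        out = gcn_forward(x, layer)
        for i in range(2):
            np.testing.assert_allclose(out[0, i], 2.0 * w1[0], atol=1e-12)

    def test_zero_weights(self):
        g = generate_random_graph(4, 0.5, seed=1)
        layer = GCNLayer(g, 1, 2, activation="tanh")
        layer.params["W1"][...] = 0.0
        layer.params["W2"][...] = 0.0
        x = np.random.default_rng(2).standard_normal((3, 4, 1))
        np.testing.assert_array_equal(gcn_forward(x, layer), np.zeros((3, 4, 2)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_node_wise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(3, 21))
        h_in = int(rng.integers(1, 4))
        h_out = int(rng.integers(1, 5))
        g = generate_random_graph(d, float(rng.uniform(0.1, 0.8)), seed=seed + 50)
        layer = GCNLayer(g, h_in, h_out, activation="tanh",
                         rng=np.random.default_rng(seed + 200))
        x = rng.standard_normal((3, d, h_in))
        expected = gcn_oracle(x, layer.params["W1"], layer.params["W2"], g)
        np.testing.assert_allclose(gcn_forward(x, layer), expected, atol=1e-6)

    def test_regular_graph_neighbourhood_mean(self):
        """On an r-regular graph with W2=0, identity activation: rows are the
        self-inclusive neighbourhood mean scaled by W1."""
        d = 6  # cycle graph: 2-regular
        adj = np.zeros((d, d), dtype=int)
        for i in range(d):
            adj[i, (i + 1) % d] = adj[(i + 1) % d, i] = 1
        from ncgex.graph import BinaryGeneGraph

        g = BinaryGeneGraph([f"g{i}" for i in range(d)], adj)
        layer = GCNLayer(g, 1, 2, activation="identity")
        layer.params["W2"][...] = 0.0
        x = np.random.default_rng(3).standard_normal((2, d, 1))
        out = gcn_forward(x, layer)
        r = 2
        for s in range(2):
            for i in range(d):
                mean = (x[s, i, 0] + sum(x[s, j, 0] for j in g.neighbor_sets[i])) / (r + 1)
                np.testing.assert_allclose(out[s, i], mean * layer.params["W1"][0],
                                           atol=1e-12)


class TestNCNNPredict:
    def test_zero_everything_gives_zero(self):
        g = generate_random_graph(6, 0.4, seed=0)
        model = build_ncnn(g, 4, H=12, L=2, seed=0)
        for _, _, value, _, _ in model.parameters():
            value[...] = 0.0
        out = ncnn_predict(np.zeros((3, 6)), model)
        np.testing.assert_array_equal(out, np.zeros((3, 4)))

    def test_composition_oracle(self):
        """Full forward equals manually composing NC, flatten, and dense math."""
        g = generate_random_graph(7, 0.4, seed=1)
        model = build_ncnn(g, 5, H=21, L=2, seed=1)
        x = np.random.default_rng(2).standard_normal((4, 7))
        nc, fl, hidden, out_layer = model.layers
        h = nc_oracle(x[:, :, None], nc.params["W"], nc.params["b"], nc.mask, np.tanh)
        v = np.stack([flatten(h[s]) for s in range(4)])
        z = v @ hidden.params["W"] + hidden.params["b"]
        a = -np.logaddexp(0.0, -z)
        expected = a @ out_layer.params["W"] + out_layer.params["b"]
        np.testing.assert_allclose(ncnn_predict(x, model), expected, atol=1e-6)

    def test_mask_mismatch_rejected(self):
        g = generate_random_graph(6, 0.4, seed=3)
        other = generate_random_graph(6, 0.9, seed=4)
        model = build_ncnn(g, 4, H=12, L=2, seed=0)
        with pytest.raises(ValueError, match="mask"):
            ncnn_predict(np.zeros((2, 6)), model, mask=build_mask(other))


class TestCountParameters:
    def test_gcn_closed_form_at_scale(self):
        g = generate_random_graph(943, 0.01, seed=0)
        pc = count_parameters("gcn", g, H=9000, n_targets=9520)
        assert pc.first_layer_edge_params == 18  # 2 * floor(9000 / 943)

    def test_ncnn_synthetic_enumeration(self):
        # d=10, |E|=7, H=40: edge weights 2*7*4, plus self weights 10*4
        adj = np.zeros((10, 10), dtype=int)
        edges = [(0, 1), (1, 2), (2, 3), (4, 5), (6, 7), (8, 9), (0, 9)]
        for i, j in edges:
            adj[i, j] = adj[j, i] = 1
        from ncgex.graph import BinaryGeneGraph

        g = BinaryGeneGraph([f"g{i}" for i in range(10)], adj)
        pc = count_parameters("ncnn", g, H=40, n_targets=20)
        assert pc.first_layer_edge_params == 2 * 7 * 4
        model = build_ncnn(g, 20, H=40, L=2)
        nc = model.layers[0]
        assert int(nc.mask.sum()) * 4 == 56 + 40  # edge + self weights

    def test_dense_first_layer(self):
        pc = count_parameters("mlp", None, H=20, n_targets=20, d=10)
        assert pc.first_layer_edge_params == 200

    @pytest.mark.parametrize("seed", range(10))
    def test_totals_match_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(5, 15))
        H = int(d * rng.integers(1, 5))
        n = int(rng.integers(3, 12))
        g = generate_random_graph(d, float(rng.uniform(0.1, 0.9)), seed=seed)
        h1 = H // d
        pc = count_parameters("ncnn", g, H=H, n_targets=n, L=2)
        assert pc.first_layer_edge_params == 2 * g.n_edges * h1
        # brute force: NC masked weights + biases + hidden dense + output dense
        nc_w = (2 * g.n_edges + d) * h1
        nc_b = d * h1
        hid = d * h1 * H + H
        out = H * n + n
        assert pc.total_trainable == nc_w + nc_b + hid + out
        pc_gcn = count_parameters("gcn", g, H=H, n_targets=n, L=2)
        assert pc_gcn.first_layer_edge_params == 2 * h1


class TestLinearRegression:
    def test_recovers_noiseless_coefficients(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 5))
        b0 = rng.standard_normal((5, 3))
        model = fit_linear_regression(x, x @ b0)
        np.testing.assert_allclose(model.coef, b0, atol=1e-6)
        np.testing.assert_allclose(model.intercept, 0.0, atol=1e-6)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((40, 4))
        y = rng.standard_normal((40, 2))
        model = fit_linear_regression(x, y)
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        coef = np.linalg.solve(xc.T @ xc, xc.T @ yc)
        np.testing.assert_allclose(model.coef, coef, atol=1e-6)

    def test_intercept_only_predicts_column_means(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((30, 3))
        x = np.zeros((30, 0))
        model = fit_linear_regression(x, y)
        np.testing.assert_allclose(model.predict(np.zeros((5, 0))),
                                   np.tile(y.mean(axis=0), (5, 1)), atol=1e-12)

    def test_rank_deficiency_warns(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((20, 3))
        x = np.hstack([x, x[:, :1]])  # duplicated column
        with pytest.warns(UserWarning, match="minimum-norm"):
            fit_linear_regression(x, rng.standard_normal((20, 2)))
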