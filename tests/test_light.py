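"""Encoder fidelity: embeddings, attention biases, layers, readout, heads."""

import math

import numpy as np
import pytest

import linemol as lm
from linemol.light import (
    AttentionBias,
    LiGhTConfig,
    LiGhTModel,
    PredictionHead,
    attention_layer,
    count_parameters,
    distance_bias,
    embed_nodes,
    ffn_block,
    forward,
    path_bias,
    predict_head,
)
from linemol.molgraph import (
    AugmentedGraph,
    LineGraph,
    LineGraphNode,
    all_pairs_paths,
    parse_smiles,
    to_line_graph,
)
from linemol.nn import Tensor


def gauss_gelu(x):
    return x * 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def scalar_line_graph(features, edges):
    """Line graph with 1-dim atom/bond features for hand calculations."""
    nodes = [LineGraphNode(i, np.array([xi]), np.array([xj]), np.array([xe]))
             for i, (xi, xj, xe) in enumerate(features)]
    return all_pairs_paths(LineGraph(nodes, edges, len(nodes)))


def scalar_model(**overrides):
    cfg = LiGhTConfig(n_layers=1, hidden=2, n_heads=1, atom_dim=1, bond_dim=1,
                      d_path=1, d_dist=1, dropout=0.0, **overrides)
    return LiGhTModel.init(cfg)


class TestEmbedNodes:
    def test_hand_scalar_case(self):
        """x_i=1, x_j=2, x_e=1 with W_v=[3], W_e=[5] embeds to (9, 5)."""
        m = scalar_model()
        m.params["embed.Wv"].data = np.array([[3.0]])
        m.params["embed.We"].data = np.array([[5.0]])
        lg = scalar_line_graph([(1.0, 2.0, 1.0)], [])
        h = embed_nodes(lg, m)
        np.testing.assert_allclose(h.data, [[9.0, 5.0]])

    def test_endpoint_swap_symmetry(self, tiny_model):
        lg = to_line_graph(parse_smiles("CCOc1ccncc1"))
        h1 = embed_nodes(lg, tiny_model)
        for nd in lg.nodes:
            nd.x_i, nd.x_j = nd.x_j, nd.x_i
        h2 = embed_nodes(lg, tiny_model)
        np.testing.assert_array_equal(h1.data, h2.data)

    def test_zero_weights_zero_rows(self, tiny_model):
        for name in ("embed.Wv", "embed.We", "embed.bv", "embed.be"):
            tiny_model.params[name].data = np.zeros_like(tiny_model.params[name].data)
        lg = to_line_graph(parse_smiles("CCC"))
        np.testing.assert_array_equal(embed_nodes(lg, tiny_model).data,
                                      np.zeros((2, 32)))

    def test_knowledge_row_projects_712_vector(self, tiny_model, benzene_aug):
        h = embed_nodes(benzene_aug, tiny_model)
        p = tiny_model.params
        expected = (p["know.Wk"].data @ benzene_aug.knowledge + p["know.bk"].data)
        np.testing.assert_allclose(h.data[-1], expected, atol=1e-12)


class TestPathBias:
    def test_zero_bank_zero_matrix(self, tiny_model, benzene_aug):
        for n in range(1, 6):
            tiny_model.params[f"path.W{n}"].data *= 0.0
        h0 = embed_nodes(benzene_aug, tiny_model)
        np.testing.assert_array_equal(path_bias(benzene_aug, tiny_model, h0).data,
                                      np.zeros((7, 7)))

    def test_hand_scalar_case(self):
        """Two-node path with unit projections: a^p = mean(2, 4) = 3."""
        m = scalar_model()
        m.params["path.W1"].data = np.array([[1.0, 0.0]])
        m.params["path.W2"].data = np.array([[1.0, 0.0]])
        for n in range(3, 6):
            m.params[f"path.W{n}"].data *= 0.0
        m.params["path.Wa"].data = np.array([[1.0]])
        lg = scalar_line_graph([(0, 0, 0), (0, 0, 0)], [(0, 1)])
        h0 = Tensor(np.array([[2.0, 0.0], [4.0, 0.0]]))
        a = path_bias(lg, m, h0)
        assert a.data[0, 1] == pytest.approx(3.0)
        assert a.data[1, 0] == pytest.approx(3.0)

    def test_diagonal_uses_length_one_path(self):
        m = scalar_model()
        m.params["path.W1"].data = np.array([[1.0, 0.0]])
        m.params["path.Wa"].data = np.array([[1.0]])
        lg = scalar_line_graph([(0, 0, 0), (0, 0, 0)], [(0, 1)])
        h0 = Tensor(np.array([[2.0, 0.0], [4.0, 0.0]]))
        a = path_bias(lg, m, h0)
        assert a.data[0, 0] == pytest.approx(2.0)
        assert a.data[1, 1] == pytest.approx(4.0)

    def test_k_pairs_get_dedicated_scalar(self, tiny_model, benzene_aug):
        tiny_model.params["path.k_scalar"].data = np.array([4.5])
        h0 = embed_nodes(benzene_aug, tiny_model)
        a = path_bias(benzene_aug, tiny_model, h0).data
        assert (a[-1, :] == 4.5).all()
        assert (a[:, -1] == 4.5).all()

    def test_unreachable_pairs_get_dedicated_scalar(self, tiny_model):
        lg = LineGraph([LineGraphNode(i, np.zeros(tiny_model.config.atom_dim),
                                      np.zeros(tiny_model.config.atom_dim),
                                      np.zeros(tiny_model.config.bond_dim))
                        for i in range(3)], [(0, 1)], 3)
        lg = all_pairs_paths(lg)
        tiny_model.params["path.unreach_scalar"].data = np.array([-2.5])
        h0 = embed_nodes(lg, tiny_model)
        a = path_bias(lg, tiny_model, h0).data
        assert a[0, 2] == -2.5 and a[2, 0] == -2.5 and a[1, 2] == -2.5


class TestDistanceBias:
    def test_zero_output_projection(self, tiny_model, benzene_aug):
        tiny_model.params["dist.W2"].data *= 0.0
        tiny_model.params["dist.k_scalar"].data *= 0.0
        np.testing.assert_array_equal(distance_bias(benzene_aug, tiny_model).data,
                                      np.zeros((7, 7)))

    def test_hand_scalar_case_gelu(self):
        """Unit 1-dim weights, d=2: a^d = GELU(2) = 2 * Phi(2)."""
        m = scalar_model()
        m.params["dist.W1"].data = np.array([[1.0]])
        m.params["dist.W2"].data = np.array([[1.0]])
        lg = scalar_line_graph([(0, 0, 0)] * 3, [(0, 1), (1, 2)])
        a = distance_bias(lg, m)
        assert a.data[0, 2] == pytest.approx(gauss_gelu(2.0), abs=1e-12)
        assert a.data[0, 1] == pytest.approx(gauss_gelu(1.0), abs=1e-12)

    def test_zero_distance_zero_bias(self, tiny_model):
        """GELU(0) = 0, so the diagonal is 0 for any weights."""
        lg = to_line_graph(parse_smiles("CCCC"))
        a = distance_bias(lg, tiny_model).data
        np.testing.assert_allclose(np.diag(a), 0.0, atol=1e-15)

    def test_distance_clipped(self):
        m = scalar_model()
        m.config.distance_clip = 3
        m.params["dist.W1"].data = np.array([[1.0]])
        m.params["dist.W2"].data = np.array([[1.0]])
        lg = scalar_line_graph([(0, 0, 0)] * 7,
                               [(i, i + 1) for i in range(6)])
        a = distance_bias(lg, m)
        assert a.data[0, 6] == pytest.approx(gauss_gelu(3.0), abs=1e-12)


def zero_bias(n):
    return AttentionBias(a_path=Tensor(np.zeros((n, n))),
                         a_dist=Tensor(np.zeros((n, n))))


class TestAttention:
    def test_rows_sum_to_one(self, tiny_model):
        rng = np.random.default_rng(0)
        n, d = 5, tiny_model.config.hidden
        h = Tensor(rng.standard_normal((n, d)))
        bias = AttentionBias(a_path=Tensor(rng.standard_normal((n, n))),
                             a_dist=Tensor(rng.standard_normal((n, n))))
        # check the attention weights directly, per head
        p = tiny_model.params
        dh = tiny_model.config.head_dim
        q = h.data @ p["layer0.Wq"].data + p["layer0.bq"].data
        k = h.data @ p["layer0.Wk"].data + p["layer0.bk"].data
        for head in range(tiny_model.config.n_heads):
            sl = slice(head * dh, (head + 1) * dh)
            scores = q[:, sl] @ k[:, sl].T / np.sqrt(dh) + bias.total().data
            attn = Tensor(scores).softmax(axis=-1).data
            np.testing.assert_allclose(attn.sum(axis=1), np.ones(n), atol=1e-6)

    def test_zero_bias_reduces_to_plain_attention(self, tiny_model):
        """With A^p = A^d = 0 the layer equals unbiased attention (oracle)."""
        rng = np.random.default_rng(1)
        cfg, p = tiny_model.config, tiny_model.params
        n = 6
        h = Tensor(rng.standard_normal((n, cfg.hidden)))
        out = attention_layer(h, zero_bias(n), tiny_model, 0)

        q = h.data @ p["layer0.Wq"].data + p["layer0.bq"].data
        k = h.data @ p["layer0.Wk"].data + p["layer0.bk"].data
        v = h.data @ p["layer0.Wv"].data + p["layer0.bv"].data
        dh = cfg.head_dim
        expect = []
        for head in range(cfg.n_heads):
            sl = slice(head * dh, (head + 1) * dh)
            s = q[:, sl] @ k[:, sl].T / np.sqrt(dh)
            e = np.exp(s - s.max(axis=1, keepdims=True))
            a = e / e.sum(axis=1, keepdims=True)
            expect.append(a @ v[:, sl])
        np.testing.assert_allclose(out.data, np.hstack(expect), atol=1e-10)

    def test_row_shift_invariance(self, tiny_model):
        """Adding a constant to one bias row leaves the output unchanged."""
        rng = np.random.default_rng(2)
        n = 5
        h = Tensor(rng.standard_normal((n, tiny_model.config.hidden)))
        bias = AttentionBias(a_path=Tensor(rng.standard_normal((n, n))),
                             a_dist=Tensor(rng.standard_normal((n, n))))
        out1 = attention_layer(h, bias, tiny_model, 0)
        shifted = bias.a_path.data.copy()
        shifted[2, :] += 7.3
        bias2 = AttentionBias(a_path=Tensor(shifted), a_dist=bias.a_dist)
        out2 = attention_layer(h, bias2, tiny_model, 0)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-10)

    def test_uniform_attention_for_identical_features(self, tiny_model):
        """Zero bias + identical node features => uniform attention rows."""
        n = 4
        h = Tensor(np.tile(np.linspace(-1, 1, tiny_model.config.hidden), (n, 1)))
        out = attention_layer(h, zero_bias(n), tiny_model, 0)
        v = h.data @ tiny_model.params["layer0.Wv"].data + tiny_model.params["layer0.bv"].data
        np.testing.assert_allclose(out.data, v.mean(axis=0)[None, :].repeat(n, 0),
                                   atol=1e-10)

    def test_nonfinite_input_rejected(self, tiny_model):
        h = Tensor(np.full((3, 32), np.nan))
        with pytest.raises(ValueError):
            attention_layer(h, zero_bias(3), tiny_model, 0)


class TestFFN:
    def test_zero_w2_reduces_to_layernorm(self, tiny_model):
        rng = np.random.default_rng(3)
        tiny_model.params["layer0.W2"].data *= 0.0
        tiny_model.params["layer0.b2"].data *= 0.0
        h_prev = Tensor(rng.standard_normal((4, 32)))
        h_attn = Tensor(rng.standard_normal((4, 32)))
        out = ffn_block(h_prev, h_attn, tiny_model, 0)
        s = h_prev.data + h_attn.data
        h_hat = (s - s.mean(1, keepdims=True)) / np.sqrt(s.var(1, keepdims=True) + 1e-5)
        # the outer LN re-standardizes h_hat (a no-op up to the eps term)
        expect = (h_hat - h_hat.mean(1, keepdims=True)) / np.sqrt(
            h_hat.var(1, keepdims=True) + 1e-5)
        np.testing.assert_allclose(out.data, expect, atol=1e-10)
        np.testing.assert_allclose(out.data, h_hat, atol=1e-4)

    def test_shape_preserved_and_rows_standardized(self, tiny_model):
        """With untrained LN affine (gamma=1, beta=0) output rows have zero
        mean and unit variance."""
        rng = np.random.default_rng(4)
        h_prev = Tensor(rng.standard_normal((5, 32)))
        h_attn = Tensor(rng.standard_normal((5, 32)))
        out = ffn_block(h_prev, h_attn, tiny_model, 0)
        assert out.shape == (5, 32)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.data.var(axis=1), 1.0, atol=1e-3)


def permuted_augmented(ag: AugmentedGraph, perm: np.ndarray) -> AugmentedGraph:
    """Relabel base nodes by ``perm`` (stored paths permuted consistently)."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    base = ag.base
    nodes = [base.nodes[i] for i in perm]
    edges = [(int(inv[a]), int(inv[b])) for a, b in base.edges]
    n = base.n_nodes
    dist = base.dist[np.ix_(perm, perm)]
    paths = [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            p = base.paths[perm[i]][perm[j]]
            paths[i][j] = None if p is None else [int(inv[x]) for x in p]
    lg = LineGraph(nodes, edges, n, base.smiles_canonical, dist, paths)
    return AugmentedGraph(lg, ag.k_index, ag.knowledge,
                          [(n, i) for i in range(n)], ag.knowledge_mask)


class TestForward:
    def test_single_node_pool_equals_embedding(self, tiny_model):
        lg = to_line_graph(parse_smiles("C"))
        h, pooled = forward(lg, tiny_model)
        np.testing.assert_allclose(pooled.data, h.data[0], atol=1e-12)

    def test_permutation_equivariance(self, tiny_model, small_corpus):
        rng = np.random.default_rng(0)
        for pm in small_corpus.molecules[:6]:
            ag = pm.graph
            n = ag.base.n_nodes
            if n < 2:
                continue
            perm = rng.permutation(n)
            h1, pooled1 = forward(ag, tiny_model)
            h2, pooled2 = forward(permuted_augmented(ag, perm), tiny_model)
            np.testing.assert_allclose(h2.data[:n], h1.data[:n][perm], atol=1e-5)
            np.testing.assert_allclose(pooled1.data, pooled2.data, atol=1e-5)

    def test_eval_mode_bitwise_deterministic(self, tiny_model, benzene_aug):
        tiny_model.eval()
        h1, p1 = forward(benzene_aug, tiny_model)
        h2, p2 = forward(benzene_aug, tiny_model)
        assert (h1.data == h2.data).all()
        assert (p1.data == p2.data).all()

    def test_k_node_pool_switch(self, tiny_model, benzene_aug):
        h, pooled_with = forward(benzene_aug, tiny_model)
        tiny_model.config.include_k_in_pool = False
        h2, pooled_without = forward(benzene_aug, tiny_model)
        np.testing.assert_allclose(pooled_with.data, h.data.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(pooled_without.data, h2.data[:6].mean(axis=0),
                                   atol=1e-12)

    def test_gradient_reaches_every_parameter(self, tiny_model, small_corpus):
        """No dead modules: each parameter bank gets a nonzero gradient."""
        long_chain = to_line_graph(parse_smiles("CCCCCCCC"))  # paths of >= 5 nodes
        disconnected = all_pairs_paths(
            LineGraph([LineGraphNode(i, np.zeros(tiny_model.config.atom_dim),
                                     np.zeros(tiny_model.config.atom_dim),
                                     np.ones(tiny_model.config.bond_dim))
                       for i in range(4)], [(0, 1), (2, 3)], 4))
        masked = small_corpus.molecules[0].graph
        masked.base.nodes[0].is_masked = True
        masked.knowledge_mask = np.ones(712)
        graphs = [long_chain, disconnected, masked,
                  small_corpus.molecules[1].graph]
        loss = Tensor(0.0)
        for g in graphs:
            h, pooled = forward(g, tiny_model)
            loss = loss + (h * h).sum() + (pooled * pooled).sum()
        tiny_model.zero_grad()
        loss.backward()
        masked.base.nodes[0].is_masked = False
        masked.knowledge_mask = None
        dead = [name for name, p in tiny_model.params.items()
                if p.grad is None or np.abs(p.grad).max() == 0.0]
        assert dead == []


class TestPredictionHead:
    def test_zero_weights_zero_output(self):
        head = PredictionHead(8, 2, seed=0)
        for t in head.params.values():
            t.data *= 0.0
        out = predict_head(Tensor(np.ones(8)), head)
        np.testing.assert_array_equal(out.data, np.zeros(2))

    def test_output_width_matches_tasks(self):
        head = PredictionHead(16, 3, seed=1)
        assert predict_head(Tensor(np.ones(16)), head).shape == (3,)
        assert predict_head(Tensor(np.ones((5, 16))), head).shape == (5, 3)

    def test_hand_scalar_case(self):
        head = PredictionHead(1, 1, hidden=1, seed=0)
        w1, w2, x = 0.7, -1.3, 2.1
        head.params["head.W1"].data = np.array([[w1]])
        head.params["head.W2"].data = np.array([[w2]])
        head.params["head.b1"].data *= 0.0
        head.params["head.b2"].data *= 0.0
        out = predict_head(Tensor(np.array([x])), head)
        assert out.data[0] == pytest.approx(w2 * gauss_gelu(w1 * x), abs=1e-9)

    def test_dim_mismatch_rejected(self):
        head = PredictionHead(8, 1)
        with pytest.raises(ValueError):
            predict_head(Tensor(np.ones(9)), head)


class TestParameterCount:
    def test_matches_hand_formula_for_tiny_config(self, tiny_config, tiny_model):
        D, L = tiny_config.hidden, tiny_config.n_layers
        Dv, De, Dk = tiny_config.atom_dim, tiny_config.bond_dim, 712
        embed = D // 2 * Dv + D // 2 * De + D // 2 + D // 2  # Wv, We, bv, be
        embed += D + 2 * (D * Dk) + D              # mask token, know.Wk/Wmask, bk
        path = 5 * (tiny_config.d_path * D) + tiny_config.d_path + 2
        dist = tiny_config.d_dist + tiny_config.d_dist + 2
        per_layer = 3 * (D * D + D) + (4 * D * D + 4 * D) + (D * 4 * D + D) + 4 * D
        assert count_parameters(tiny_model) == embed + path + dist + L * per_layer

    def test_doubling_layers_doubles_layer_bank(self, tiny_config):
        c2 = count_parameters(LiGhTModel.init(tiny_config))
        cfg4 = LiGhTConfig(n_layers=4, hidden=32, n_heads=4, dropout=0.0)
        c4 = count_parameters(LiGhTModel.init(cfg4))
        per_layer = (c4 - c2) / 2
        non_layer = c2 - 2 * per_layer
        assert non_layer > 0
        assert c4 == pytest.approx(non_layer + 4 * per_layer)

    def test_head_counts_linear_map_with_bias(self):
        head = PredictionHead(7, 3, hidden=5)
        n = sum(t.size for t in head.params.values())
        assert n == (5 * 7 + 5) + (3 * 5 + 3)
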