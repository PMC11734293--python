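import numpy as np
import pytest

from gala.autodiff import Tensor, softmax
from gala.graph_build import ProteinGraph, build_features
from gala.network import GalaModel, ModelConfig, _normalized_adjacency

from conftest import tiny_config
from oracles import naive_gcn_layer, naive_softmax


def path_graph(n=3, seq=None):
    seq = seq or "A" * n
    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return ProteinGraph(id=f"path{n}", sequence=seq, adjacency=adj,
                        features=build_features(seq))


class TestGcnForward:
    def test_single_node_identity_normalization(self, tiny_model):
        g = path_graph(1)
        H = tiny_model.gcn_forward(g.features, g.adjacency)
        # two-layer composition of ReLU(x W) with A~ = D~ = [1]
        x = g.features
        expected = naive_gcn_layer(naive_gcn_layer(
            x, np.zeros((1, 1)), tiny_model.params["gcn_W0"].data),
            np.zeros((1, 1)), tiny_model.params["gcn_W1"].data)
        np.testing.assert_allclose(H.data, expected, atol=1e-12)

    def test_zero_features_give_zero(self, tiny_model):
        g = path_graph(4)
        H = tiny_model.gcn_forward(np.zeros_like(g.features), g.adjacency)
        np.testing.assert_array_equal(H.data, 0.0)

    def test_matches_dense_oracle(self, tiny_model):
        g = path_graph(3, "ACD")
        H = tiny_model.gcn_forward(g.features, g.adjacency)
        expected = g.features
        for l in range(tiny_model.config.gcn_layers):
            expected = naive_gcn_layer(expected, g.adjacency,
                                       tiny_model.params[f"gcn_W{l}"].data)
        np.testing.assert_allclose(H.data, expected, atol=1e-10)

    def test_shape_mismatch(self, tiny_model):
        with pytest.raises(ValueError, match="feature"):
            tiny_model.gcn_forward(np.zeros((4, 25)), np.zeros((3, 3)))


class TestMetaNodeAttention:
    def test_identical_values_collapse(self, tiny_model, rng):
        # force identical value rows by zeroing H except one repeated row
        g = path_graph(4)
        H = Tensor(np.tile(rng.standard_normal(8), (4, 1)))
        # with a regular graph (all degrees equal), identical rows stay identical
        adj = np.ones((4, 4), dtype=np.int8) - np.eye(4, dtype=np.int8)
        gamma = tiny_model.meta_node_attention(H, adj, head=0)
        for k in range(1, gamma.shape[0]):
            np.testing.assert_allclose(gamma.data[k], gamma.data[0], atol=1e-10)

    def test_single_node_single_meta(self):
        model = GalaModel(tiny_config(meta_nodes=1))
        g = path_graph(1)
        H = model.gcn_forward(g.features, g.adjacency)
        gamma = model.meta_node_attention(H, g.adjacency, head=0)
        A_hat = _normalized_adjacency(g.adjacency)
        values = naive_gcn_layer(H.data, g.adjacency,
                                 model.params["value_gcn_W"].data)
        np.testing.assert_allclose(gamma.data, values, atol=1e-10)

    def test_matches_explicit_oracle(self, tiny_model):
        g = path_graph(3, "ACD")
        H = tiny_model.gcn_forward(g.features, g.adjacency)
        gamma = tiny_model.meta_node_attention(H, g.adjacency, head=1)
        keys = naive_gcn_layer(H.data, g.adjacency,
                               tiny_model.params["key_gcn_W"].data)
        values = naive_gcn_layer(H.data, g.adjacency,
                                 tiny_model.params["value_gcn_W"].data)
        Q = tiny_model.params["queries_1"].data
        D = tiny_model.config.hidden_dim
        expected = naive_softmax(Q @ keys.T / np.sqrt(D)) @ values
        np.testing.assert_allclose(gamma.data, expected, atol=1e-10)

    def test_attention_rows_sum_to_one(self, tiny_model):
        g = path_graph(6, "ACDEFG")
        H = tiny_model.gcn_forward(g.features, g.adjacency)
        keys = tiny_model._single_gcn(
            H, Tensor(_normalized_adjacency(g.adjacency)),
            tiny_model.params["key_gcn_W"])
        scores = (tiny_model.params["queries_0"] @ keys.T) / np.sqrt(8)
        rows = softmax(scores, axis=-1).data
        np.testing.assert_allclose(rows.sum(axis=-1), 1.0, atol=1e-6)
        assert (rows >= 0).all()


class TestMergeAndPool:
    def test_zero_inputs_zero_bias(self, tiny_model):
        gammas = [Tensor(np.zeros((3, 8))) for _ in range(2)]
        U = tiny_model.multihead_merge(gammas)
        np.testing.assert_allclose(U.data, 0.0, atol=1e-12)

    def test_merge_oracle(self, tiny_model, rng):
        gammas = [Tensor(rng.standard_normal((3, 8))) for _ in range(2)]
        U = tiny_model.multihead_merge(gammas)
        cat = np.concatenate([g.data for g in gammas], axis=-1)
        hidden = np.maximum(cat @ tiny_model.params["merge_W1"].data
                            + tiny_model.params["merge_b1"].data, 0)
        expected = hidden @ tiny_model.params["merge_W2"].data \
            + tiny_model.params["merge_b2"].data
        np.testing.assert_allclose(U.data, expected, atol=1e-10)

    def test_merge_head_count_checked(self, tiny_model):
        with pytest.raises(ValueError, match="heads"):
            tiny_model.multihead_merge([Tensor(np.zeros((3, 8)))])

    def test_pool_identical_rows(self, tiny_model, rng):
        u = rng.standard_normal(8)
        U = Tensor(np.tile(u, (3, 1)))
        z = tiny_model.attention_pool(U)
        np.testing.assert_allclose(z.data,
                                   u @ tiny_model.params["pool_V"].data,
                                   atol=1e-10)

    def test_pool_single_meta_node(self, rng):
        model = GalaModel(tiny_config(meta_nodes=1))
        U = Tensor(rng.standard_normal((1, 8)))
        z = model.attention_pool(U)
        np.testing.assert_allclose(
            z.data, (U.data @ model.params["pool_V"].data)[0], atol=1e-10)

    def test_pool_oracle(self, tiny_model, rng):
        U = Tensor(rng.standard_normal((3, 8)))
        q = tiny_model.params["pool_q"].data
        K = tiny_model.params["pool_K"].data
        V = tiny_model.params["pool_V"].data
        w = naive_softmax(q @ (U.data @ K).T / np.sqrt(8))
        np.testing.assert_allclose(tiny_model.attention_pool(U).data,
                                   w @ (U.data @ V), atol=1e-10)


class TestHeads:
    def test_classify_zero_weights_gives_half(self, tiny_model):
        tiny_model.params["cls_W"].data[:] = 0
        tiny_model.params["cls_b"].data[:] = 0
        probs, logits = tiny_model.classify(Tensor(np.ones(8)))
        np.testing.assert_allclose(probs.data, 0.5)
        np.testing.assert_allclose(logits.data, 0.0)

    def test_classify_clipped(self, tiny_model):
        tiny_model.params["cls_b"].data[:] = 1000.0
        probs, _ = tiny_model.classify(Tensor(np.zeros(8)))
        assert (probs.data <= 1 - 1e-7 + 1e-12).all()

    def test_classify_oracle(self, tiny_model, rng):
        z = rng.standard_normal(8)
        probs, logits = tiny_model.classify(Tensor(z))
        expected = z @ tiny_model.params["cls_W"].data \
            + tiny_model.params["cls_b"].data
        np.testing.assert_allclose(logits.data, expected, atol=1e-10)
        np.testing.assert_allclose(probs.data, 1 / (1 + np.exp(-expected)),
                                   atol=1e-10)

    def test_embed_labels_zero(self, tiny_model):
        b = tiny_model.embed_labels(np.zeros(15))
        np.testing.assert_allclose(
            b.data, tiny_model.params["proj_b1"].data.clip(min=0)
            @ tiny_model.params["proj_W2"].data
            + tiny_model.params["proj_b2"].data, atol=1e-12)

    def test_embed_labels_deterministic(self, tiny_model, rng):
        y = (rng.random(15) < 0.4).astype(float)
        np.testing.assert_array_equal(tiny_model.embed_labels(y).data,
                                      tiny_model.embed_labels(y).data)

    def test_embed_labels_rejects_nonbinary(self, tiny_model):
        with pytest.raises(ValueError, match="binary"):
            tiny_model.embed_labels(np.full(15, 0.5))

    def test_embed_labels_oracle(self, tiny_model, rng):
        y = (rng.random(15) < 0.5).astype(float)
        hidden = np.maximum(y @ tiny_model.params["proj_W1"].data
                            + tiny_model.params["proj_b1"].data, 0)
        expected = hidden @ tiny_model.params["proj_W2"].data \
            + tiny_model.params["proj_b2"].data
        np.testing.assert_allclose(tiny_model.embed_labels(y).data, expected,
                                   atol=1e-10)


class TestMultilinearMap:
    def test_identity_matrices_closed_form(self):
        model = GalaModel(tiny_config(hidden_dim=2, n_classes=2,
                                      multilinear_dim=2, meta_nodes=1))
        model.R_z = np.eye(2)
        model.R_y = np.eye(2)
        t = model.multilinear_map(Tensor([1.0, 2.0]), Tensor([1.0, 0.0]))
        np.testing.assert_allclose(t.data, [1 / np.sqrt(2), 0.0], atol=1e-12)

    def test_zero_prediction_gives_zero(self, tiny_model):
        t = tiny_model.multilinear_map(Tensor(np.ones(8)), Tensor(np.zeros(15)))
        np.testing.assert_array_equal(t.data, 0.0)

    def test_elementwise_oracle(self, tiny_model, rng):
        z, y = rng.standard_normal(8), rng.random(15)
        t = tiny_model.multilinear_map(Tensor(z), Tensor(y))
        expected = (tiny_model.R_z @ z) * (tiny_model.R_y @ y) / np.sqrt(6)
        np.testing.assert_allclose(t.data, expected, atol=1e-12)

    def test_frozen_matrices_survive_reload(self, tiny_model, tmp_path):
        tiny_model.save(tmp_path / "m.npz")
        reloaded = GalaModel.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(reloaded.R_z, tiny_model.R_z)
        np.testing.assert_array_equal(reloaded.R_y, tiny_model.R_y)

    def test_r_matrices_unit_variance(self):
        model = GalaModel(tiny_config(multilinear_dim=512, hidden_dim=64))
        assert abs(model.R_z.std() - 1.0) < 0.02
        assert abs(model.R_z.mean()) < 0.02


class TestDiscriminator:
    def test_zero_weights_give_half(self, tiny_model):
        for k in tiny_model.discriminator_params():
            tiny_model.params[k].data[:] = 0
        out = tiny_model.discriminate(Tensor(np.ones(6)))
        np.testing.assert_allclose(out.data, 0.5)

    def test_output_clipped(self, tiny_model, rng):
        tiny_model.params["disc_b2"].data[:] = 500.0
        out = tiny_model.discriminate(Tensor(rng.standard_normal(6)))
        assert 1e-7 <= out.data[0] <= 1 - 1e-7 + 1e-12

    def test_mlp_oracle(self, tiny_model, rng):
        t = rng.standard_normal(6)
        hidden = np.maximum(t @ tiny_model.params["disc_W1"].data
                            + tiny_model.params["disc_b1"].data, 0)
        logit = hidden @ tiny_model.params["disc_W2"].data \
            + tiny_model.params["disc_b2"].data
        np.testing.assert_allclose(tiny_model.discriminate(Tensor(t)).data,
                                   1 / (1 + np.exp(-logit)), atol=1e-10)


class TestForward:
    def test_batch_of_one_equals_single(self, tiny_model, fixture):
        g = fixture["source_graphs"][0]
        single = tiny_model.forward_one(g)
        batch = tiny_model.forward([g])
        np.testing.assert_array_equal(batch[0]["z"].data, single["z"].data)

    def test_batch_equals_per_graph_loop(self, tiny_model, fixture):
        graphs = fixture["source_graphs"][:3]
        batch = tiny_model.forward(graphs)
        for g, out in zip(graphs, batch):
            solo = tiny_model.forward_one(g)
            np.testing.assert_allclose(out["z"].data, solo["z"].data, atol=1e-5)
            np.testing.assert_allclose(out["y_hat"].data, solo["y_hat"].data,
                                       atol=1e-5)

    def test_batch_order_permutes_outputs(self, tiny_model, fixture):
        graphs = fixture["source_graphs"][:3]
        fwd = tiny_model.forward(graphs)
        rev = tiny_model.forward(graphs[::-1])
        for a, b in zip(fwd, rev[::-1]):
            np.testing.assert_array_equal(a["y_hat"].data, b["y_hat"].data)

    def test_node_relabeling_invariance(self, tiny_model, fixture, rng):
        g = fixture["source_graphs"][1]
        perm = rng.permutation(len(g))
        permuted = ProteinGraph(
            id=g.id, sequence="".join(g.sequence[i] for i in perm),
            adjacency=g.adjacency[np.ix_(perm, perm)],
            features=g.features[perm])
        a = tiny_model.forward_one(g)
        b = tiny_model.forward_one(permuted)
        np.testing.assert_allclose(a["z"].data, b["z"].data, atol=1e-5)
        np.testing.assert_allclose(a["y_hat"].data, b["y_hat"].data, atol=1e-5)

    def test_empty_batch_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="empty"):
            tiny_model.forward([])

    def test_outputs_finite_across_sizes(self, tiny_model, rng):
        for n in (1, 2, 17, 300):
            g = path_graph(n, "".join(rng.choice(list("ACDEFG"), size=n)))
            out = tiny_model.forward_one(g, reverse_grad=1.0)
            for key in ("z", "y_hat", "logits", "domain_prob"):
                assert np.isfinite(out[key].data).all(), (n, key)


class TestCheckpoint:
    def test_bit_exact_reload(self, tiny_model, fixture, tmp_path):
        tiny_model.save(tmp_path / "model.npz")
        reloaded = GalaModel.load(tmp_path / "model.npz")
        assert reloaded.config == tiny_model.config
        g = fixture["target_graphs"][0]
        a = tiny_model.forward_one(g)["y_hat"].data
        b = reloaded.forward_one(g)["y_hat"].data
        np.testing.assert_array_equal(a, b)


def test_dropout_only_active_with_installed_rng(fixture):
    model = GalaModel(tiny_config(dropout=0.5))
    g = fixture["source_graphs"][0]
    eval_out = model.forward_one(g)["y_hat"].data
    model.dropout_rng = np.random.default_rng(0)
    train_out = model.forward_one(g)["y_hat"].data
    model.dropout_rng = None
    assert not np.allclose(eval_out, train_out)
    np.testing.assert_array_equal(model.forward_one(g)["y_hat"].data, eval_out)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(hidden_dim=0)
    with pytest.raises(ValueError):
        ModelConfig(temperature=0.0)
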