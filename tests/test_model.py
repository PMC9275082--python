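"""Encoder, attention, decoder: algebra oracles, dropout semantics,
permutation equivariance and the finite-difference gradient check."""

import numpy as np
import pytest

from mtlink import model as M
from mtlink.hetgraph import symmetric_degree_normalize
from mtlink.model import (
    ModelConfig,
    attend,
    decode,
    encode,
    gcn_layer,
    load_checkpoint,
    predict_scores,
    save_checkpoint,
    selu,
    sigmoid,
    softmax,
)
from mtlink.training import (
    LossSpec,
    init_state,
    loss_gradient,
    weighted_cross_entropy,
)


def make_state(graph, cfg, seed=0):
    rng = np.random.default_rng(seed)
    state = init_state(graph, cfg, rng)
    state.att_logits = rng.normal(size=cfg.n_layers) * 0.5
    return state


class TestGcnLayer:
    def test_identity_propagation(self, rng):
        H = rng.random((4, 4))
        out = gcn_layer(H, np.eye(4), np.eye(4), activation=None)
        assert np.allclose(out, H)

    def test_zero_input_stays_zero(self, rng):
        out = gcn_layer(np.zeros((5, 3)), rng.random((5, 5)),
                        rng.random((3, 2)))
        assert np.allclose(out, 0)  # SELU(0) = 0

    def test_matches_dense_product_oracle(self, rng):
        G = rng.random((6, 6))
        H = rng.random((6, 4))
        W = rng.random((4, 3))
        out = gcn_layer(H, G, W, activation=None)
        assert np.abs(out - G @ H @ W).max() < 1e-12

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            gcn_layer(rng.random((4, 3)), rng.random((5, 5)),
                      rng.random((3, 2)))


class TestActivations:
    def test_selu_constants(self):
        # SELU(1) = lambda, SELU(-inf) -> -lambda*alpha
        assert selu(np.array([1.0]))[0] == pytest.approx(1.0507, abs=1e-4)
        assert selu(np.array([-30.0]))[0] == pytest.approx(
            -1.0507 * 1.6733, abs=1e-3)

    def test_sigmoid_extremes_are_finite(self):
        out = sigmoid(np.array([-1000.0, 0.0, 1000.0]))
        assert np.all(np.isfinite(out))
        assert out[1] == 0.5


class TestEncode:
    def test_single_layer_matches_explicit_formula(self, tiny_graph):
        cfg = ModelConfig(embed_dim=4, n_layers=1, node_dropout=0,
                          edge_dropout=0)
        state = make_state(tiny_graph, cfg)
        stack = encode(tiny_graph, state, cfg)
        Gn = symmetric_degree_normalize(tiny_graph.G)
        H0 = tiny_graph.H0.toarray()
        assert np.allclose(stack.layers[0], selu(Gn @ H0 @ state.W0),
                           atol=1e-12)

    def test_eval_mode_is_deterministic(self, tiny_graph):
        cfg = ModelConfig(embed_dim=4, n_layers=3)
        state = make_state(tiny_graph, cfg)
        s1 = encode(tiny_graph, state, cfg)
        s2 = encode(tiny_graph, state, cfg)
        for a, b in zip(s1.layers, s2.layers):
            assert np.array_equal(a, b)

    def test_zero_dropout_training_equals_eval(self, tiny_graph):
        cfg = ModelConfig(embed_dim=4, n_layers=2, node_dropout=0,
                          edge_dropout=0)
        state = make_state(tiny_graph, cfg)
        rng = np.random.default_rng(0)
        train = encode(tiny_graph, state, cfg, training=True, rng=rng)
        ev = encode(tiny_graph, state, cfg, training=False)
        assert np.allclose(train.H_I, ev.H_I)
        assert np.allclose(train.H_G, ev.H_G)

    def test_dropout_draws_differ_between_steps(self, tiny_graph):
        cfg = ModelConfig(embed_dim=4, n_layers=2)
        state = make_state(tiny_graph, cfg)
        rng = np.random.default_rng(0)
        a = encode(tiny_graph, state, cfg, training=True, rng=rng)
        b = encode(tiny_graph, state, cfg, training=True, rng=rng)
        assert not np.allclose(a.H_I, b.H_I)


class TestAttend:
    def test_equal_logits_give_layer_mean(self, rng):
        layers = [rng.random((6, 3)) for _ in range(3)]
        H_I, H_G, a = attend(layers, np.zeros(3), M=2)
        assert np.allclose(a, 1 / 3)
        mean = sum(layers) / 3
        assert np.allclose(np.vstack([H_I, H_G]), mean)

    def test_dominant_logit_selects_single_layer(self, rng):
        layers = [rng.random((5, 2)) for _ in range(3)]
        logits = np.array([0.0, 50.0, 0.0])
        H_I, H_G, a = attend(layers, logits, M=2)
        assert a[1] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.vstack([H_I, H_G]), layers[1], atol=1e-12)

    def test_weights_sum_to_one_for_random_logits(self, rng):
        for _ in range(10):
            _, _, a = attend([rng.random((4, 2))] * 3, rng.normal(size=3) * 5,
                             M=1)
            assert a.sum() == pytest.approx(1.0, abs=1e-12)
            assert (a > 0).all()


class TestDecode:
    def test_zero_embeddings_score_half(self):
        s = decode(np.zeros((3, 4)), np.zeros((5, 4)), np.eye(4))
        assert np.allclose(s, 0.5)

    def test_scalar_case(self):
        s = decode(np.array([[2.0]]), np.array([[3.0]]), np.array([[1.0]]))
        assert s[0, 0] == pytest.approx(1 / (1 + np.exp(-6.0)))

    def test_matches_triple_product_oracle(self, rng):
        H_I, H_G, W = rng.random((4, 3)), rng.random((6, 3)), rng.random((3, 3))
        s = decode(H_I, H_G, W)
        expected = 1 / (1 + np.exp(-(H_I @ W @ H_G.T)))
        assert np.abs(s - expected).max() < 1e-12

    def test_scores_strictly_inside_unit_interval(self, tiny_graph):
        cfg = ModelConfig(embed_dim=8, n_layers=3)
        state = make_state(tiny_graph, cfg)
        s = predict_scores(tiny_graph, state, cfg)
        assert np.all((s > 0) & (s < 1))
        assert np.all(np.isfinite(s))


class TestAblationVariants:
    def test_ave_equals_attend_with_equal_logits(self, tiny_graph):
        cfg_f = ModelConfig(embed_dim=4, n_layers=3, variant="full")
        state = make_state(tiny_graph, cfg_f)
        state.att_logits = np.zeros(3)
        cfg_a = cfg_f.with_variant("AVE")
        assert np.allclose(predict_scores(tiny_graph, state, cfg_f),
                           predict_scores(tiny_graph, state, cfg_a))

    def test_l1_with_single_layer_model_equals_full(self, tiny_graph):
        cfg_f = ModelConfig(embed_dim=4, n_layers=1, variant="full")
        state = make_state(tiny_graph, cfg_f)
        assert np.allclose(
            predict_scores(tiny_graph, state, cfg_f),
            predict_scores(tiny_graph, state, cfg_f.with_variant("L1")))

    def test_con_concatenates_layer_embeddings(self, tiny_graph):
        cfg = ModelConfig(embed_dim=4, n_layers=3, variant="CON")
        assert cfg.decoder_dim == 12
        state = make_state(tiny_graph, cfg)
        assert state.Wdec.shape == (12, 12)
        stack = encode(tiny_graph, state, cfg)
        Gn = symmetric_degree_normalize(tiny_graph.G)
        H0 = tiny_graph.H0.toarray()
        cache = M.forward(Gn, H0, state, cfg, *tiny_graph.block_sizes)
        assert cache.C.shape[1] == 12
        assert np.allclose(cache.C, np.hstack(stack.layers))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            ModelConfig(n_layers=3, variant="L4")


class TestPermutationEquivariance:
    def test_scores_permute_with_nodes(self, rng):
        from scipy import sparse

        from mtlink.hetgraph import AssociationMatrix, build_propagation_graph
        from mtlink.seqfeat import SimilarityMatrix

        m, n = 5, 7
        A_mat = (rng.random((m, n)) < 0.4).astype(float)
        Sm = rng.random((m, m))
        Sm = (Sm + Sm.T) / 2
        Sn = rng.random((n, n))
        Sn = (Sn + Sn.T) / 2

        def mk(Am, Smm, Snn):
            A = AssociationMatrix(
                matrix=sparse.csr_matrix(Am),
                mirna_ids=[f"m{i}" for i in range(m)],
                target_ids=[f"t{j}" for j in range(n)])
            return build_propagation_graph(
                A, SimilarityMatrix(matrix=Smm, measure="jaccard",
                                    normalized=True),
                SimilarityMatrix(matrix=Snn, measure="jaccard",
                                 normalized=True), mu=0.2)

        g = mk(A_mat, Sm, Sn)
        cfg = ModelConfig(embed_dim=4, n_layers=2)
        state = make_state(g, cfg)
        scores = predict_scores(g, state, cfg)

        pm, pn = rng.permutation(m), rng.permutation(n)
        g_p = mk(A_mat[np.ix_(pm, pn)], Sm[np.ix_(pm, pm)], Sn[np.ix_(pn, pn)])
        full = np.concatenate([pm, m + pn])
        state_p = M.ModelState(W0=state.W0[full], Ws=[w.copy() for w in state.Ws],
                               att_logits=state.att_logits.copy(),
                               Wdec=state.Wdec.copy())
        scores_p = predict_scores(g_p, state_p, cfg)
        assert np.allclose(scores_p, scores[np.ix_(pm, pn)], atol=1e-10)


class TestGradients:
    @pytest.mark.parametrize("variant", ["full", "AVE", "CON", "L2"])
    def test_analytic_gradients_match_finite_differences(self, tiny_graph,
                                                         tiny_dataset,
                                                         variant):
        """Central finite differences on the 5 x 7 fixture, rel err < 1e-4."""
        cfg = ModelConfig(embed_dim=4, n_layers=3, node_dropout=0,
                          edge_dropout=0, variant=variant)
        state = make_state(tiny_graph, cfg, seed=7)
        spec = LossSpec.from_association(tiny_dataset.A)
        Gn = symmetric_degree_normalize(tiny_graph.G)
        H0 = tiny_graph.H0.toarray().astype(float)
        Mb, Nb = tiny_graph.block_sizes

        def loss():
            cache = M.forward(Gn, H0, state, cfg, Mb, Nb)
            return weighted_cross_entropy(cache.scores, spec)

        cache = M.forward(Gn, H0, state, cfg, Mb, Nb)
        grads = M.backward(loss_gradient(cache.scores, spec), cache, state,
                           cfg)
        eps = 1e-6
        for name, p in state.params().items():
            flat_idx = range(0, p.size, max(1, p.size // 10))
            for t in flat_idx:
                ix = np.unravel_index(t, p.shape)
                orig = p[ix]
                p[ix] = orig + eps
                lp = loss()
                p[ix] = orig - eps
                lm = loss()
                p[ix] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads[name][ix]
                rel = abs(fd - an) / max(1e-8, abs(fd) + abs(an))
                assert rel < 1e-4, f"{variant}/{name}{ix}: fd={fd}, an={an}"


def test_checkpoint_round_trip(tiny_graph, tmp_path):
    cfg = ModelConfig(embed_dim=4, n_layers=3, variant="full", seed=5)
    state = make_state(tiny_graph, cfg, seed=5)
    path = tmp_path / "model.npz"
    save_checkpoint(path, state, cfg)
    state2, cfg2 = load_checkpoint(path)
    assert cfg2 == cfg
    assert np.array_equal(state2.W0, state.W0)
    assert all(np.array_equal(a, b) for a, b in zip(state2.Ws, state.Ws))
    assert np.array_equal(state2.Wdec, state.Wdec)
    assert np.allclose(predict_scores(tiny_graph, state2, cfg2),
                       predict_scores(tiny_graph, state, cfg))


def test_softmax_is_shift_invariant(rng):
    x = rng.normal(size=5) * 10
    assert np.allclose(softmax(x), softmax(x + 100))
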