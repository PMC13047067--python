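"""Forward-block semantics, estimator contract, and serialization."""

import numpy as np
import pytest
from sklearn.base import clone

from m1alink.model import (GCNLinkPredictor, ModelState, decode_pairs, full_forward,
                           gcn_forward, init_model_state, residual_combine,
                           self_attention)
from m1alink._autodiff import Tensor


@pytest.fixture
def tiny_state():
    rng = np.random.default_rng(5)
    return init_model_state(rng, n_features_m=4, n_features_d=3, n_layers=2,
                            hidden_dim=6, embed_dim=4, n_heads=2, mlp_hidden=(3, 5, 3))


def set_weights(state, name, value):
    state.params[name] = Tensor(np.asarray(value, dtype=float), requires_grad=True)


class TestGCNForward:
    def test_identity_propagation(self):
        rng = np.random.default_rng(0)
        state = init_model_state(rng, 3, 3, n_layers=1, hidden_dim=3, embed_dim=3,
                                 n_heads=1, mlp_hidden=(2,))
        set_weights(state, "gcn_m1a_W0", np.eye(3))
        h0 = np.abs(rng.normal(size=(5, 3)))
        out = gcn_forward(h0, np.eye(5), state, "m1a")
        np.testing.assert_allclose(out, h0)

    def test_relu_zeroes_negative_columns(self):
        rng = np.random.default_rng(0)
        state = init_model_state(rng, 2, 2, n_layers=1, hidden_dim=2, embed_dim=2,
                                 n_heads=1, mlp_hidden=(2,))
        set_weights(state, "gcn_m1a_W0", np.eye(2))
        h0 = np.array([[1.0, -2.0], [3.0, -4.0]])
        out = gcn_forward(h0, np.eye(2), state, "m1a")
        np.testing.assert_allclose(out, [[1.0, 0.0], [3.0, 0.0]])

    def test_two_layer_hand_computation(self):
        rng = np.random.default_rng(1)
        state = init_model_state(rng, 2, 2, n_layers=2, hidden_dim=3, embed_dim=2,
                                 n_heads=1, mlp_hidden=(2,))
        adj = np.array([[0.5, 0.5], [0.5, 0.5]])
        h0 = rng.normal(size=(2, 2))
        w0 = state["gcn_m1a_W0"].data
        w1 = state["gcn_m1a_W1"].data
        expected = np.maximum(adj @ np.maximum(adj @ h0 @ w0, 0) @ w1, 0)
        np.testing.assert_allclose(gcn_forward(h0, adj, state, "m1a"), expected)

    def test_output_nonnegative(self, tiny_state, rng):
        h0 = rng.normal(size=(7, 4))
        adj = np.abs(rng.normal(size=(7, 7)))
        adj = (adj + adj.T) / 2
        out = gcn_forward(h0, adj / adj.sum(), tiny_state, "m1a")
        assert (out >= 0).all()

    def test_shape_mismatch_raises(self, tiny_state):
        with pytest.raises(ValueError):
            gcn_forward(np.zeros((3, 4)), np.eye(5), tiny_state, "m1a")


class TestSelfAttention:
    def test_rows_are_probability_vectors(self, tiny_state, rng):
        h = rng.normal(size=(6, 4))
        _, weights = self_attention(h, tiny_state, "m1a", return_weights=True)
        assert len(weights) == 2  # one matrix per head
        for w in weights:
            assert (w >= 0).all()
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_single_node_passes_through_value_projection(self, tiny_state, rng):
        h = rng.normal(size=(1, 4))
        out = self_attention(h, tiny_state, "m1a")
        v_parts = [h @ tiny_state[f"att_m1a_V{k}"].data for k in range(2)]
        expected = np.concatenate(v_parts, axis=1) @ tiny_state["att_m1a_O"].data
        np.testing.assert_allclose(out, expected)

    def test_duplicated_nodes_get_identical_rows(self, tiny_state, rng):
        row = rng.normal(size=4)
        h = np.stack([row, row, rng.normal(size=4)])
        out = self_attention(h, tiny_state, "m1a")
        np.testing.assert_allclose(out[0], out[1])

    def test_indivisible_head_count_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="divide"):
            init_model_state(rng, 4, 4, n_layers=1, hidden_dim=4, embed_dim=6,
                             n_heads=4, mlp_hidden=(2,))


class TestResidualCombine:
    def test_zero_residual_weight_returns_attention(self, tiny_state, rng):
        set_weights(tiny_state, "residual_m1a", np.zeros((4, 4)))
        h_att, h_gcn = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        np.testing.assert_allclose(
            residual_combine(h_att, h_gcn, tiny_state, "m1a"), h_att)

    def test_identity_residual_with_zero_attention(self, tiny_state, rng):
        set_weights(tiny_state, "residual_m1a", np.eye(4))
        h_gcn = rng.normal(size=(5, 4))
        np.testing.assert_allclose(
            residual_combine(np.zeros((5, 4)), h_gcn, tiny_state, "m1a"), h_gcn)

    def test_matches_matrix_arithmetic(self, tiny_state, rng):
        h_att, h_gcn = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        expected = h_att + h_gcn @ tiny_state["residual_m1a"].data
        np.testing.assert_allclose(
            residual_combine(h_att, h_gcn, tiny_state, "m1a"), expected)

    def test_shape_mismatch_raises(self, tiny_state):
        with pytest.raises(ValueError):
            residual_combine(np.zeros((5, 4)), np.zeros((4, 4)), tiny_state, "m1a")


class TestDecodePairs:
    def test_zero_weights_give_half(self, tiny_state, rng):
        for k in range(4):
            w = tiny_state[f"mlp_W{k}"].data
            set_weights(tiny_state, f"mlp_W{k}", np.zeros_like(w))
        probs = decode_pairs(rng.normal(size=(3, 4)), rng.normal(size=(2, 4)),
                             [(0, 0), (2, 1)], tiny_state)
        np.testing.assert_allclose(probs, 0.5)

    def test_monotone_in_output_bias(self, tiny_state, rng):
        hm, hd = rng.normal(size=(3, 4)), rng.normal(size=(2, 4))
        pairs = [(0, 0), (1, 1)]
        probs = []
        for bias in (-2.0, 0.0, 2.0):
            set_weights(tiny_state, "mlp_b3", np.array([bias]))
            probs.append(decode_pairs(hm, hd, pairs, tiny_state))
        assert (probs[0] < probs[1]).all() and (probs[1] < probs[2]).all()
        assert (probs[0] > 0).all() and (probs[2] < 1).all()

    def test_matches_straight_line_oracle(self, tiny_state, rng):
        hm, hd = rng.normal(size=(3, 4)), rng.normal(size=(2, 4))
        pairs = [(1, 0), (2, 1)]
        x = np.concatenate([hm[[1, 2]], hd[[0, 1]]], axis=1)
        for k in range(3):
            x = np.maximum(x @ tiny_state[f"mlp_W{k}"].data
                           + tiny_state[f"mlp_b{k}"].data, 0)
        logits = x @ tiny_state["mlp_W3"].data + tiny_state["mlp_b3"].data
        expected = 1 / (1 + np.exp(-logits.ravel()))
        np.testing.assert_allclose(decode_pairs(hm, hd, pairs, tiny_state), expected)

    def test_out_of_range_pair_raises(self, tiny_state, rng):
        with pytest.raises(IndexError):
            decode_pairs(rng.normal(size=(3, 4)), rng.normal(size=(2, 4)),
                         [(3, 0)], tiny_state)


class TestFullForward:
    @pytest.fixture
    def toy_inputs(self, rng):
        fm, fd = rng.random((6, 4)), rng.random((4, 3))
        am = np.abs(rng.normal(size=(6, 6)))
        am = (am + am.T) / 10
        ad = np.abs(rng.normal(size=(4, 4)))
        ad = (ad + ad.T) / 10
        pairs = np.array([(0, 1), (5, 3), (2, 0)])
        return fm, fd, am, ad, pairs

    def test_deterministic_and_permutation_consistent(self, tiny_state, toy_inputs):
        fm, fd, am, ad, pairs = toy_inputs
        p1 = full_forward(fm, fd, am, ad, pairs, tiny_state)
        p2 = full_forward(fm, fd, am, ad, pairs, tiny_state)
        np.testing.assert_array_equal(p1, p2)
        perm = [2, 0, 1]
        p3 = full_forward(fm, fd, am, ad, pairs[perm], tiny_state)
        np.testing.assert_array_equal(p3, p1[perm])

    def test_equals_composition_of_blocks(self, tiny_state, toy_inputs):
        fm, fd, am, ad, pairs = toy_inputs
        hm_gcn = gcn_forward(fm, am, tiny_state, "m1a")
        hd_gcn = gcn_forward(fd, ad, tiny_state, "disease")
        hm = residual_combine(self_attention(hm_gcn, tiny_state, "m1a"),
                              hm_gcn, tiny_state, "m1a")
        hd = residual_combine(self_attention(hd_gcn, tiny_state, "disease"),
                              hd_gcn, tiny_state, "disease")
        expected = decode_pairs(hm, hd, pairs, tiny_state)
        np.testing.assert_allclose(full_forward(fm, fd, am, ad, pairs, tiny_state),
                                   expected)


class TestModelState:
    def test_save_load_round_trip(self, tiny_state, tmp_path, rng):
        fm, fd = rng.random((5, 4)), rng.random((3, 3))
        am, ad = np.eye(5), np.eye(3)
        pairs = [(0, 0), (4, 2)]
        before = full_forward(fm, fd, am, ad, pairs, tiny_state)
        tiny_state.save(tmp_path / "ckpt")
        reloaded = ModelState.load(tmp_path / "ckpt")
        after = full_forward(fm, fd, am, ad, pairs, reloaded)
        np.testing.assert_array_equal(before, after)


class TestEstimator:
    @pytest.fixture
    def toy_problem(self, rng):
        n_m, n_d = 12, 6
        fm, fd = rng.random((n_m, n_m)), rng.random((n_d, n_d))
        am = np.abs(rng.normal(size=(n_m, n_m)))
        am = (am + am.T) / (2 * n_m)
        ad = np.abs(rng.normal(size=(n_d, n_d)))
        ad = (ad + ad.T) / (2 * n_d)
        X = np.array([(i, j) for i in range(n_m) for j in range(n_d)])
        y = ((X[:, 0] % 2) == (X[:, 1] % 2)).astype(float)
        return fm, fd, am, ad, X, y

    def _fit(self, toy_problem, **kw):
        fm, fd, am, ad, X, y = toy_problem
        est = GCNLinkPredictor(n_layers=2, hidden_dim=8, embed_dim=8, n_heads=2,
                               mlp_hidden=(4, 6, 4), epochs=30, random_state=0, **kw)
        return est.fit(X, y, adj_m=am, adj_d=ad, features_m=fm, features_d=fd), X, y

    def test_fit_reduces_loss_and_predicts_probabilities(self, toy_problem):
        est, X, y = self._fit(toy_problem)
        assert est.loss_history_[-1] < est.loss_history_[0]
        proba = est.predict_proba(X)
        assert proba.shape == (len(X), 2)
        assert ((proba > 0) & (proba < 1)).all()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_same_seed_is_bit_reproducible(self, toy_problem):
        est1, X, _ = self._fit(toy_problem)
        est2, _, _ = self._fit(toy_problem)
        assert est1.loss_history_ == est2.loss_history_
        np.testing.assert_array_equal(est1.predict_proba(X), est2.predict_proba(X))

    def test_sklearn_clone_and_get_params(self):
        est = GCNLinkPredictor(epochs=5, random_state=3)
        params = est.get_params()
        assert params["epochs"] == 5 and params["focal_alpha"] == 0.25
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_invalid_pair_array_rejected(self, toy_problem):
        fm, fd, am, ad, X, y = toy_problem
        est = GCNLinkPredictor(epochs=1, random_state=0)
        with pytest.raises(ValueError, match="n_pairs"):
            est.fit(np.zeros((4, 3)), np.zeros(4), adj_m=am, adj_d=ad,
                    features_m=fm, features_d=fd)
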