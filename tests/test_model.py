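"""Encoder contracts: time embedding, loop-oracle equality, causality,
rollout semantics, event scores, normalized risk."""

import numpy as np
import pytest

from jointmm._autodiff import Tensor
from jointmm.model import (JointTransformer, normalized_risk, time_embedding,
                           time_embedding_matrix)


def loop_encode(model, B, X, M, A):
    """Independent loop-based re-computation of the encoder: explicit
    per-patient, per-query attention restricted to keys at periods <= t."""
    p = {k: t.data for k, t in model.params_.items()}
    n, T, _ = X.shape
    D, H = model.hidden_dim, model.n_heads
    dh = D // H
    tau, tmax = model.dims_["tau"], model.dims_["t_max"]

    def ln(v, g, b):
        mu = v.mean()
        var = ((v - mu) ** 2).mean()
        return (v - mu) / np.sqrt(var + 1e-5) * g + b

    out = np.zeros((n, T, D))
    for i in range(n):
        z = np.zeros((T, D))
        for t in range(T):
            vec = np.concatenate([B[i], X[i, t], M[i, t], A[i, t],
                                  time_embedding(t, tau, tmax)])
            z[t] = vec @ p["W_in"] + p["b_in"]
        for l in range(model.n_layers):
            h = np.stack([ln(z[t], p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
                          for t in range(T)])
            att = np.zeros((T, D))
            for t in range(T):
                pieces = []
                for head in range(H):
                    sl = slice(head * dh, (head + 1) * dh)
                    q = (h[t] @ p[f"l{l}.Wq"])[sl]
                    scores = [q @ (h[t2] @ p[f"l{l}.Wk"])[sl] / np.sqrt(dh)
                              for t2 in range(t + 1)]
                    w = np.exp(np.asarray(scores) - max(scores))
                    w /= w.sum()
                    acc = np.zeros(dh)
                    for t2 in range(t + 1):
                        acc += w[t2] * (h[t2] @ p[f"l{l}.Wv"])[sl]
                    pieces.append(acc)
                att[t] = np.concatenate(pieces) @ p[f"l{l}.Wo"] + p[f"l{l}.bo"]
            z = z + att
            for t in range(T):
                h2 = ln(z[t], p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
                ff = (np.maximum(0.0, h2 @ p[f"l{l}.W1"] + p[f"l{l}.c1"])
                      @ p[f"l{l}.W2"] + p[f"l{l}.c2"])
                z[t] = z[t] + ff
        out[i] = z
    return out


class TestTimeEmbedding:
    def test_fixed_values(self):
        e0 = time_embedding(0, 4, 20.0)
        assert e0[0] == 0.0 and e0[1] == 1.0  # sin(0), cos(0)
        for tmax in (5.0, 24.0, 100.0):
            assert time_embedding(1, 6, tmax)[0] == pytest.approx(np.sin(1.0))

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            time_embedding(0, 5, 10.0)
        with pytest.raises(ValueError):
            time_embedding(-1, 4, 10.0)

    def test_matrix_shape(self):
        assert time_embedding_matrix(7, 8, 24.0).shape == (7, 8)


class TestEncoder:
    @pytest.mark.parametrize("n_heads", [1, 2])
    def test_matches_loop_oracle(self, n_heads):
        model = JointTransformer(hidden_dim=4, n_layers=2, n_heads=n_heads,
                                 tau=2, dropout=0.0, t_max=8.0, random_state=5)
        model.build(d_base=2, n_vars=1, d_treat=1, n_periods=3)
        rng = np.random.default_rng(3)
        B, X = rng.normal(size=(3, 2)), rng.normal(size=(3, 3, 1))
        M, A = np.ones((3, 3, 1)), rng.normal(size=(3, 3, 1))
        z = model.encode(B, X, M, A).data
        assert np.allclose(z, loop_encode(model, B, X, M, A), atol=1e-6)

    def test_single_period_softmax_is_trivial(self, tiny_model):
        rng = np.random.default_rng(0)
        B, X = rng.normal(size=(2, 2)), rng.normal(size=(2, 1, 1))
        M, A = np.ones((2, 1, 1)), rng.normal(size=(2, 1, 1))
        z = tiny_model.encode(B, X, M, A).data
        assert np.allclose(z, loop_encode(tiny_model, B, X, M, A), atol=1e-10)

    def test_empty_sequence_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.encode(np.zeros((1, 2)), np.zeros((1, 0, 1)),
                              np.zeros((1, 0, 1)), np.zeros((1, 0, 1)))

    def test_causality_under_future_perturbation(self, tiny_model, tiny_inputs):
        B, X, M, A = tiny_inputs
        z = tiny_model.encode(B, X, M, A).data
        X2, A2 = X.copy(), A.copy()
        X2[:, 2:], A2[:, 2:] = 99.0, -99.0
        z2 = tiny_model.encode(B, X2, M, A2).data
        assert np.allclose(z[:, :2], z2[:, :2], atol=1e-12)
        assert not np.allclose(z[:, 2:], z2[:, 2:])

    def test_masked_value_still_enters_embedding(self, tiny_model, tiny_inputs):
        """The mask is an input channel, not a filter: changing a value at an
        M=0 entry changes the state (values there are imputed upstream)."""
        B, X, M, A = tiny_inputs
        M = M.copy()
        M[:, 1] = 0.0
        z = tiny_model.encode(B, X, M, A).data
        X2 = X.copy()
        X2[:, 1] += 1.0
        assert not np.allclose(tiny_model.encode(B, X2, M, A).data[:, 1], z[:, 1])


class TestHeads:
    def test_zero_weight_forecast_head_returns_zero(self, tiny_model):
        for k in ("pred.W1", "pred.b1", "pred.W2", "pred.b2"):
            tiny_model.params_[k].data[:] = 0.0
        out = tiny_model.forecast_next(Tensor(np.ones((3, 4))))
        assert np.array_equal(out.data, np.zeros((3, 1)))

    def test_affine_forecast_head_identity(self):
        model = JointTransformer(hidden_dim=2, nonlinear_head=False,
                                 tau=2, random_state=0)
        model.build(d_base=1, n_vars=2, d_treat=1, n_periods=3)
        model.params_["pred.W"].data = np.eye(2)
        model.params_["pred.b"].data[:] = 0.0
        z = np.array([[0.3, -1.2]])
        assert np.allclose(model.forecast_next(Tensor(z)).data, z)

    def test_event_score_linear_head_hand_computed(self):
        model = JointTransformer(hidden_dim=2, n_layers=1, nonlinear_head=False,
                                 tau=2, rollout_window=1, t_max=8.0,
                                 random_state=1)
        model.build(d_base=1, n_vars=1, d_treat=1, n_periods=4)
        w = np.array([[0.5], [-1.0], [2.0], [0.25]])
        model.params_["head.pfs.W"].data = w
        model.params_["head.pfs.b"].data[:] = 0.5
        rng = np.random.default_rng(2)
        B, X = rng.normal(size=(2, 1)), rng.normal(size=(2, 3, 1))
        M, A = np.ones((2, 3, 1)), rng.normal(size=(2, 3, 1))
        feats = model.event_features(B, X, M, A, t_cond=2)
        expected = feats @ w[:, 0] + 0.5
        assert np.allclose(model.event_score(B, X, M, A, 2, "pfs"), expected)

    def test_event_score_causal_in_observed_future(self, tiny_model, tiny_inputs):
        B, X, M, A = tiny_inputs
        y = tiny_model.event_score(B, X, M, A, 2, "pfs")
        X2 = X.copy()
        X2[:, 2:] = 123.0  # observed data after the conditioning time
        assert np.allclose(tiny_model.event_score(B, X2, M, A, 2, "pfs"), y)

    def test_rollout_window_zero_uses_only_current_state(self, tiny_inputs):
        model = JointTransformer(hidden_dim=4, rollout_window=0, tau=2,
                                 t_max=8.0, random_state=5)
        B, X, M, A = tiny_inputs
        model.build(B.shape[1], X.shape[2], A.shape[2], X.shape[1])
        feats = model.event_features(B, X, M, A, t_cond=2)
        z = model.encode(B, X[:, :2], M[:, :2], A[:, :2]).data
        assert np.array_equal(feats, z[:, 1])

    def test_unknown_event_type(self, tiny_model, tiny_inputs):
        with pytest.raises(ValueError):
            tiny_model.event_score(*tiny_inputs, 1, "relapse")


class TestRollout:
    def test_horizon_one_equals_forecast_next(self, tiny_model, tiny_inputs):
        B, X, M, A = tiny_inputs
        pred = tiny_model.rollout(B, X, M, A, t_cond=2, horizon=1)
        z = tiny_model.encode(B, X[:, :2], M[:, :2], A[:, :2])
        direct = tiny_model.forecast_next(z[:, -1]).data
        assert np.allclose(pred[:, 0], direct)

    def test_two_step_hand_unrolled(self, tiny_model, tiny_inputs):
        B, X, M, A = tiny_inputs
        pred = tiny_model.rollout(B, X, M, A, t_cond=1, horizon=2)
        # manual unroll: feed the first prediction back with mask set observed
        z1 = tiny_model.encode(B, X[:, :1], M[:, :1], A[:, :1])
        x1 = tiny_model.forecast_next(z1[:, -1]).data
        X_ext = np.concatenate([X[:, :1], x1[:, None]], axis=1)
        M_ext = np.concatenate([M[:, :1], np.ones_like(M[:, :1])], axis=1)
        z2 = tiny_model.encode(B, X_ext, M_ext, A[:, :2])
        x2 = tiny_model.forecast_next(z2[:, -1]).data
        assert np.allclose(pred, np.stack([x1, x2], axis=1))

    def test_future_observations_never_used(self, tiny_model, tiny_inputs):
        B, X, M, A = tiny_inputs
        pred = tiny_model.rollout(B, X, M, A, t_cond=1, horizon=3)
        X2 = X.copy()
        X2[:, 1:] = -77.0
        assert np.array_equal(pred, tiny_model.rollout(B, X2, M, A, 1, 3))

    def test_deterministic(self, tiny_model, tiny_inputs):
        a = tiny_model.rollout(*tiny_inputs, t_cond=2, horizon=2)
        b = tiny_model.rollout(*tiny_inputs, t_cond=2, horizon=2)
        assert np.array_equal(a, b)

    def test_short_treatment_plan_rejected(self, tiny_model, tiny_inputs):
        B, X, M, A = tiny_inputs
        with pytest.raises(ValueError, match="treatment plan"):
            tiny_model.rollout(B, X, M, A[:, :2], t_cond=2, horizon=3)

    def test_literal_input_reuse_flag(self, tiny_inputs):
        B, X, M, A = tiny_inputs
        kw = dict(hidden_dim=4, tau=2, t_max=8.0, random_state=5, dropout=0.0)
        default = JointTransformer(**kw)
        default.build(B.shape[1], X.shape[2], A.shape[2], X.shape[1])
        literal = JointTransformer(literal_rollout_inputs=True, **kw)
        literal.build(B.shape[1], X.shape[2], A.shape[2], X.shape[1])
        literal.set_weights(default.get_weights())
        one_d = default.rollout(B, X, M, A, 1, 1)
        one_l = literal.rollout(B, X, M, A, 1, 1)
        assert np.allclose(one_d, one_l)  # first step identical by construction
        two_d = default.rollout(B, X, M, A, 1, 2)
        two_l = literal.rollout(B, X, M, A, 1, 2)
        assert not np.allclose(two_d[:, 1], two_l[:, 1])


class TestNormalizedRisk:
    def test_linear_map_and_clipping(self):
        train = [1.0, 3.0, 5.0]
        assert normalized_risk(1.0, train) == 0.0
        assert normalized_risk(5.0, train) == 1.0
        assert normalized_risk(3.0, train) == 0.5
        assert normalized_risk(9.0, train) == 1.0
        assert normalized_risk(-2.0, train) == 0.0

    def test_degenerate_train_scores(self):
        with pytest.raises(ValueError):
            normalized_risk(0.5, [2.0, 2.0])
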