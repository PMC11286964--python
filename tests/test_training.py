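"""Losses against enumeration oracles; two-stage training contracts."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jointmm import training
from jointmm._autodiff import Tensor
from jointmm.cohort import SurvivalOutcomes
from jointmm.model import JointTransformer
from jointmm.training import (cox_event_loss, default_grid, finetune_heads,
                              fit_bagged_ensemble, forecast_loss, pretrain,
                              tune_hyperparameters, BaggedEnsemble)


def brute_force_cox(scores, times, events):
    """Explicit risk-set loops: negative Breslow partial log-likelihood."""
    total = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        denom = sum(np.exp(scores[j]) for j in range(len(times))
                    if times[j] >= times[i])
        total += scores[i] - np.log(denom)
    return -total


class TestForecastLoss:
    def test_perfect_prediction_is_zero(self):
        X = np.random.default_rng(0).normal(size=(3, 4, 2))
        assert forecast_loss(X, X, np.ones_like(X)) == 0.0

    def test_hand_computed_masked_mean(self):
        X = np.array([[[1.0], [2.0]]])
        X_hat = np.zeros((1, 2, 1))
        M = np.array([[[1.0], [0.0]]])
        assert forecast_loss(X, X_hat, M) == pytest.approx(1.0)

    def test_explicit_sum_two_patients(self):
        X = np.array([[[1.0, 2.0], [3.0, 4.0]], [[0.0, 0.0], [1.0, 1.0]]])
        X_hat = X - 0.5
        M = np.array([[[1.0, 1.0], [0.0, 1.0]], [[1.0, 0.0], [1.0, 1.0]]])
        # per patient: sum(M * 0.25) / sum(M), then averaged
        expected = 0.5 * (3 * 0.25 / 3 + 3 * 0.25 / 3)
        assert forecast_loss(X, X_hat, M) == pytest.approx(expected)

    def test_masked_entries_do_not_contribute(self):
        rng = np.random.default_rng(1)
        X, X_hat = rng.normal(size=(2, 3, 2)), rng.normal(size=(2, 3, 2))
        M = (rng.uniform(size=(2, 3, 2)) > 0.4).astype(float)
        base = forecast_loss(X, X_hat, M)
        X2 = X.copy()
        X2[M == 0] = 1e6
        assert forecast_loss(X2, X_hat, M) == pytest.approx(base)

    def test_zero_observation_patient_excluded_with_warning(self):
        X = np.ones((2, 2, 1))
        M = np.stack([np.ones((2, 1)), np.zeros((2, 1))])
        with pytest.warns(UserWarning, match="zero observed"):
            val = forecast_loss(X, np.zeros_like(X), M)
        assert val == pytest.approx(1.0)


class TestCoxLoss:
    def test_two_patient_hand_value(self):
        o = SurvivalOutcomes([1.0, 2.0], [1, 1])
        assert cox_event_loss(np.zeros(2), o) == pytest.approx(np.log(2))

    def test_single_event_is_zero(self):
        assert cox_event_loss([1.7], SurvivalOutcomes([2.0], [1])) == pytest.approx(0.0)

    @given(st.floats(-3, 3))
    @settings(max_examples=20, deadline=None)
    def test_shift_invariance(self, c):
        rng = np.random.default_rng(4)
        s = rng.normal(size=5)
        o = SurvivalOutcomes(rng.integers(1, 6, size=5).astype(float),
                             [1, 0, 1, 1, 0])
        assert cox_event_loss(s + c, o) == pytest.approx(cox_event_loss(s, o))

    @pytest.mark.parametrize("events", [(1, 1, 1, 1), (1, 0, 1, 1), (0, 1, 1, 0)])
    def test_enumeration_oracle_all_orderings(self, events):
        rng = np.random.default_rng(7)
        s = rng.normal(size=4)
        for times in itertools.permutations([1.0, 2.0, 3.0, 4.0]):
            o = SurvivalOutcomes(np.array(times), np.array(events))
            assert cox_event_loss(s, o) == pytest.approx(
                brute_force_cox(s, times, events), abs=1e-12)

    def test_ties_use_breslow_risk_sets(self):
        # two events at the same time share the identical risk set
        s = np.array([0.5, -0.2, 0.1])
        o = SurvivalOutcomes([2.0, 2.0, 3.0], [1, 1, 1])
        assert cox_event_loss(s, o) == pytest.approx(
            brute_force_cox(s, [2.0, 2.0, 3.0], [1, 1, 1]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(9)
        for n in (3, 6):
            times = rng.integers(1, 5, size=n).astype(float)
            events = (rng.uniform(size=n) < 0.7).astype(int)
            events[0] = 1
            o = SurvivalOutcomes(times, events)
            s = Tensor(rng.normal(size=n), requires_grad=True)
            cox_event_loss(s, o).backward()
            num = np.zeros(n)
            for i in range(n):
                eps = 1e-6
                s.data[i] += eps
                lp = cox_event_loss(s.data, o)
                s.data[i] -= 2 * eps
                lm = cox_event_loss(s.data, o)
                s.data[i] += eps
                num[i] = (lp - lm) / (2 * eps)
            assert np.allclose(s.grad, num, atol=1e-4)

    def test_landmark_weighted_hand_value(self):
        # times (1,2) both events, horizon 2: event 1 weighted 1 + 1/2, event 2 by 1/2
        o = SurvivalOutcomes([1.0, 2.0], [1, 1])
        val = cox_event_loss(np.zeros(2), o, landmark_weighted=True, t_max=2)
        assert val == pytest.approx(1.5 * np.log(2))

    def test_error_cases(self):
        with pytest.raises(ValueError, match="at least one"):
            cox_event_loss([0.1, 0.2], SurvivalOutcomes([1.0, 2.0], [0, 0]))
        with pytest.raises(ValueError, match="non-finite"):
            cox_event_loss([np.nan, 0.2], SurvivalOutcomes([1.0, 2.0], [1, 0]))


class TestPretrain:
    def test_zero_epochs_leaves_model_unchanged(self, prep):
        m = JointTransformer(hidden_dim=8, random_state=0)
        B, X, M, A = prep.inputs
        m.build(B.shape[1], X.shape[2], A.shape[2], X.shape[1])
        before = m.get_weights()
        pretrain(m, prep.inputs, epochs=0, seed=0)
        after = m.get_weights()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_fixed_seed_reproduces_loss_curve(self, prep):
        def run():
            m = JointTransformer(hidden_dim=8, random_state=3)
            pretrain(m, prep.inputs, epochs=5, seed=3)
            return m.pretrain_history_["train"]

        assert run() == run()

    def test_converges_on_noise_free_dynamics(self):
        from jointmm.pipeline import prepare_cohort
        from jointmm.simulate import SimConfig, generate_cohort

        c = generate_cohort(SimConfig(n_patients=80, n_periods=8, seed=5,
                                      noise_sd=0.0, missingness=0.0,
                                      baseline_missingness=0.0))
        p = prepare_cohort(c)
        m = JointTransformer(hidden_dim=16, dropout=0.0, random_state=0)
        pretrain(m, p.inputs, epochs=150, seed=0)
        h = m.pretrain_history_["train"]
        assert h[-1] < 0.05 * h[0]

    def test_early_stopping_on_validation(self, prep):
        """Overfitting a 4-patient training set degrades held-out loss, which
        must trigger the patience stop and restore the best weights."""
        m = JointTransformer(hidden_dim=16, dropout=0.0, random_state=1)
        B, X, M, A = prep.inputs
        val = (B[50:100], X[50:100], M[50:100], A[50:100])
        pretrain(m, (B[:4], X[:4], M[:4], A[:4]), epochs=500, seed=1,
                 val_inputs=val, patience=5)
        hist = m.pretrain_history_["val"]
        assert len(hist) < 500
        from jointmm.training import validation_forecast_loss
        assert validation_forecast_loss(m, val) == pytest.approx(min(hist))


class TestFinetune:
    def test_backbone_frozen_and_forecasts_unchanged(self, prep, trained_model):
        m = JointTransformer(**trained_model.get_params())
        B, X, M, A = prep.inputs
        m.build(B.shape[1], X.shape[2], A.shape[2], X.shape[1])
        m.set_weights(trained_model.get_weights())
        before = {k: v.tobytes() for k, v in m.get_weights().items()
                  if not k.startswith("head.")}
        roll_before = m.rollout(B, X, M, A, 1, 4)
        finetune_heads(m, prep.inputs, prep.outcomes["pfs"], "pfs",
                       epochs=30, seed=0)
        after = m.get_weights()
        for k, blob in before.items():
            assert after[k].tobytes() == blob
        assert np.array_equal(m.rollout(B, X, M, A, 1, 4), roll_before)

    def test_signal_recovery_above_chance(self, prep, trained_model):
        from jointmm.evaluation import averaged_cindex

        s = trained_model.event_score(*prep.inputs, t_cond=1, event_type="pfs")
        assert averaged_cindex(s, prep.outcomes["pfs"]) > 0.55

    def test_ae_head_trains_twelve_outputs_jointly(self, prep):
        m = JointTransformer(hidden_dim=8, random_state=2, rollout_window=0)
        B, X, M, A = prep.inputs
        m.build(B.shape[1], X.shape[2], A.shape[2], X.shape[1])
        finetune_heads(m, prep.inputs, prep.outcomes["ae"], "ae", epochs=5, seed=0)
        out = m.event_score(B, X, M, A, 1, "ae")
        assert out.shape == (len(B), 12)

    def test_head_restart_snapshots_differ(self, prep, trained_model):
        m = JointTransformer(**trained_model.get_params())
        B, X, M, A = prep.inputs
        m.build(B.shape[1], X.shape[2], A.shape[2], X.shape[1])
        m.set_weights(trained_model.get_weights())
        snaps = training.finetune_heads_ensemble(
            m, prep.inputs, prep.outcomes["pfs"], "pfs", n_restarts=2,
            epochs=10, seed=0)
        assert len(snaps) == 2
        k = next(iter(snaps[0]))
        assert not np.array_equal(snaps[0][k], snaps[1][k])


class TestBagging:
    def test_aggregate_mean_and_spread(self):
        class Stub:
            def __init__(self, v):
                self.v = v

        ens = BaggedEnsemble([Stub(1.0), Stub(1.0), Stub(1.0)])
        mean, sd = ens.aggregate(lambda m: np.full(4, m.v))
        assert np.array_equal(mean, np.ones(4)) and np.array_equal(sd, np.zeros(4))

    def test_resample_size_is_1p5x(self, prep):
        ens = fit_bagged_ensemble(prep.inputs, None,
                                  JointTransformer(hidden_dim=8, random_state=0),
                                  n_bags=2, seed=0, pretrain_epochs=1)
        assert len(ens.models) == 2
        assert all(len(idx) == round(1.5 * len(prep.B)) for idx in ens.bag_indices_)

    def test_single_bag_warns(self, prep):
        with pytest.warns(UserWarning, match="fewer than 2 bags"):
            fit_bagged_ensemble(prep.inputs, None,
                                JointTransformer(hidden_dim=8, random_state=0),
                                n_bags=1, seed=0, pretrain_epochs=1)


class TestTuning:
    def test_default_grid_has_sixteen_configurations(self):
        grid = default_grid()
        assert len(grid) == 16
        assert all(g["n_layers"] == 2 for g in grid)
        assert {g["rollout_window"] for g in grid} == {0, 1}

    def test_rollout_window_default_is_one(self):
        assert JointTransformer().rollout_window == 1

    def test_singleton_grid_returned(self):
        cfg, table = tune_hyperparameters([{"hidden_dim": 16}], lambda c: [1.0])
        assert cfg == {"hidden_dim": 16} and len(table) == 1

    def test_argmin_selection_and_empty_grid(self):
        objectives = {16: [0.3, 0.4], 32: [0.1, 0.2]}
        cfg, _ = tune_hyperparameters(
            [{"hidden_dim": h} for h in (16, 32)],
            lambda c: objectives[c["hidden_dim"]])
        assert cfg["hidden_dim"] == 32
        with pytest.raises(ValueError):
            tune_hyperparameters([], lambda c: [0.0])
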