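"""Two-stage optimization: forecasting pre-training, then event-head
fine-tuning with a frozen backbone; plus bootstrap aggregation and grid
search over the encoder hyperparameters.

Pre-training minimizes the masked forecasting loss teacher-forced (the
model always sees observed inputs, predictions are compared one step
ahead).  Fine-tuning freezes every backbone weight and trains only the
selected event head against the negative Breslow partial log-likelihood
of the Cox model; head inputs are the (frozen) hidden-state features, so
they are precomputed once and the stage is cheap.  Ties in event times
are handled by Breslow's convention.  Both stages use Adam, full-batch at
these cohort sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor
from .cohort import SurvivalOutcomes
from .model import EVENT_HEADS, JointTransformer

__all__ = ["forecast_loss", "cox_event_loss", "pretrain", "finetune_heads",
           "BaggedEnsemble", "fit_bagged_ensemble", "tune_hyperparameters",
           "default_grid"]


# --------------------------------------------------------------------- losses
def _forecast_weights(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    denom = M.sum(axis=(1, 2))
    valid = denom > 0
    if not valid.any():
        raise ValueError("no observed entries in any patient")
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} patient(s) with zero observed entries "
                      "excluded from the forecasting loss")
    w = np.zeros_like(denom)
    w[valid] = 1.0 / (valid.sum() * denom[valid])
    return w, valid


def forecast_loss(X, X_hat, M):
    """Masked per-patient-normalized squared error, averaged over patients.

    Each patient contributes sum_t M(t) * (X(t) - X_hat(t))^2 divided by the
    patient's observed-entry count; masked entries contribute nothing.
    """
    X = np.asarray(X, float)
    M = np.asarray(M, float)
    w, _ = _forecast_weights(M)
    if isinstance(X_hat, Tensor):
        err = Tensor(X) - X_hat
        return ((err * err) * Tensor(M * w[:, None, None])).sum()
    X_hat = np.asarray(X_hat, float)
    return float((M * (X - X_hat) ** 2 * w[:, None, None]).sum())


def _cox_terms(scores: Tensor, outcomes: SurvivalOutcomes):
    ev = np.flatnonzero(outcomes.event == 1)
    if len(ev) == 0:
        raise ValueError("Cox loss needs at least one observed event")
    # Breslow risk sets: all patients with observed time >= y_i
    riskmat = (outcomes.time[None, :] >= outcomes.time[ev, None]).astype(float)
    log_denoms = (Tensor(riskmat) @ scores.exp()).log()
    return ev, scores[ev] - log_denoms


def cox_event_loss(scores, outcomes: SurvivalOutcomes,
                   landmark_weighted: bool = False, t_max: int | None = None):
    """Negative Breslow partial log-likelihood of Cox scores (lower = better).

    With `landmark_weighted`, per-event contributions are re-weighted by the
    sum over landmark times t of 1(y_i <= t) / #(events by t), an aggregation
    of repeated partial likelihoods over landmarks; the default is the plain
    partial likelihood.  Shift-invariant in the scores.
    """
    is_tensor = isinstance(scores, Tensor)
    s = scores if is_tensor else Tensor(np.asarray(scores, float))
    if not np.all(np.isfinite(s.data)):
        raise ValueError("non-finite Cox scores")
    ev, contrib = _cox_terms(s, outcomes)
    if landmark_weighted:
        t_max = int(t_max if t_max is not None else outcomes.time.max())
        times_ev = outcomes.time[ev]
        omega = np.zeros(len(ev))
        for t in range(1, t_max + 1):
            n_by_t = (times_ev <= t).sum()
            if n_by_t > 0:
                omega += (times_ev <= t) / n_by_t
        loss = -(contrib * Tensor(omega)).sum()
    else:
        loss = -contrib.sum()
    return loss if is_tensor else loss.item()


# ------------------------------------------------------------------- pretrain
def pretrain(model: JointTransformer, inputs, epochs: int, lr: float = 1e-3,
             seed: int = 0, val_inputs=None, patience: int = 10):
    """Minimize the forecasting loss over backbone + forecasting-head weights.

    Teacher forcing: hidden states are computed from observed inputs; the
    prediction at t is compared with the observation at t + 1.  Logs a loss
    curve (and a validation curve when `val_inputs` is given, with early
    stopping on it).
    """
    B, X, M, A = (np.asarray(a, float) for a in inputs)
    if not hasattr(model, "params_"):
        model.build(B.shape[1], X.shape[2], A.shape[2], X.shape[1])
    params = {k: model.params_[k] for k in model.backbone_names_}
    opt = Adam(params, lr=lr)
    rng = np.random.default_rng((seed, 1))
    history, val_history = [], []
    best_val, best_weights, wait = np.inf, None, 0
    for epoch in range(epochs):
        opt.zero_grad()
        z = model.encode(B, X, M, A, train=True, rng=rng)
        x_hat = model.forecast_next(z[:, :-1])
        loss = forecast_loss(X[:, 1:], x_hat, M[:, 1:])
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"forecasting loss diverged at epoch {epoch}: {loss.item()!r}")
        loss.backward()
        opt.step()
        history.append(loss.item())
        if val_inputs is not None:
            val_history.append(validation_forecast_loss(model, val_inputs))
            if val_history[-1] < best_val - 1e-9:
                best_val, wait = val_history[-1], 0
                best_weights = model.get_weights()
            else:
                wait += 1
                if wait > patience:
                    model.set_weights(best_weights)
                    break
    model.pretrain_history_ = {"train": history, "val": val_history}
    return model


def validation_forecast_loss(model: JointTransformer, inputs) -> float:
    B, X, M, A = (np.asarray(a, float) for a in inputs)
    z = model.encode(B, X, M, A)
    x_hat = model.forecast_next(z[:, :-1])
    return forecast_loss(X[:, 1:], x_hat.data, M[:, 1:])


# ------------------------------------------------------------------- finetune
def _landmark_subsets(outcomes: SurvivalOutcomes, landmarks):
    for t_cond in landmarks:
        idx = np.flatnonzero(outcomes.time >= t_cond)
        yield t_cond, idx


def reinit_head(model: JointTransformer, event_type: str, seed: int):
    """Re-draw one event head's weights (for restart averaging); the
    backbone is untouched."""
    rng = np.random.default_rng(seed)
    for k in model.head_names(event_type):
        t = model.params_[k]
        if t.data.ndim == 2:
            s = np.sqrt(2.0 / sum(t.data.shape))
            t.data = rng.normal(0.0, s, size=t.data.shape)
        else:
            t.data = np.zeros_like(t.data)
    return model


def finetune_heads(model: JointTransformer, inputs, outcomes, event_type: str,
                   epochs: int, lr: float = 1e-2, seed: int = 0,
                   landmarks=(1,), landmark_weighted: bool = False,
                   weight_decay: float = 0.0):
    """Train one event head on the Cox loss; every backbone weight is frozen.

    `outcomes` is a SurvivalOutcomes for 'pfs'/'os', or a list of 12 for
    'ae' (optimized jointly with a summed loss; categories without any
    observed event are skipped with a warning).  Head features are the
    frozen hidden states at each landmark's conditioning time, restricted
    to patients still at risk there.
    """
    if event_type not in EVENT_HEADS:
        raise ValueError(f"unknown event head {event_type!r}")
    B, X, M, A = (np.asarray(a, float) for a in inputs)
    outc_list = list(outcomes) if EVENT_HEADS[event_type] > 1 else [outcomes]
    if EVENT_HEADS[event_type] > 1 and len(outc_list) != EVENT_HEADS[event_type]:
        raise ValueError(f"'{event_type}' head expects {EVENT_HEADS[event_type]} "
                         f"outcome sets, got {len(outc_list)}")
    ref = outc_list[0]
    feats = {t: Tensor(model.event_features(B, X, M, A, t)[idx])
             for t, idx in _landmark_subsets(ref, landmarks)}
    subset_idx = {t: idx for t, idx in _landmark_subsets(ref, landmarks)}

    head_params = {k: model.params_[k] for k in model.head_names(event_type)}
    opt = Adam(head_params, lr=lr)
    history = []
    skipped = set()
    for _ in range(max(0, epochs)):
        opt.zero_grad()
        total = None
        for t_cond, F in feats.items():
            out = model._head(event_type, F)
            for col, outc in enumerate(outc_list):
                sub = outc.subset(subset_idx[t_cond])
                if sub.event.sum() == 0:
                    skipped.add(col)
                    continue
                scores = out[:, col]
                term = cox_event_loss(scores, sub, landmark_weighted=landmark_weighted)
                total = term if total is None else total + term
        if total is None:
            raise ValueError("no observed events for any outcome at any landmark")
        if weight_decay > 0:
            for t in head_params.values():
                if t.data.ndim == 2:
                    total = total + (t * t).sum() * weight_decay
        if not np.isfinite(total.data):
            raise RuntimeError("Cox loss diverged during fine-tuning")
        total.backward()
        opt.step()
        history.append(total.item())
    if skipped:
        warnings.warn(f"adverse-event columns without events skipped: {sorted(skipped)}")
    if not hasattr(model, "finetune_history_"):
        model.finetune_history_ = {}
    model.finetune_history_[event_type] = history
    # store train scores for normalized-risk reporting (over patients and landmarks)
    all_scores = np.concatenate(
        [model._head(event_type, F).data.ravel() for F in feats.values()])
    model.train_scores_[event_type] = all_scores
    return model


def finetune_heads_ensemble(model: JointTransformer, inputs, outcomes,
                            event_type: str, n_restarts: int = 3, epochs: int = 400,
                            lr: float = 1e-2, seed: int = 0,
                            weight_decay: float = 1e-3) -> list[dict]:
    """Fine-tune one head several times from fresh initializations and return
    the weight snapshots; averaging their scores damps head-level noise."""
    snapshots = []
    names = model.head_names(event_type)
    for r in range(max(1, n_restarts)):
        reinit_head(model, event_type, seed=(seed, r))
        finetune_heads(model, inputs, outcomes, event_type, epochs=epochs,
                       lr=lr, seed=seed, weight_decay=weight_decay)
        snapshots.append({k: model.params_[k].data.copy() for k in names})
    return snapshots


def ensemble_event_score(model: JointTransformer, snapshots: list[dict],
                         B, X, M, A, t_cond: int, event_type: str) -> np.ndarray:
    """Mean event score over head snapshots (backbone shared and frozen)."""
    scores = []
    for snap in snapshots:
        for k, w in snap.items():
            model.params_[k].data = w.copy()
        scores.append(model.event_score(B, X, M, A, t_cond, event_type))
    return np.mean(scores, axis=0)


# -------------------------------------------------------------------- bagging
@dataclass
class BaggedEnsemble:
    """Bootstrap-aggregated models: mean prediction, between-model sd."""

    models: list[JointTransformer]

    def aggregate(self, predict_fn):
        preds = np.stack([np.asarray(predict_fn(m)) for m in self.models])
        return preds.mean(axis=0), preds.std(axis=0, ddof=0)

    def event_score(self, B, X, M, A, t_cond, event_type):
        return self.aggregate(
            lambda m: m.event_score(B, X, M, A, t_cond, event_type))

    def rollout(self, B, X, M, A, t_cond, horizon):
        return self.aggregate(
            lambda m: m.rollout(B, X, M, A, t_cond, horizon))


def fit_bagged_ensemble(inputs, outcomes, base_model: JointTransformer,
                        n_bags: int = 5, resample_factor: float = 1.5,
                        seed: int = 0, pretrain_epochs=None,
                        finetune_epochs=None) -> BaggedEnsemble:
    """Train `n_bags` models, each on a with-replacement resample of the
    training set of size round(resample_factor * n)."""
    if n_bags < 2:
        warnings.warn("fewer than 2 bags: no between-model uncertainty")
    B, X, M, A = (np.asarray(a, float) for a in inputs)
    n = len(B)
    size = int(round(resample_factor * n))
    models, bag_indices = [], []
    for b in range(n_bags):
        rng = np.random.default_rng((seed, b))
        idx = rng.integers(0, n, size=size)
        bag_indices.append(idx)
        m = JointTransformer(**base_model.get_params())
        m.set_params(random_state=base_model.random_state + b)
        bag_outcomes = _subset_outcomes(outcomes, idx) if outcomes is not None else None
        m.fit((B[idx], X[idx], M[idx], A[idx]), bag_outcomes,
              pretrain_epochs=pretrain_epochs, finetune_epochs=finetune_epochs)
        models.append(m)
    ens = BaggedEnsemble(models)
    ens.bag_indices_ = bag_indices
    return ens


def _subset_outcomes(outcomes, idx):
    out = {}
    for k, v in outcomes.items():
        out[k] = [o.subset(idx) for o in v] if isinstance(v, (list, tuple)) \
            else v.subset(idx)
    return out


# ---------------------------------------------------------------- grid search
def default_grid() -> list[dict]:
    """The encoder tuning grid: 2 x 2 x 2 x 1 x 2 = 16 configurations."""
    grid = []
    for hidden_dim in (16, 32):
        for dropout in (0.1, 0.2):
            for rollout_window in (0, 1):
                for nonlinear_head in (True, False):
                    grid.append({"hidden_dim": hidden_dim, "dropout": dropout,
                                 "rollout_window": rollout_window,
                                 "n_layers": 2, "nonlinear_head": nonlinear_head})
    return grid


def tune_hyperparameters(grid, evaluate) -> tuple[dict, pd.DataFrame]:
    """Select the configuration minimizing the mean validation objective.

    `evaluate(config) -> iterable of per-fold objectives (lower is better)`.
    Returns the winning config and the full results table.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    for config in grid:
        vals = np.asarray(list(evaluate(config)), dtype=float)
        rows.append({**config, "objective_mean": vals.mean(),
                     "objective_sd": vals.std(ddof=0), "n_folds": len(vals)})
    results = pd.DataFrame(rows)
    best = results["objective_mean"].idxmin()
    return grid[best], results
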