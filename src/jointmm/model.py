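"""Causal transformer encoder with forecasting and Cox event-score heads.

The encoder maps, at every 28-day treatment period t, the concatenation
[B, X(t), M(t), A(t), E(t)] (baseline covariates, biomarkers, observation
mask, treatment dosages, sinusoidal time embedding) through a learned
affine input embedding and a stack of pre-norm residual self-attention
blocks.  Attention is restricted to periods <= t (causal mask), so the
hidden state z_t^(L) is a function of the history only; this information
contract is what makes landmark predictions honest and is asserted by
perturbation tests.

Three kinds of heads read the final-layer states:

* a forecasting head f_pred(z_t) -> X_hat(t+1), trained teacher-forced and
  applied autoregressively for multi-step rollout (predictions are fed
  back as the next input, future treatments and time embeddings are used
  as given);
* scalar Cox score heads for progression-free and overall survival;
* a 12-output head for adverse-event categories.

Event scores at time t consume the K+1 states [z_t, ..., z_{t+K}] where
states beyond t come from rollout, never from observed future data.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._autodiff import Tensor, concatenate

__all__ = ["time_embedding", "time_embedding_matrix", "JointTransformer",
           "normalized_risk", "EVENT_HEADS"]

EVENT_HEADS = {"pfs": 1, "os": 1, "ae": 12}


def time_embedding(t: float, tau: int, t_max: float) -> np.ndarray:
    """Sinusoidal embedding: E_{2k}(t) = sin(t / t_max^(2k/tau)),
    E_{2k+1}(t) = cos(t / t_max^((2k+1)/tau)), 0 <= k <= tau/2 - 1."""
    if tau % 2 != 0 or tau <= 0:
        raise ValueError("time embedding dimension must be a positive even number")
    if t < 0:
        raise ValueError("period must be non-negative")
    k = np.arange(tau // 2)
    out = np.empty(tau)
    out[0::2] = np.sin(t / t_max ** (2 * k / tau))
    out[1::2] = np.cos(t / t_max ** ((2 * k + 1) / tau))
    return out


def time_embedding_matrix(T: int, tau: int, t_max: float) -> np.ndarray:
    return np.stack([time_embedding(t, tau, t_max) for t in range(T)])


def normalized_risk(score, train_scores) -> np.ndarray | float:
    """Min-max normalized risk over the train-set score range, clipped to [0, 1].

    A value of 0.7 reads as: 70% of the training cohort's (patient, time)
    scores lie below this patient's score."""
    train_scores = np.asarray(train_scores, dtype=float)
    lo, hi = train_scores.min(), train_scores.max()
    if hi <= lo:
        raise ValueError("degenerate train scores: max must exceed min")
    out = np.clip((np.asarray(score, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    return out if out.ndim else float(out)


def _layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / ((var + eps) ** 0.5) * g + b


class JointTransformer(BaseEstimator):
    """Joint longitudinal-survival transformer (sklearn-style estimator).

    Parameters
    ----------
    hidden_dim : transformer hidden size D_z (grid values 16 or 32).
    n_layers : number of encoder layers (2 by default).
    n_heads : attention heads; D_z must be divisible by it.
    ff_mult : feed-forward width as a multiple of D_z.
    dropout : dropout probability inside the encoder during training.
    rollout_window : K, number of rolled-out future states fed to event heads.
    nonlinear_head : one-hidden-layer ReLU heads if True, affine otherwise.
    head_hidden : hidden width of nonlinear heads.
    tau : time-embedding dimension (even).
    t_max : horizon constant of the time embedding; defaults to max(24, T).
    literal_rollout_inputs : reuse A(t), E(t) (not t+1) when rolling out.
    random_state : seed for weight initialization and dropout.

    Fitted attributes (set by `fit` / the training routines) end in ``_``:
    ``params_`` (named weight tensors), ``dims_``, ``pretrain_history_``,
    ``finetune_history_``, ``train_scores_`` (per event, for risk
    normalization).
    """

    def __init__(self, hidden_dim: int = 16, n_layers: int = 2, n_heads: int = 1,
                 ff_mult: int = 4, dropout: float = 0.1, rollout_window: int = 1,
                 nonlinear_head: bool = True, head_hidden: int = 32, tau: int = 8,
                 t_max: float | None = None, literal_rollout_inputs: bool = False,
                 lr: float = 1e-3, pretrain_epochs: int = 150,
                 finetune_epochs: int = 300, random_state: int = 0):
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ff_mult = ff_mult
        self.dropout = dropout
        self.rollout_window = rollout_window
        self.nonlinear_head = nonlinear_head
        self.head_hidden = head_hidden
        self.tau = tau
        self.t_max = t_max
        self.literal_rollout_inputs = literal_rollout_inputs
        self.lr = lr
        self.pretrain_epochs = pretrain_epochs
        self.finetune_epochs = finetune_epochs
        self.random_state = random_state

    # ------------------------------------------------------------------ build
    def build(self, d_base: int, n_vars: int, d_treat: int, n_periods: int):
        """Allocate parameters for given input dimensions."""
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.n_layers < 1:
            raise ValueError("need at least one encoder layer")
        if self.rollout_window < 0:
            raise ValueError("rollout window K must be >= 0")
        rng = np.random.default_rng(self.random_state)
        D = self.hidden_dim
        d_in = d_base + 2 * n_vars + d_treat + self.tau
        t_max = self.t_max if self.t_max is not None else float(max(24, n_periods))

        def w(fan_in, fan_out):
            s = np.sqrt(2.0 / (fan_in + fan_out))
            return Tensor(rng.normal(0.0, s, size=(fan_in, fan_out)), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        def ones(*shape):
            return Tensor(np.ones(shape), requires_grad=True)

        p: dict[str, Tensor] = {"W_in": w(d_in, D), "b_in": zeros(D)}
        ff = self.ff_mult * D
        for l in range(self.n_layers):
            p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"] = ones(D), zeros(D)
            p[f"l{l}.Wq"], p[f"l{l}.Wk"], p[f"l{l}.Wv"] = w(D, D), w(D, D), w(D, D)
            p[f"l{l}.Wo"], p[f"l{l}.bo"] = w(D, D), zeros(D)
            p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"] = ones(D), zeros(D)
            p[f"l{l}.W1"], p[f"l{l}.c1"] = w(D, ff), zeros(ff)
            p[f"l{l}.W2"], p[f"l{l}.c2"] = w(ff, D), zeros(D)
        # forecasting head
        if self.nonlinear_head:
            p["pred.W1"], p["pred.b1"] = w(D, self.head_hidden), zeros(self.head_hidden)
            p["pred.W2"], p["pred.b2"] = w(self.head_hidden, n_vars), zeros(n_vars)
        else:
            p["pred.W"], p["pred.b"] = w(D, n_vars), zeros(n_vars)
        # event heads on concatenated [z_t, ..., z_{t+K}]
        d_head_in = D * (self.rollout_window + 1)
        for name, d_out in EVENT_HEADS.items():
            if self.nonlinear_head:
                p[f"head.{name}.W1"] = w(d_head_in, self.head_hidden)
                p[f"head.{name}.b1"] = zeros(self.head_hidden)
                p[f"head.{name}.W2"] = w(self.head_hidden, d_out)
                p[f"head.{name}.b2"] = zeros(d_out)
            else:
                p[f"head.{name}.W"] = w(d_head_in, d_out)
                p[f"head.{name}.b"] = zeros(d_out)
        self.params_ = p
        self.dims_ = {"d_base": d_base, "n_vars": n_vars, "d_treat": d_treat,
                      "tau": self.tau, "t_max": t_max}
        self.train_scores_ = {}
        return self

    @property
    def backbone_names_(self) -> list[str]:
        return [k for k in self.params_ if not k.startswith("head.")]

    def head_names(self, event_type: str) -> list[str]:
        return [k for k in self.params_ if k.startswith(f"head.{event_type}.")]

    # --------------------------------------------------------------- forward
    def _embed(self, B, X, M, A, start_period: int = 0) -> Tensor:
        n, T, _ = X.shape
        E = time_embedding_matrix(start_period + T, self.dims_["tau"],
                                  self.dims_["t_max"])[start_period:]
        parts = np.concatenate([
            np.broadcast_to(B[:, None, :], (n, T, B.shape[1])),
            X, M, A,
            np.broadcast_to(E[None], (n, T, E.shape[1])),
        ], axis=-1)
        return Tensor(parts) @ self.params_["W_in"] + self.params_["b_in"]

    def _dropout(self, x: Tensor, train: bool, rng) -> Tensor:
        if not train or self.dropout <= 0:
            return x
        keep = (rng.uniform(size=x.shape) >= self.dropout) / (1.0 - self.dropout)
        return x * Tensor(keep)

    def encode(self, B, X, M, A, train: bool = False, rng=None) -> Tensor:
        """Final-layer hidden states (n, T, D_z); causal across periods."""
        n, T, _ = np.asarray(X).shape
        if T < 1:
            raise ValueError("need at least one time step to encode")
        z = self._embed(np.asarray(B, float), np.asarray(X, float),
                        np.asarray(M, float), np.asarray(A, float))
        mask = Tensor(np.triu(np.full((T, T), -1e9), k=1))
        H, D = self.n_heads, self.hidden_dim
        dh = D // H
        p = self.params_
        for l in range(self.n_layers):
            h = _layer_norm(z, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
            q = (h @ p[f"l{l}.Wq"]).reshape(n, T, H, dh).swapaxes(1, 2)
            k = (h @ p[f"l{l}.Wk"]).reshape(n, T, H, dh).swapaxes(1, 2)
            v = (h @ p[f"l{l}.Wv"]).reshape(n, T, H, dh).swapaxes(1, 2)
            scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh)) + mask
            att = scores.softmax(axis=-1) @ v
            att = att.swapaxes(1, 2).reshape(n, T, D) @ p[f"l{l}.Wo"] + p[f"l{l}.bo"]
            z = z + self._dropout(att, train, rng)
            h2 = _layer_norm(z, p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
            ff = (h2 @ p[f"l{l}.W1"] + p[f"l{l}.c1"]).relu() @ p[f"l{l}.W2"] + p[f"l{l}.c2"]
            z = z + self._dropout(ff, train, rng)
        return z

    def forecast_next(self, z: Tensor) -> Tensor:
        """One-step biomarker prediction X_hat(t+1) from hidden state(s) z_t."""
        p = self.params_
        if self.nonlinear_head:
            return (z @ p["pred.W1"] + p["pred.b1"]).relu() @ p["pred.W2"] + p["pred.b2"]
        return z @ p["pred.W"] + p["pred.b"]

    def _head(self, name: str, features: Tensor) -> Tensor:
        p = self.params_
        if self.nonlinear_head:
            return ((features @ p[f"head.{name}.W1"] + p[f"head.{name}.b1"]).relu()
                    @ p[f"head.{name}.W2"] + p[f"head.{name}.b2"])
        return features @ p[f"head.{name}.W"] + p[f"head.{name}.b"]

    # --------------------------------------------------------------- rollout
    def rollout(self, B, X, M, A_full, t_cond: int, horizon: int,
                return_states: bool = False):
        """Autoregressive forecast over (t_cond, t_cond + horizon].

        Observed biomarkers are used only for periods < t_cond; predictions
        are fed back as inputs (their mask channel set to observed), while
        treatments and time embeddings advance with the rollout (or stay at
        the conditioning step when `literal_rollout_inputs`).  Deterministic
        given fixed weights and inputs.
        """
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        if t_cond < 1:
            raise ValueError("need at least one observed period (t_cond >= 1)")
        A_full = np.asarray(A_full, float)
        if A_full.shape[1] < t_cond + horizon - 1 + (0 if self.literal_rollout_inputs else 1):
            # step t+1 needs A(t+1) unless the literal variant reuses A(t)
            needed = t_cond + horizon - (1 if self.literal_rollout_inputs else 0)
            if A_full.shape[1] < needed:
                raise ValueError(
                    f"treatment plan covers {A_full.shape[1]} periods, "
                    f"rollout needs {needed}")
        B = np.asarray(B, float)
        Xc = np.asarray(X, float)[:, :t_cond].copy()
        Mc = np.asarray(M, float)[:, :t_cond].copy()
        n, _, J = Xc.shape
        preds = []
        for step in range(horizon):
            T_now = t_cond + step
            if self.literal_rollout_inputs and step > 0:
                A_used = np.concatenate(
                    [A_full[:, :t_cond], np.repeat(A_full[:, t_cond - 1:t_cond],
                                                   step, axis=1)], axis=1)
            else:
                A_used = A_full[:, :T_now]
            z = self.encode(B, Xc, Mc, A_used)
            x_next = self.forecast_next(z[:, -1]).data
            preds.append(x_next)
            Xc = np.concatenate([Xc, x_next[:, None, :]], axis=1)
            Mc = np.concatenate([Mc, np.ones((n, 1, J))], axis=1)
        X_hat = np.stack(preds, axis=1)
        if return_states:
            if self.literal_rollout_inputs:
                A_used = np.concatenate(
                    [A_full[:, :t_cond],
                     np.repeat(A_full[:, t_cond - 1:t_cond], horizon, axis=1)], axis=1)
            else:
                A_used = A_full[:, :t_cond + horizon]
            z_all = self.encode(B, Xc, Mc, A_used).data
            return X_hat, z_all
        return X_hat

    def event_features(self, B, X, M, A_full, t_cond: int) -> np.ndarray:
        """Concatenated states [z_{t}, ..., z_{t+K}] at t = t_cond - 1; states
        beyond t come from rollout, so no observed future data is used."""
        K = self.rollout_window
        if K == 0:
            z = self.encode(B, np.asarray(X, float)[:, :t_cond],
                            np.asarray(M, float)[:, :t_cond],
                            np.asarray(A_full, float)[:, :t_cond]).data
            return z[:, t_cond - 1]
        _, z_all = self.rollout(B, X, M, A_full, t_cond, K, return_states=True)
        return z_all[:, t_cond - 1:t_cond + K].reshape(len(z_all), -1)

    def event_score(self, B, X, M, A_full, t_cond: int, event_type: str) -> np.ndarray:
        """Cox risk score(s) at conditioning time t_cond: scalar per patient
        for 'pfs'/'os', a 12-vector for 'ae'."""
        if event_type not in EVENT_HEADS:
            raise ValueError(f"unknown event head {event_type!r}")
        feats = self.event_features(B, X, M, A_full, t_cond)
        out = self._head(event_type, Tensor(feats)).data
        return out[:, 0] if EVENT_HEADS[event_type] == 1 else out

    def predict_risk(self, B, X, M, A_full, t_cond: int, event_type: str):
        """Normalized risk in [0, 1] relative to stored training scores."""
        if event_type not in self.train_scores_:
            raise ValueError(f"no training scores stored for {event_type!r}; "
                             "fine-tune this head first")
        score = self.event_score(B, X, M, A_full, t_cond, event_type)
        return normalized_risk(score, self.train_scores_[event_type])

    # ------------------------------------------------------------------- fit
    def fit(self, inputs, outcomes=None, pretrain_epochs=None, finetune_epochs=None):
        """Pretrain on forecasting, then fine-tune event heads if outcomes given.

        `inputs` is a (B, X, M, A) tuple of arrays; `outcomes` a mapping
        event-type -> SurvivalOutcomes ('ae' takes a list of 12).
        """
        from . import training  # deferred: training imports loss utilities
        B, X, M, A = (np.asarray(a, float) for a in inputs)
        if not hasattr(self, "params_"):
            self.build(B.shape[1], X.shape[2], A.shape[2], X.shape[1])
        training.pretrain(self, (B, X, M, A),
                          epochs=pretrain_epochs or self.pretrain_epochs,
                          lr=self.lr, seed=self.random_state)
        if outcomes is not None:
            for event_type, outc in outcomes.items():
                training.finetune_heads(
                    self, (B, X, M, A), outc, event_type,
                    epochs=finetune_epochs or self.finetune_epochs,
                    lr=self.lr, seed=self.random_state)
        return self

    # ----------------------------------------------------------- persistence
    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params_.items()}

    def set_weights(self, weights: dict[str, np.ndarray]):
        for k, arr in weights.items():
            self.params_[k].data = np.asarray(arr, float).copy()
        return self
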