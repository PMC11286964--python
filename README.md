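# jointmm

Joint transformer modelling of longitudinal biomarkers, time-to-event
outcomes and individual treatment effects in two-arm myeloma trials.

Managing multiple myeloma means balancing three things at once: survival,
disease progression, and the adverse events of therapy, all tracked through
monthly labs (M-protein, free light chains, hemoglobin, creatinine, ...).
`jointmm` is for biostatisticians and ML researchers working with
longitudinal randomized-trial data who want a *single* model that

1. **forecasts biomarker trajectories** over a chosen horizon,
2. **scores time-to-event risks** — progression-free survival (PFS), overall
   survival (OS), and 12 adverse-event categories — with Cox
   proportional-hazards heads, and
3. **estimates individual treatment effects** (here: a triplet regimen, IRd,
   vs. a doublet control, Rd) for data-driven subgroup discovery.

Because real trial data of this kind are proprietary, the package ships a
synthetic randomized-trial simulator with the same statistical structure
(1:1 randomization, Ig-subtype marginals, treatment-responsive biomarker
dynamics driven by a latent disease burden, proportional-hazards events,
right censoring, structured missingness), so every stage is trainable and
testable offline.

## Model

Time is measured in 28-day treatment periods. At period `t` the encoder
embeds the concatenation `[B, X(t), M(t), A(t), E(t)]` — baseline
covariates, biomarkers, observation mask, drug dosages, and a sinusoidal
time embedding `E_2k(t) = sin(t / T_max^(2k/τ))`, `E_{2k+1}(t) =
cos(t / T_max^((2k+1)/τ))` — and passes it through `L = 2` causal
self-attention layers:

    q_t = W_q z_t,  k_t = W_k z_t,  v_t = W_v z_t
    z_t^(l+1) = f_l( softmax(q_t K_{≤t}^T / √d_k) V_{≤t} )

Attention is restricted to periods `≤ t`, so every prediction at `t` is a
function of the observed history only (asserted by perturbation tests).
A forecasting head predicts `X̂(t+1) = f_pred(z_t^(L))`, applied
autoregressively for multi-step rollout (predictions are fed back as
inputs; planned future treatments are honored). Event heads score
`ŷ_t = f_event([z_t^(L), ..., z_{t+K}^(L)])` with `K` rolled-out future
states (`K = 1` by default), trained with the negative Breslow Cox partial
log-likelihood:

    L = − Σ_{i: Δ_i = 1} [ ŷ_i − log Σ_{j ∈ R(y_i)} exp(ŷ_j) ]

Training is two-stage: pre-train everything on masked forecasting, then
fine-tune each event head with the backbone frozen. Potential outcomes are
predicted at baseline by running the fitted model under both arms
(flipping the arm covariate and the dosage plan); their difference is a
per-patient CATE, thresholded at the training median to define a
benefiting subgroup, which a depth-3 decision tree on baseline covariates
renders interpretable.

The neural network and its training loop run on a small reverse-mode
autodiff engine over numpy arrays (`jointmm._autodiff`) — the models are
small enough (hidden size 16–32, 2 layers) that this is fast on one CPU.

## Worked example

```python
from jointmm import SimConfig, generate_cohort, JointTransformer
from jointmm.pipeline import prepare_cohort
from jointmm.preprocessing import split_cohort
from jointmm import training
from jointmm.evaluation import averaged_cindex, forecast_mse, locf_forecast

cohort = generate_cohort(SimConfig(n_patients=600, n_periods=18, seed=42))
plan = split_cohort(cohort.n_patients, seed=0)           # 80/20 + five 75/25 folds
prep = prepare_cohort(cohort, train_idx=plan.train_full)  # filter/impute/normalize

model = JointTransformer(hidden_dim=16, random_state=0)
train = prep.subset_inputs(plan.train_full)
training.pretrain(model, train, epochs=120, seed=0)
heads = training.finetune_heads_ensemble(
    model, train, prep.outcomes["pfs"].subset(plan.train_full), "pfs",
    n_restarts=3, epochs=400, seed=0)

B, X, M, A = prep.subset_inputs(plan.test)
score = training.ensemble_event_score(model, heads, B, X, M, A, 1, "pfs")
test_outcomes = prep.outcomes["pfs"].subset(plan.test)
print("averaged IPCW C-index (PFS, t_cond=1):",
      round(averaged_cindex(score, test_outcomes), 3))
pred = model.rollout(B, X, M, A, t_cond=1, horizon=6)
print("forecast MSE (t_cond=1, horizon=6):", round(forecast_mse(pred, X, M, 1, 6), 3))
print("LOCF MSE     (t_cond=1, horizon=6):",
      round(forecast_mse(locf_forecast(X, M, 1, 6), X, M, 1, 6), 3))
```

prints

```
averaged IPCW C-index (PFS, t_cond=1): 0.635
forecast MSE (t_cond=1, horizon=6): 0.14
LOCF MSE     (t_cond=1, horizon=6): 0.283
```

Read: on held-out patients of a 600-patient simulated trial, risk scores
computed after one observed period rank progression times well above
chance (0.5), and six-month biomarker forecasts halve the error of
carrying the last observation forward. `pipeline.discover_subgroup` runs
the full treatment-effect analysis (CATE → median-threshold policy →
surrogate tree → Kaplan–Meier / log-rank / stratified Cox on a held-out
half) in one call.

A command-line interface covers the same pipeline for shell use:

```bash
jointmm simulate --out sim/ --seed 1
jointmm pretrain --cohort sim/ --out model.npz --epochs 100
jointmm finetune --cohort sim/ --checkpoint model.npz --event pfs --out model_pfs.npz
jointmm predict-events --cohort sim/ --checkpoint model_pfs.npz --t-cond 1 --out scores.csv
jointmm subgroup --cohort sim/ --out subgroup/
```

Every command writes a `manifest.json` (config hash, seed, version) so any
artifact is reconstructible from config + seed.

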