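# Methods

## Scope and data model

`jointmm` models a two-arm randomized oncology trial observed in discrete
28-day treatment periods. A cohort consists of a wide baseline table `B`
(demographics, Ig subtype, staging, baseline labs, randomized arm), a
longitudinal panel `X` of biomarker values with an observation mask `M`,
per-period drug dosages `A`, and right-censored outcomes `(y_i, Δ_i)` per
event type: progression-free survival (PFS), overall survival (OS) and 12
adverse-event categories (recorded at qualifying grade only; grades are
not modelled).

## Preprocessing

Longitudinal labs are normalized against clinical normal ranges rather
than cohort statistics: with range `(α_j, β_j)`,

    x* = 4 (x − α_j) / (β_j − α_j) − 2,        x† = 7 / (1 + e^(−0.25 x*)) − 3.5.

The range map puts the normal interval on [−2, 2]; the invertible sigmoid
bounds output in (−3.5, 3.5) while preserving variability near the normal
range — important for markers such as immunoglobulins that start far out
of range and fall quickly under therapy, where z-scoring would crush the
late-course signal. Variables that run far above their normal range (free
light chains, urine proteins, urate) get an extra 1/5 factor, applied to
`x*` before the sigmoid (the alternative ordering is available via
`scale_before_squash=False`). Normal ranges ship as an editable CSV
resource; they are configuration, not constants.

Baseline covariates are centered/scaled with training-fold statistics
(zero-variance columns scaled by 1 with a warning); categoricals are
one-hot encoded. Imputation: baseline categoricals take the train-fold
mode, baseline continuous the train-fold mean; longitudinal gaps at period
0 take the train-fold period-0 mean, later gaps are forward-filled.
Variable filtering drops baseline variables missing in more than 15% of
patients and longitudinal variables missing in more than 70% of entries
over the whole follow-up (thresholds read as maxima: retain below, drop
above). Splitting: one 80/20 train/test split plus five 75/25 resplits of
the 80% for validation; floor rounding for the smaller partition.

## Architecture

Input embedding: a single affine map of `[B, X(t), M(t), A(t), E(t)]` to
dimension `D_z`, where `E` is the sinusoidal time embedding
`E_2k(t) = sin(t / T_max^(2k/τ))`, `E_{2k+1}(t) = cos(t / T_max^((2k+1)/τ))`
with `τ` even and `T_max ≥` the maximum follow-up (default `max(24, T)`).
The mask is an input channel, not a filter: values at unobserved entries
are imputed upstream and still enter the embedding.

Encoder: `L = 2` pre-norm residual self-attention blocks. Attention is
causally masked (lower-triangular) so the state at period `t` depends only
on inputs at periods `≤ t` — the printed attention formula alone would
attend over all keys, but landmark predictions are only honest under the
causal restriction, which the tests assert by perturbation at every layer.
Defaults left open by the architecture sketch: 1 attention head (the
scaling `√d_k` uses the per-head key dimension), feed-forward width
`4 D_z`, pre-norm residual blocks with layer normalization, dropout inside
the blocks during training only. Tuning grid: `D_z ∈ {16, 32}`, dropout
`∈ {0.1, 0.2}`, rollout window `K ∈ {0, 1}`, linear vs. one-hidden-layer
ReLU heads — 16 configurations, selected by mean validation objective over
the five folds; `K = 1` is the default.

Rollout feeds `X̂(t+1)` back as the next input with its mask channel set
to "observed" (predictions substitute for measurements), while treatments
and time embeddings advance with the rollout (`A(t+1), E(t+1)`; the
variant that reuses `A(t), E(t)` is available via
`literal_rollout_inputs=True`). Event heads consume `[z_t, ..., z_{t+K}]`
with the `K` future states produced by rollout, never from observed future
data. For interpretation, raw Cox scores are min-max normalized against
the training set's (patient, time) score range and clipped to [0, 1],
which reads as a cohort risk quantile.

## Training

Stage 1 pre-trains everything on the masked forecasting loss (per-patient
normalized masked squared error, patients without observations excluded
with a warning), teacher-forced, full-batch Adam (lr 1e−3), optional early
stopping on a validation fold (patience 10). Stage 2 freezes the backbone
byte-for-byte and trains each event head on the negative Breslow partial
log-likelihood of scores taken at the conditioning time; ties share risk
sets (Breslow). The 12 AE outputs are optimized jointly with a summed
loss; categories without events are skipped with a warning. A
landmark-weighted aggregation of repeated partial likelihoods is available
(`landmark_weighted=True`) but the plain partial likelihood is the
default. Because the head's input features are frozen, fine-tuning is
cheap; `finetune_heads_ensemble` therefore re-initializes and re-trains
the head several times (default 3–5 restarts, small L2 of 1e−3 on head
weight matrices) and averages the scores — head-level noise in individual
risk and treatment-effect estimates is substantial at trial sample sizes,
and restart averaging damps it in the same spirit as bootstrap
aggregation at a fraction of the cost. Full bagging (5 models on
with-replacement resamples of 1.5× the training size, mean prediction,
between-model sd as uncertainty) is implemented in
`fit_bagged_ensemble`.

## Evaluation

Concordance for right-censored data uses Uno's IPCW estimator (via
scikit-survival) truncated at the 25th/50th/75th quantiles of the
evaluation fold's observed event times (linear-interpolation quantiles)
and averaged; quantile times admitting no comparable pairs are dropped
with a warning — with discrete period times and many early events the
25th-quantile term can be degenerate. Censoring-distribution ties resolve
events-first (the estimator's convention). Forecasting is scored by
masked MSE over `(t_cond, t_cond + t_horizon]` on the normalized scale,
against a last-observation-carried-forward baseline. The evaluation grid
crosses observation windows {1, 6, 12}, horizons {6, 12}, variable groups
and Ig-subtype subgroups (cells under 5 patients reported missing, not
zero). Model comparison: per-cell t-tests on the five per-fold metrics —
paired by fold, giving 4 degrees of freedom (an unpaired 5-vs-5 test would
have 8; the paired form is the one consistent with the reported d.f.) —
plus a two-way ANOVA (method × condition, no interaction) and Bonferroni
correction across method pairs.

## Treatment effects and subgroup discovery

Randomization holds at baseline only, so potential outcomes are predicted
at `t_cond = 1`: the model runs twice on identical first-period biomarkers
with the arm covariate in `B` and the dosages in `A` switched, giving
`ŷ¹, ŷ⁰` and two counterfactual trajectories. `CATE = ŷ¹ − ŷ⁰` on the
risk scale (raw Cox scores by default; they are monotone-equivalent to
the normalized scores for thresholding): negative means the triplet lowers
predicted progression risk. The analysis uses a dedicated 50/50 split:
the policy `π* = 1{CATE ≤ median(train CATEs)}` and a depth-3 surrogate
decision tree on baseline covariates (arm excluded) are fit on the
training half; Kaplan–Meier curves by actual randomized arm, the log-rank
test and a Cox regression on the arm indicator (optionally stratified;
strata are configurable since the original analysis does not list them,
and single-level strata are dropped within subsets) are computed on the
held-out half, for the discovered subgroup and the full held-out set as
contrast.

## The simulator: what it emulates, and what it does not

The generator reproduces the statistical structure the model assumes, with
defaults chosen once as the package's study conditions:

* **Cohort**: 1:1 randomization independent of covariates; Ig-subtype
  marginals fixed to a newly-diagnosed trial population's counts
  (IgG 403/703, IgA 142/703, IgD 10/703, IgE 3/703, IgM 3/703, biclonal
  23/703, no heavy chain 119/703); age ~ N(73, 7) clipped to [48, 90];
  ISS stage (46%/37%/16%).
* **Latent burden**: `b_0 ~ N(1, 0.4²)` truncated at 0.05;
  `b_{t+1} = ρ_arm b_t + η`, `ρ = 0.95` (Rd) vs `0.88` (IRd), process noise
  0.05 × the global noise multiplier. One scalar state is the simplest
  structure that makes forecasting and event prediction mutually
  informative.
* **Biomarkers**: affine emissions of the burden in clinical units
  (M-protein and light chains load positively, hemoglobin and albumin
  negatively) with variable-specific noise; `noise_sd` scales all noise,
  so `noise_sd = 0` gives fully deterministic trajectories.
* **Events**: discrete-time hazards
  `h_t = 1 − exp(−exp(β₀ + β_b b_{t−1} + β_arm · arm))`, inverse-sampled per
  period, so the Cox heads are well-specified. PFS uses `(β₀, β_b) =
  (−4.0, 2.0)` with arm log-HR −0.3; OS `(−5.0, 1.5)` with −0.15. These
  coefficients were calibrated so the *achievable* discrimination of the
  simulated world (the concordance of an oracle scoring patients by their
  true burden, ≈ 0.68) matches the discrimination reported for real trial
  cohorts of this kind (≈ 0.67); weaker coefficients create a world in
  which no method can exceed a C-index of 0.6 from baseline data. The
  calibration targets the oracle, not any fitted model.
* **Censoring**: administrative at end of follow-up plus per-period random
  censoring (default 0.02); ties between event and censoring resolve
  events-first.
* **Missingness**: MCAR per variable (default 10% longitudinal, 2% on
  three baseline labs); a monotone-dropout option exists. The real
  missingness process is uncharacterized, so MCAR is the default.
* **Heterogeneous effects**: `inject_heterogeneous_effect` shifts the
  progression log hazard ratio of treatment inside a baseline-defined
  subgroup (predicates on longitudinal variables are rejected); the
  ground-truth per-patient effect (difference in noise-free cumulative
  progression probability under the two arms) is stored for recovery
  tests.

Not emulated: pharmacokinetics, dose modification, cytogenetics,
informative missingness, visit-time irregularity, and any marginal beyond
the subtype/stage/age structure above. Passing tests therefore show the
method recovers structure *of the kind it assumes*, at realistic
signal-to-noise — not that it handles every pathology of real trial data.

## Numerical choices

Reverse-mode autodiff over float64 numpy arrays; gradients are pinned to
finite differences in tests (atol 1e−7 for the engine, 1e−4 for the Cox
loss). Xavier-style initialization; Adam (β = 0.9/0.999, ε = 1e−8);
full-batch updates at these cohort sizes; all randomness flows from
integer seeds through `numpy.random.default_rng`, making every training
run bit-reproducible. The causal mask adds −1e9 before the softmax, which
underflows to exactly zero weight after max-shifting. The sigmoid inverse
is rejected outside (−3.5, 3.5); range maps require `β > α`. CSVs are
written with `%.17g` and read with round-trip float parsing so cohorts
survive disk round-trips bit-identically.

## Known limitations

* The encoder recomputes attention over the full prefix at every rollout
  step (no caching); fine at trial scale, wasteful beyond it.
* The Cox heads are trained at a single conditioning landmark by default;
  scores at other landmarks reuse the same head rather than re-fitting.
* Subgroup discovery is hypothesis-generating: no post-selection inference
  correction is applied (the held-out evaluation controls, but does not
  adjust, selection effects).
* The IPCW estimator needs an estimable censoring distribution; heavy
  early censoring with discrete times can degenerate the lowest quantile
  term, which is then dropped (with a warning) from the average.
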