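"""End-to-end glue: preprocessing -> model inputs -> training -> analysis.

These helpers bind the preprocessing transformers, the transformer
estimator and the counterfactual analysis into reproducible runs; the
command-line interface is a thin wrapper around them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AE_TYPES, Cohort
from .counterfactual import (compute_cate, evaluate_subgroup, fit_surrogate_tree,
                             learn_threshold_policy, predict_potential_outcomes,
                             CateTable)
from .model import JointTransformer
from .preprocessing import (BaselineStandardizer, NormalRangeScaler,
                            filter_variables, impute_cohort, load_default_ranges)
from .simulate import _DOSES, TREATMENT_NAMES
from . import training

__all__ = ["PreparedCohort", "prepare_cohort", "counterfactual_arm_inputs",
           "even_split", "discover_subgroup", "outcome_dict"]

_ID_COLS = ("patient_id",)


@dataclass
class PreparedCohort:
    """Model-ready arrays plus the fitted preprocessing state."""

    B: np.ndarray
    X: np.ndarray
    M: np.ndarray
    A: np.ndarray
    outcomes: dict
    variables: list[str]
    standardizer: BaselineStandardizer
    scaler: NormalRangeScaler
    dose_scale: np.ndarray
    baseline_raw: pd.DataFrame

    @property
    def inputs(self):
        return self.B, self.X, self.M, self.A

    def subset_inputs(self, idx):
        idx = np.asarray(idx)
        return self.B[idx], self.X[idx], self.M[idx], self.A[idx]


def outcome_dict(cohort: Cohort) -> dict:
    """Outcomes grouped for the three heads: scalar pfs/os, 12-list ae."""
    out = {}
    if "pfs" in cohort.outcomes:
        out["pfs"] = cohort.outcomes["pfs"]
    if "os" in cohort.outcomes:
        out["os"] = cohort.outcomes["os"]
    aes = [cohort.outcomes[a] for a in AE_TYPES if a in cohort.outcomes]
    if len(aes) == len(AE_TYPES):
        out["ae"] = aes
    return out


def prepare_cohort(cohort: Cohort, train_idx=None, ranges=None,
                   baseline_thresh: float = 0.15,
                   longitudinal_thresh: float = 0.70) -> PreparedCohort:
    """Filter, impute, normalize and standardize a cohort into model inputs.

    All statistics (imputation means/modes, baseline standardization, dose
    scaling) come from `train_idx` rows only.
    """
    if train_idx is None:
        train_idx = np.arange(cohort.n_patients)
    train_idx = np.asarray(train_idx)
    ranges = ranges if ranges is not None else load_default_ranges()

    B_raw = cohort.baseline.drop(columns=[c for c in _ID_COLS
                                          if c in cohort.baseline.columns])
    B_f, panel_f, _ = filter_variables(B_raw, cohort.panel,
                                       baseline_thresh, longitudinal_thresh)
    B_imp, panel_imp = impute_cohort(B_f, panel_f, train_idx)

    scaler = NormalRangeScaler(ranges, variables=panel_imp.variables)
    scaler.fit(panel_imp.values)
    X = scaler.transform(panel_imp.values)
    M = panel_f.mask  # original observation flags, post-missingness

    std = BaselineStandardizer()
    std.fit(B_imp.iloc[train_idx])
    B = std.transform(B_imp).to_numpy(float)

    dose_scale = panel_imp.treatments[train_idx].max(axis=(0, 1))
    dose_scale[dose_scale == 0] = 1.0
    A = panel_imp.treatments / dose_scale

    return PreparedCohort(B, X, M, A, outcome_dict(cohort), panel_imp.variables,
                          std, scaler, dose_scale, B_imp)


def counterfactual_arm_inputs(prep: PreparedCohort):
    """Baseline features and dosage plans with the arm forced to each value.

    Returns (B1, A1, B0, A0): the treatment-arm covariate in the baseline
    table and the drug dosages in the treatment plan are both switched."""
    n, T, _ = prep.A.shape
    out = {}
    for arm in (1, 0):
        b_arm = prep.baseline_raw.copy()
        b_arm["arm"] = arm
        B_arm = prep.standardizer.transform(b_arm).to_numpy(float)
        doses = np.asarray(_DOSES[arm]) / prep.dose_scale
        A_arm = np.broadcast_to(doses, (n, T, len(TREATMENT_NAMES))).copy()
        out[arm] = (B_arm, A_arm)
    (B1, A1), (B0, A0) = out[1], out[0]
    return B1, A1, B0, A0


def even_split(n: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """50/50 train/test split used for the subgroup-discovery analysis."""
    perm = np.random.default_rng(seed).permutation(n)
    half = n // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def discover_subgroup(cohort: Cohort, seed: int = 0, model_params: dict | None = None,
                      pretrain_epochs: int = 40, finetune_epochs: int = 400,
                      n_head_restarts: int = 5, weight_decay: float = 1e-3,
                      max_depth: int = 3, strata_cols=None) -> dict:
    """Full proof-of-concept subgroup-discovery analysis.

    Trains on an even split, imputes potential outcomes for everyone,
    thresholds CATE at the train median, fits the surrogate tree on train
    baselines, and assesses both policies on the held-out half with
    Kaplan-Meier / log-rank / (stratified) Cox.  The CATE is averaged over
    `n_head_restarts` re-initializations of the event head (the backbone is
    shared), which damps head-level noise in the individual effects.
    """
    train_idx, test_idx = even_split(cohort.n_patients, seed)
    prep = prepare_cohort(cohort, train_idx=train_idx)

    params = {"hidden_dim": 32, "dropout": 0.1, "rollout_window": 1,
              "nonlinear_head": True, "random_state": seed}
    params.update(model_params or {})
    model = JointTransformer(**params)
    tr = prep.subset_inputs(train_idx)
    training.pretrain(model, tr, epochs=pretrain_epochs, seed=seed)

    B1, A1, B0, A0 = counterfactual_arm_inputs(prep)
    X0, M0 = prep.X[:, :1], prep.M[:, :1]
    outc_train = prep.outcomes["pfs"].subset(train_idx)
    y1s, y0s = [], []
    for r in range(max(1, n_head_restarts)):
        training.reinit_head(model, "pfs", seed=(seed, r))
        training.finetune_heads(model, tr, outc_train, "pfs",
                                epochs=finetune_epochs, lr=1e-2, seed=seed,
                                weight_decay=weight_decay)
        y1_r, y0_r, _, _ = predict_potential_outcomes(model, X0, M0, B1, A1,
                                                      B0, A0, horizon=1)
        y1s.append(y1_r)
        y0s.append(y0_r)
    y1, y0 = np.mean(y1s, axis=0), np.mean(y0s, axis=0)
    cate = compute_cate(y1, y0)
    delta, _ = learn_threshold_policy(cate[train_idx])
    pi_star = (cate <= delta).astype(int)

    tree_covariates = prep.baseline_raw.drop(columns=["arm"])
    tree = fit_surrogate_tree(tree_covariates.iloc[train_idx],
                              pi_star[train_idx], max_depth=max_depth,
                              random_state=seed)
    pi = tree.predict(tree_covariates)

    table = CateTable(y1=y1, y0=y0, cate=cate, delta=delta,
                      pi_star=pi_star, pi=pi)
    arm = cohort.arm
    strata = (cohort.baseline[list(strata_cols)] if strata_cols else None)
    outcomes = cohort.outcomes["pfs"]
    reports = {}
    for name, labels in (("pi_star", pi_star), ("pi", pi)):
        try:
            reports[name] = evaluate_subgroup(
                outcomes.subset(test_idx), arm[test_idx],
                np.asarray(labels)[test_idx].astype(bool),
                strata.iloc[test_idx] if strata is not None else None)
        except ValueError as exc:
            reports[name] = {"error": str(exc)}
    return {"cate_table": table, "tree": tree, "reports": reports,
            "train_idx": train_idx, "test_idx": test_idx, "model": model}
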