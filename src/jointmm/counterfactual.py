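"""Potential-outcome prediction, CATE, policy learning and subgroup assessment.

Because treatment is randomized at baseline, running the fitted model twice
on the same patient — once with the triplet-arm covariates/dosages and once
with the control-arm ones — yields potential-outcome risk scores whose
difference is an individual (conditional average) treatment effect on
progression risk:

    CATE_i = y_hat(1)_i - y_hat(0)_i,

negative values meaning the triplet is predicted to lower progression risk.
A simple policy thresholds at the training-fold median CATE; a shallow
decision tree fitted to the policy labels on baseline covariates gives an
interpretable surrogate.  Discovered subgroups are assessed on held-out
patients with Kaplan-Meier curves by actual randomized arm, a log-rank
test, and a (optionally stratified) Cox regression on the arm indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .cohort import SurvivalOutcomes
from .model import normalized_risk

__all__ = ["CateTable", "predict_potential_outcomes", "compute_cate",
           "learn_threshold_policy", "SurrogateTreePolicy", "fit_surrogate_tree",
           "evaluate_subgroup"]


@dataclass
class CateTable:
    """Per-patient potential-outcome risks and subgroup assignments."""

    y1: np.ndarray          # predicted progression risk under the triplet (IRd)
    y0: np.ndarray          # ... under the control arm (Rd)
    cate: np.ndarray        # y1 - y0; negative = triplet beneficial
    delta: float | None = None      # train-median threshold
    pi_star: np.ndarray | None = None  # 1 = in benefiting subgroup (CATE <= delta)
    pi: np.ndarray | None = None       # surrogate-tree assignment


def predict_potential_outcomes(model, X0, M0, B1, A1, B0, A0,
                               event_type: str = "pfs", horizon: int = 6,
                               t_cond: int = 1, use_normalized: bool = False):
    """Run the model under both arms from baseline information only.

    Both runs share the identical first-period biomarkers X0/M0; only the
    baseline treatment covariates (B1 vs B0) and dosage plans (A1 vs A0)
    differ.  Returns (y1, y0, traj1, traj0).  Predictions are restricted to
    the baseline conditioning time because randomization — hence the causal
    interpretation — holds only there.
    """
    if t_cond != 1:
        raise ValueError("potential outcomes are defined at baseline only "
                         "(t_cond = 1); randomization does not hold later")
    y1 = model.event_score(B1, X0, M0, A1, t_cond, event_type)
    y0 = model.event_score(B0, X0, M0, A0, t_cond, event_type)
    if use_normalized:
        train = model.train_scores_[event_type]
        y1, y0 = normalized_risk(y1, train), normalized_risk(y0, train)
    traj1 = model.rollout(B1, X0, M0, A1, t_cond, horizon)
    traj0 = model.rollout(B0, X0, M0, A0, t_cond, horizon)
    return y1, y0, traj1, traj0


def compute_cate(y1, y0) -> np.ndarray:
    """Risk-scale treatment effect y1 - y0; positive flags predicted harm."""
    return np.asarray(y1, float) - np.asarray(y0, float)


def learn_threshold_policy(train_cates) -> tuple[float, np.ndarray]:
    """delta = median(train CATEs); patient i is in the benefiting subgroup
    (pi* = 1) iff CATE_i <= delta."""
    cates = np.asarray(train_cates, float)
    if cates.size == 0:
        raise ValueError("no CATE values to learn a policy from")
    delta = float(np.median(cates))
    return delta, (cates <= delta).astype(int)


class SurrogateTreePolicy:
    """Shallow decision-tree replication of a subgroup policy on baseline data."""

    def __init__(self, max_depth: int = 3, random_state: int = 0):
        self.max_depth = max_depth
        self.random_state = random_state

    def _encode(self, B: pd.DataFrame) -> np.ndarray:
        pieces = []
        for c, levels in self.schema_.items():
            if levels is None:
                pieces.append(B[c].to_numpy(float))
            else:
                vals = B[c].astype(str)
                pieces.extend((vals == lv).to_numpy(float) for lv in levels)
        return np.column_stack(pieces)

    def fit(self, B: pd.DataFrame, labels) -> "SurrogateTreePolicy":
        labels = np.asarray(labels, int)
        self.schema_ = {}
        self.feature_names_ = []
        for c in B.columns:
            if B[c].dtype == object or isinstance(B[c].dtype, pd.CategoricalDtype):
                levels = sorted(B[c].dropna().astype(str).unique())
                self.schema_[c] = levels
                self.feature_names_ += [f"{c}={lv}" for lv in levels]
            else:
                self.schema_[c] = None
                self.feature_names_.append(c)
        if len(np.unique(labels)) < 2:
            warnings.warn("single-class policy labels: surrogate tree is a "
                          "single leaf")
        if self.max_depth == 0:  # majority vote: forbid any split
            self.tree_ = DecisionTreeClassifier(
                max_depth=1, min_samples_split=len(labels) + 1,
                random_state=self.random_state)
        else:
            self.tree_ = DecisionTreeClassifier(max_depth=self.max_depth,
                                                random_state=self.random_state)
        self.tree_.fit(self._encode(B), labels)
        self.training_accuracy_ = float(
            (self.predict(B) == labels).mean())
        return self

    def predict(self, B: pd.DataFrame) -> np.ndarray:
        return self.tree_.predict(self._encode(B)).astype(int)

    def describe(self) -> list[str]:
        """Human-readable node report: rule, sample count, label proportions
        P0 (not in subgroup) and P1 (in subgroup)."""
        t = self.tree_.tree_
        lines = []

        def rec(node, depth, rule):
            counts = t.value[node][0]
            n = int(t.n_node_samples[node])
            p = counts / counts.sum()
            p0 = p[0] if self.tree_.classes_[0] == 0 else (p[1] if len(p) > 1 else 0.0)
            p1 = 1.0 - p0
            lines.append(f"{'  ' * depth}{rule} [n={n}, P0={p0:.2f}, P1={p1:.2f}]")
            if t.children_left[node] != -1:
                feat = self.feature_names_[t.feature[node]]
                thr = t.threshold[node]
                rec(t.children_left[node], depth + 1, f"{feat} <= {thr:.3g}")
                rec(t.children_right[node], depth + 1, f"{feat} > {thr:.3g}")

        rec(0, 0, "root")
        return lines


def fit_surrogate_tree(B: pd.DataFrame, labels, max_depth: int = 3,
                       random_state: int = 0) -> SurrogateTreePolicy:
    """Axis-aligned tree on baseline covariates replicating the policy labels."""
    return SurrogateTreePolicy(max_depth=max_depth,
                               random_state=random_state).fit(B, labels)


def _arm_effect(outcomes: SurvivalOutcomes, arm, strata: pd.DataFrame | None):
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"time": outcomes.time, "event": outcomes.event,
                       "arm": np.asarray(arm, int)})
    strata_cols = []
    if strata is not None:
        strata = strata.reset_index(drop=True)
        strata_cols = list(strata.columns)
        df = pd.concat([df, strata], axis=1)
        # drop strata with a single level in this subset (no information)
        strata_cols = [c for c in strata_cols if df[c].nunique() > 1]
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event",
            strata=strata_cols or None)
    return float(cph.params_["arm"]), float(cph.summary.loc["arm", "p"])


def evaluate_subgroup(outcomes: SurvivalOutcomes, arm, in_subgroup,
                      strata: pd.DataFrame | None = None) -> dict:
    """Survival assessment of a discovered subgroup on held-out patients.

    Returns Kaplan-Meier curves by actual randomized arm, the log-rank p,
    and the (stratified) Cox arm effect, both inside the subgroup and for
    the full held-out set as contrast.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    arm = np.asarray(arm, int)
    in_subgroup = np.asarray(in_subgroup).astype(bool)

    def report(idx):
        sub = outcomes.subset(idx)
        a = arm[idx]
        if min((a == 1).sum(), (a == 0).sum()) < 2:
            raise ValueError("need at least 2 patients per arm")
        km = {}
        for val, lab in ((1, "IRd"), (0, "Rd")):
            f = KaplanMeierFitter(label=lab)
            f.fit(sub.time[a == val], sub.event[a == val])
            km[lab] = f
        lr = logrank_test(sub.time[a == 1], sub.time[a == 0],
                          sub.event[a == 1], sub.event[a == 0])
        st = strata.iloc[idx] if strata is not None else None
        coef, cox_p = _arm_effect(sub, a, st)
        return {"n": len(idx), "n_IRd": int((a == 1).sum()),
                "n_Rd": int((a == 0).sum()), "km": km,
                "logrank_p": float(lr.p_value), "cox_arm_coef": coef,
                "cox_arm_p": cox_p}

    return {"subgroup": report(np.flatnonzero(in_subgroup)),
            "full": report(np.arange(len(arm)))}
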