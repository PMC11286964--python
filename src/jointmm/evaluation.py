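"""Evaluation protocol: truncated IPCW concordance at event-time quantiles,
masked forecasting error over horizons, the last-observation-carried-forward
baseline, and paired-t / two-way-ANOVA model comparisons.

Concordance for right-censored data uses inverse-probability-of-censoring
weights (Uno's estimator) with the censoring survival curve estimated by
Kaplan-Meier on the censoring indicator; ties between an event and a
censoring at the same time are resolved events-first.  A value of 0.5 is
chance level, 1.0 a perfect risk ranking.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sksurv.util import Surv

from .cohort import SurvivalOutcomes

__all__ = ["cindex_ipcw", "averaged_cindex", "forecast_mse", "locf_forecast",
           "EvalGrid", "evaluate_grid", "compare_models", "bonferroni"]


def _surv(outcomes: SurvivalOutcomes):
    return Surv.from_arrays(event=outcomes.event.astype(bool), time=outcomes.time)


def cindex_ipcw(scores, outcomes: SurvivalOutcomes, eval_time: float,
                censoring_from: SurvivalOutcomes | None = None) -> float:
    """IPCW concordance truncated at `eval_time`; higher scores = higher risk.

    `censoring_from` supplies the sample used to estimate the censoring
    distribution (defaults to the evaluation sample itself).
    """
    from sksurv.metrics import concordance_index_ipcw

    scores = np.asarray(scores, float)
    train = censoring_from if censoring_from is not None else outcomes
    c, *_ = concordance_index_ipcw(_surv(train), _surv(outcomes), scores,
                                   tau=float(eval_time))
    return float(c)


def averaged_cindex(scores, outcomes: SurvivalOutcomes,
                    quantiles=(0.25, 0.50, 0.75),
                    censoring_from: SurvivalOutcomes | None = None) -> float:
    """Mean IPCW concordance over the given quantiles of observed event times.

    Quantiles use linear interpolation on the evaluation fold's event times.
    A quantile whose truncation time admits no comparable pairs is dropped
    with a warning.
    """
    q = np.asarray(quantiles, float)
    if np.any(np.diff(q) <= 0) or np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantiles must be strictly increasing within (0, 1)")
    event_times = outcomes.time[outcomes.event == 1]
    if len(event_times) == 0:
        raise ValueError("no observed events to take quantiles of")
    taus = np.quantile(event_times, q)
    vals = []
    for tau in taus:
        try:
            vals.append(cindex_ipcw(scores, outcomes, tau, censoring_from))
        except Exception as exc:  # no comparable pairs at this truncation
            warnings.warn(f"concordance at truncation {tau} dropped: {exc}")
    if not vals:
        raise ValueError("no evaluable truncation times")
    return float(np.mean(vals))


def forecast_mse(X_hat, X, M, t_cond: int, t_horizon: int,
                 var_idx=None) -> float:
    """Masked MSE over the horizon window (t_cond, t_cond + t_horizon].

    `X_hat` has shape (n, t_horizon, J) aligned to the window; `X`, `M` are
    the full panels.  `var_idx` restricts to a variable group.  Values at
    masked entries never contribute.
    """
    X_hat = np.asarray(X_hat, float)
    Xw = np.asarray(X, float)[:, t_cond:t_cond + t_horizon]
    Mw = np.asarray(M, float)[:, t_cond:t_cond + t_horizon]
    if X_hat.shape != Xw.shape:
        raise ValueError(f"predictions {X_hat.shape} do not cover the window "
                         f"{Xw.shape}")
    if var_idx is not None:
        X_hat, Xw, Mw = X_hat[:, :, var_idx], Xw[:, :, var_idx], Mw[:, :, var_idx]
    total = Mw.sum()
    if total == 0:
        raise ValueError("no observed entries in the evaluation window")
    return float((Mw * (Xw - X_hat) ** 2).sum() / total)


def locf_forecast(X, M, t_cond: int, t_horizon: int) -> np.ndarray:
    """Carry the last observed (or, failing that, last imputed) value at or
    before t_cond forward over the whole horizon."""
    X = np.asarray(X, float)
    M = np.asarray(M, float)
    n, T, J = X.shape
    last = X[:, t_cond - 1].copy()  # fallback: imputed value at the last period
    for t in range(t_cond):
        last = np.where(M[:, t] == 1, X[:, t], last)
    return np.repeat(last[:, None, :], t_horizon, axis=1)


@dataclass
class EvalGrid:
    """Observation windows, horizons, truncation quantiles and variable groups."""

    t_cond: tuple = (1, 6, 12)
    t_horizon: tuple = (6, 12)
    quantiles: tuple = (0.25, 0.50, 0.75)
    events: tuple = ("pfs", "os")
    variable_groups: dict = field(default_factory=dict)  # name -> list of variables
    min_subgroup: int = 5

    def __post_init__(self):
        if any(t <= 0 for t in self.t_cond) or any(h <= 0 for h in self.t_horizon):
            raise ValueError("windows and horizons must be positive")
        q = np.asarray(self.quantiles)
        if np.any(np.diff(q) <= 0) or np.any((q <= 0) | (q >= 1)):
            raise ValueError("quantiles must be strictly increasing within (0, 1)")


def evaluate_grid(ensemble, inputs, outcomes: dict, grid: EvalGrid,
                  variables: list[str] | None = None,
                  subgroups: np.ndarray | None = None) -> pd.DataFrame:
    """Per (task, t_cond, t_horizon, subgroup) cell: mean and sd over the
    bagged models, plus the per-model values for downstream testing.

    `subgroups` is an optional per-patient label array (e.g. Ig heavy-chain
    type); cells with fewer than `grid.min_subgroup` patients are reported
    as missing (NaN), not zero.
    """
    B, X, M, A = (np.asarray(a, float) for a in inputs)
    models = getattr(ensemble, "models", [ensemble])
    n = len(B)
    labels = [("all", np.arange(n))]
    if subgroups is not None:
        subgroups = np.asarray(subgroups)
        for lab in pd.unique(subgroups):
            labels.append((str(lab), np.flatnonzero(subgroups == lab)))
    groups = {"all": None}
    if variables is not None:
        for gname, gvars in grid.variable_groups.items():
            groups[gname] = [variables.index(v) for v in gvars]

    rows = []
    for t_cond in grid.t_cond:
        # event prediction: one score per model per patient
        for event in grid.events:
            try:
                per_model = [m.event_score(B, X, M, A, t_cond, event)
                             for m in models]
            except ValueError:  # window/rollout not supported by this panel
                per_model = []
            for lab, idx in labels:
                vals = []
                if per_model and len(idx) >= grid.min_subgroup:
                    sub = outcomes[event].subset(idx)
                    for s in per_model:
                        try:
                            vals.append(averaged_cindex(s[idx], sub, grid.quantiles))
                        except ValueError:
                            pass
                rows.append(_row(f"cindex_{event}", t_cond, np.nan, lab, vals))
        # forecasting
        for t_horizon in grid.t_horizon:
            try:
                per_model = [m.rollout(B, X, M, A, t_cond, t_horizon)
                             for m in models]
            except ValueError:
                per_model = []
            for gname, gidx in groups.items():
                for lab, idx in labels:
                    vals = []
                    if per_model and len(idx) >= grid.min_subgroup:
                        for pred in per_model:
                            try:
                                vals.append(forecast_mse(
                                    pred[idx], X[idx], M[idx], t_cond, t_horizon,
                                    var_idx=gidx))
                            except ValueError:
                                pass
                    rows.append(_row(f"mse_{gname}", t_cond, t_horizon, lab, vals))
    return pd.DataFrame(rows)


def _row(task, t_cond, t_horizon, subgroup, vals):
    vals = np.asarray(vals, float)
    ok = len(vals) > 0
    return {"task": task, "t_cond": t_cond, "t_horizon": t_horizon,
            "subgroup": subgroup,
            "mean": vals.mean() if ok else np.nan,
            "sd": vals.std(ddof=0) if ok else np.nan,
            "n_models": len(vals), "values": vals.tolist()}


def bonferroni(p: float, m: int) -> float:
    """Multiply a p-value by the number of comparisons, capped at 1."""
    return float(min(1.0, p * m))


_CELL = ["task", "t_cond", "t_horizon", "subgroup"]


def compare_models(results_a: pd.DataFrame, results_b: pd.DataFrame,
                   labels: tuple[str, str] = ("a", "b"),
                   paired: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell t-tests plus an overall two-way ANOVA without interaction.

    Each results table must carry the same cells with equal replicate counts
    (the per-model metric vectors from `evaluate_grid`).  The default test
    is paired by model replicate (5 replicates -> 4 degrees of freedom); the
    ANOVA factors are method and the cell (condition combination).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    a = results_a.set_index(_CELL)["values"]
    b = results_b.set_index(_CELL)["values"]
    if not a.index.equals(b.index):
        raise ValueError("results tables cover different cells")
    rows, long = [], []
    for cell in a.index:
        va, vb = np.asarray(a[cell], float), np.asarray(b[cell], float)
        if len(va) != len(vb):
            raise ValueError(f"unequal replicate counts in cell {cell}")
        if len(va) == 0:
            continue
        diffs = va - vb
        if paired and np.allclose(diffs.std(ddof=0), 0.0):
            t, p = (0.0, 1.0) if np.allclose(diffs, 0.0) else (np.inf, 0.0)
        elif paired:
            t, p = stats.ttest_rel(va, vb)
        else:
            t, p = stats.ttest_ind(va, vb)
        rows.append(dict(zip(_CELL, cell)) | {
            f"mean_{labels[0]}": va.mean(), f"mean_{labels[1]}": vb.mean(),
            "t": float(t), "p": float(p), "df": len(va) - 1 if paired else 2 * len(va) - 2})
        for method, vals in zip(labels, (va, vb)):
            for v in vals:
                long.append({"metric": v, "method": method,
                             "cell": "|".join(str(c) for c in cell)})
    long = pd.DataFrame(long)
    if long["cell"].nunique() > 1:
        fit = ols("metric ~ C(method) + C(cell)", data=long).fit()
    else:
        fit = ols("metric ~ C(method)", data=long).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    return pd.DataFrame(rows), anova
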