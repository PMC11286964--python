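"""Hidden-state interpretation: correlation maps between encoder dimensions
and predictions, patient-level narrative summaries, and a 2-D embedding hook.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Tensor

__all__ = ["CorrelationMap", "hidden_correlation_map", "patient_summary",
           "embed_states_2d", "DEFAULT_INSPECTION_TIMES"]

DEFAULT_INSPECTION_TIMES = (1, 3, 6, 9, 12)


@dataclass
class CorrelationMap:
    """Tidy Pearson correlations (dimension, time, target, rho).

    Constant hidden dimensions have undefined correlation: they are flagged
    and excluded, never reported as zero.  The display threshold selects
    which dimensions to show; stored values are never altered by it.
    """

    table: pd.DataFrame
    threshold: float = 0.4
    undefined: list = field(default_factory=list)  # (dimension, time, target)

    def display_dimensions(self) -> list[int]:
        """Dimensions with at least one |rho| >= threshold at any time/target."""
        t = self.table
        keep = t.loc[t["rho"].abs() >= self.threshold, "dimension"].unique()
        return sorted(int(d) for d in keep)

    def display_table(self) -> pd.DataFrame:
        return self.table[self.table["dimension"].isin(self.display_dimensions())]


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson correlation, or None when either series is constant."""
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def hidden_correlation_map(model, inputs, event_type: str = "pfs",
                           biomarkers: list[int] | None = None,
                           times=DEFAULT_INSPECTION_TIMES,
                           threshold: float = 0.4) -> CorrelationMap:
    """Across patients, correlate every final-layer hidden dimension with
    (a) the predicted event risk and (b) each selected biomarker's next-step
    prediction, at the given conditioning times."""
    B, X, M, A = (np.asarray(a, float) for a in inputs)
    if len(B) < 3:
        raise ValueError("need at least 3 patients for correlation maps")
    rows, undefined = [], []
    T = X.shape[1]
    for t_cond in times:
        if t_cond < 1 or t_cond > T:
            continue
        z = model.encode(B, X[:, :t_cond], M[:, :t_cond], A[:, :t_cond]).data
        state = z[:, t_cond - 1]  # (n, D_z)
        targets = {"risk": model.event_score(B, X, M, A, t_cond, event_type)}
        x_next = model.forecast_next(Tensor(state)).data
        for j in (biomarkers or []):
            targets[f"biomarker_{j}"] = x_next[:, j]
        for d in range(state.shape[1]):
            for name, target in targets.items():
                rho = _pearson(state[:, d], np.asarray(target, float))
                if rho is None:
                    undefined.append((d, t_cond, name))
                else:
                    rows.append({"dimension": d, "time": t_cond,
                                 "target": name, "rho": rho})
    return CorrelationMap(pd.DataFrame(rows), threshold=threshold,
                          undefined=undefined)


def _trend(traj: np.ndarray, flat_tol: float = 1e-3) -> str:
    slope = (traj[-1] - traj[0]) / max(1, len(traj) - 1)
    if abs(slope) <= flat_tol:
        return "flat"
    return "up" if slope > 0 else "down"


def patient_summary(model, inputs, patient: int, t_conds, horizon: int = 6,
                    event_type: str = "pfs", variables: list[str] | None = None,
                    ranges=None, scale_before_squash: bool = True) -> dict:
    """Clinical vignette for one patient: per conditioning time, the
    normalized risk, de-normalized forecast trajectories, and trend labels.

    A forecast that cannot be mapped back to clinical units (outside the
    invertible squash domain) is reported on the normalized scale with a
    flag rather than dropped.
    """
    from .preprocessing import denormalize_longitudinal

    B, X, M, A = (np.asarray(a, float)[patient:patient + 1] for a in inputs)
    record = {"patient": patient, "windows": []}
    for t_cond in t_conds:
        risk = float(model.predict_risk(B, X, M, A, t_cond, event_type)[0])
        traj = model.rollout(B, X, M, A, t_cond, horizon)[0]  # (horizon, J)
        entry = {"t_cond": int(t_cond), "normalized_risk": risk,
                 "narrative": f"{round(100 * risk)}% of patients in the cohort "
                              "have a lower risk score",
                 "forecasts": {}}
        for j in range(traj.shape[1]):
            name = variables[j] if variables else f"var_{j}"
            vals = traj[:, j]
            fc = {"trend": _trend(vals)}
            if ranges is not None:
                try:
                    fc["values"] = denormalize_longitudinal(
                        traj[:, [j]], [name], ranges,
                        scale_before_squash).ravel().tolist()
                    fc["units"] = "clinical"
                except ValueError:
                    fc["values"] = vals.tolist()
                    fc["units"] = "normalized"
                    fc["denormalization_failed"] = True
            else:
                fc["values"] = vals.tolist()
                fc["units"] = "normalized"
            entry["forecasts"][name] = fc
        record["windows"].append(entry)
    return record


def embed_states_2d(states: np.ndarray, method: str = "umap",
                    n_neighbors: int = 15, random_state: int = 0) -> np.ndarray:
    """2-D manifold embedding of baseline hidden states (thin, configurable
    hook; default UMAP, 'pca' for a deterministic linear alternative)."""
    states = np.asarray(states, float)
    if len(states) < 10:
        raise ValueError("need at least 10 patients to embed")
    if method == "umap":
        if len(states) <= n_neighbors:
            raise ValueError("fewer patients than the neighbors parameter")
        import umap

        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            random_state=random_state)
        return np.asarray(reducer.fit_transform(states))
    if method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=2, random_state=random_state).fit_transform(states)
    raise ValueError(f"unknown embedding method {method!r}")
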