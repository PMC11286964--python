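"""Readers/writers for cohorts, configs, manifests and model checkpoints.

A cohort on disk is four CSV files (UTF-8, comma-separated, '.' decimal,
NA token "NA") plus a JSON sidecar of simulator ground truth when present:

* baseline.csv      — wide, one row per patient
* longitudinal.csv  — long: patient_id, period, variable, value, observed
* treatments.csv    — long: patient_id, period, drug, dose
* outcomes.csv      — long: patient_id, event, time, indicator

Periods are 0-based integer 28-day treatment periods.  Every run writes a
manifest (config hash, seed, package version) alongside its outputs so any
artifact is reconstructible from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, LongitudinalPanel, SurvivalOutcomes

__all__ = ["write_cohort", "load_cohort", "load_config", "write_manifest",
           "save_checkpoint", "load_checkpoint"]

# %.17g guarantees exact float64 round-trips through text
_CSV_KW = dict(na_rep="NA", index=False, float_format="%.17g")
_READ_KW = dict(na_values=["NA"], keep_default_na=False,
                float_precision="round_trip")


def write_cohort(cohort: Cohort, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.baseline.to_csv(outdir / "baseline.csv", **_CSV_KW)

    p = cohort.panel
    n, T, J = p.values.shape
    pid = np.repeat(p.patient_ids, T * J)
    period = np.tile(np.repeat(np.arange(T), J), n)
    var = np.tile(p.variables, n * T)
    pd.DataFrame({
        "patient_id": pid, "period": period, "variable": var,
        "value": p.values.ravel(), "observed": p.mask.ravel().astype(int),
    }).to_csv(outdir / "longitudinal.csv", **_CSV_KW)

    D = p.treatments.shape[2]
    pd.DataFrame({
        "patient_id": np.repeat(p.patient_ids, T * D),
        "period": np.tile(np.repeat(np.arange(T), D), n),
        "drug": np.tile(p.treatment_names, n * T),
        "dose": p.treatments.ravel(),
    }).to_csv(outdir / "treatments.csv", **_CSV_KW)

    rows = []
    for event, o in cohort.outcomes.items():
        for i, pid_ in enumerate(p.patient_ids):
            rows.append({"patient_id": pid_, "event": event,
                         "time": o.time[i], "indicator": o.event[i]})
    pd.DataFrame(rows).to_csv(outdir / "outcomes.csv", **_CSV_KW)

    if cohort.truth:
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in cohort.truth.items()}
        (outdir / "ground_truth.json").write_text(json.dumps(truth))
    return outdir


def load_cohort(indir) -> Cohort:
    """Load and validate the four-CSV cohort layout."""
    indir = Path(indir)
    baseline = pd.read_csv(indir / "baseline.csv", **_READ_KW)
    long = pd.read_csv(indir / "longitudinal.csv", **_READ_KW)
    treat = pd.read_csv(indir / "treatments.csv", **_READ_KW)
    outc = pd.read_csv(indir / "outcomes.csv", **_READ_KW)

    errors = []
    pids = baseline["patient_id"].tolist()
    pid_set = set(pids)
    for name, df in (("longitudinal", long), ("treatments", treat),
                     ("outcomes", outc)):
        unknown = set(df["patient_id"]) - pid_set
        if unknown:
            errors.append(f"{name}.csv references unknown patient ids: "
                          f"{sorted(unknown)[:5]}")
    for name, df in (("longitudinal", long), ("treatments", treat)):
        per = df["period"]
        if not np.array_equal(per, per.astype(int)):
            errors.append(f"{name}.csv has non-integer periods")
    dup = long.duplicated(["patient_id", "period", "variable"])
    if dup.any():
        errors.append(f"longitudinal.csv has {int(dup.sum())} duplicate "
                      "(patient, period, variable) rows")
    if errors:
        raise ValueError("cohort validation failed:\n- " + "\n- ".join(errors))

    variables = sorted(long["variable"].unique())
    drugs = sorted(treat["drug"].unique())
    T = int(long["period"].max()) + 1
    n = len(pids)
    pid_ix = {p: i for i, p in enumerate(pids)}
    var_ix = {v: j for j, v in enumerate(variables)}
    drug_ix = {d: j for j, d in enumerate(drugs)}

    X = np.full((n, T, len(variables)), np.nan)
    M = np.zeros((n, T, len(variables)))
    i = long["patient_id"].map(pid_ix).to_numpy()
    t = long["period"].to_numpy(int)
    j = long["variable"].map(var_ix).to_numpy()
    X[i, t, j] = long["value"].to_numpy(float)
    M[i, t, j] = long["observed"].to_numpy(float)

    A = np.zeros((n, T, len(drugs)))
    i = treat["patient_id"].map(pid_ix).to_numpy()
    t = treat["period"].to_numpy(int)
    j = treat["drug"].map(drug_ix).to_numpy()
    A[i, t, j] = treat["dose"].to_numpy(float)

    panel = LongitudinalPanel(X, M, A, variables, drugs, np.asarray(pids))
    outcomes = {}
    for event, g in outc.groupby("event"):
        g = g.set_index("patient_id").loc[pids]
        outcomes[event] = SurvivalOutcomes(g["time"].to_numpy(float),
                                           g["indicator"].to_numpy(int))
    truth = {}
    gt = indir / "ground_truth.json"
    if gt.exists():
        truth = json.loads(gt.read_text())
        for k in ("burden", "true_cate"):
            if k in truth:
                truth[k] = np.asarray(truth[k], float)
    return Cohort(baseline, panel, outcomes, truth)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def write_manifest(outdir, command: str, config: dict, seed: int) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "package_version": __version__,
        "python": platform.python_version(),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def save_checkpoint(model, path, preprocessing: dict | None = None):
    """Single-file checkpoint: weights + architecture + preprocessing state,
    so inference is self-contained."""
    meta = {"params": model.get_params(), "dims": model.dims_,
            "train_scores": {k: v.tolist() for k, v in model.train_scores_.items()},
            "preprocessing": preprocessing or {}}
    arrays = {f"w::{k}": v for k, v in model.get_weights().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    from .model import JointTransformer

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        weights = {k[3:]: data[k] for k in data.files if k.startswith("w::")}
    model = JointTransformer(**meta["params"])
    dims = meta["dims"]
    model.t_max = dims["t_max"]
    model.build(dims["d_base"], dims["n_vars"], dims["d_treat"], 1)
    model.set_weights(weights)
    model.train_scores_ = {k: np.asarray(v) for k, v in meta["train_scores"].items()}
    return model, meta["preprocessing"]
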