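"""In-memory containers for a longitudinal trial cohort."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LongitudinalPanel", "SurvivalOutcomes", "Cohort", "AE_TYPES"]

# Adverse-event categories, time-to-first-occurrence outcomes.  Only events at
# qualifying grade (>= grade 2 non-hematologic, >= grade 3 hematologic) are
# recorded; grades themselves are not modelled.
AE_TYPES = [
    "acute_renal_failure", "cardiac_arrhythmias", "diarrhea", "heart_failure",
    "hypotension", "liver_impairment", "nausea", "neutropenia",
    "peripheral_neuropathies", "rash", "thrombocytopenia", "vomiting",
]


@dataclass
class LongitudinalPanel:
    """Per-patient biomarker matrices indexed by 28-day treatment period.

    values : (n, T, J) biomarker values (NaN where never defined)
    mask   : (n, T, J) 1 where observed, 0 where missing
    treatments : (n, T, D) per-period drug dosages
    """

    values: np.ndarray
    mask: np.ndarray
    treatments: np.ndarray
    variables: list[str]
    treatment_names: list[str]
    patient_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=float)
        self.treatments = np.asarray(self.treatments, dtype=float)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape[:2] != self.treatments.shape[:2]:
            raise ValueError("treatments misaligned with values")
        if self.values.shape[2] != len(self.variables):
            raise ValueError("variable list length mismatch")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_periods(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "LongitudinalPanel":
        return LongitudinalPanel(
            self.values.copy(), self.mask.copy(), self.treatments.copy(),
            list(self.variables), list(self.treatment_names),
            self.patient_ids.copy())

    def subset(self, idx) -> "LongitudinalPanel":
        idx = np.asarray(idx)
        return LongitudinalPanel(
            self.values[idx], self.mask[idx], self.treatments[idx],
            list(self.variables), list(self.treatment_names),
            self.patient_ids[idx])


@dataclass
class SurvivalOutcomes:
    """Right-censored times for one event type: y_i > 0 in periods, delta in {0,1}."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time/event shape mismatch")
        if np.any(self.time <= 0):
            raise ValueError("event times must be positive")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicators must be 0/1")

    def risk_set(self, y: float) -> np.ndarray:
        """Indices of patients with observed time >= y."""
        return np.flatnonzero(self.time >= y)

    def subset(self, idx) -> "SurvivalOutcomes":
        idx = np.asarray(idx)
        return SurvivalOutcomes(self.time[idx], self.event[idx])


@dataclass
class Cohort:
    """A two-arm trial cohort: baseline table, longitudinal panel, outcomes.

    `truth` optionally holds simulator ground truth (latent burden, true
    CATE) used by recovery tests; it is absent for real data.
    """

    baseline: pd.DataFrame
    panel: LongitudinalPanel
    outcomes: dict[str, SurvivalOutcomes]
    truth: dict = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return len(self.baseline)

    @property
    def arm(self) -> np.ndarray:
        return self.baseline["arm"].to_numpy()

    def subset(self, idx) -> "Cohort":
        idx = np.asarray(idx)
        truth = {}
        for k, v in self.truth.items():
            if isinstance(v, np.ndarray) and v.shape[:1] == (self.n_patients,):
                truth[k] = v[idx]
            else:
                truth[k] = v
        return Cohort(
            self.baseline.iloc[idx].reset_index(drop=True),
            self.panel.subset(idx),
            {k: o.subset(idx) for k, o in self.outcomes.items()},
            truth,
        )
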