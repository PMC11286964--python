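"""Synthetic two-arm randomized myeloma trial cohorts.

The generator emulates the statistical structure the joint model assumes:
a 1:1 randomized cohort with immunoglobulin-subtype marginals matching a
newly-diagnosed myeloma trial population, treatment-responsive biomarker
dynamics, proportional-hazards event generation, right censoring and
structured missingness.

The core is a scalar latent disease-burden state per patient following a
discrete-time linear update with arm-specific decay:

    b_0 ~ N(1, 0.4^2) truncated below, b_{t+1} = rho_arm * b_t + eta_t,

with the triplet arm (IRd) decaying faster than the doublet (Rd).
Biomarkers are affine emissions of the burden plus variable-specific noise
(M-protein and light chains load positively, hemoglobin and albumin
negatively).  Events follow discrete-time proportional hazards on the
latent burden,

    h_t = 1 - exp(-exp(beta_0 + beta_b * b_{t-1} + beta_arm * arm [+ subgroup shift])),

sampled by per-period inversion, so the Cox prediction heads being tested
are well-specified for the simulated world.  Ground-truth burden paths and
per-patient treatment effects are kept for recovery tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import AE_TYPES, Cohort, LongitudinalPanel, SurvivalOutcomes

__all__ = [
    "SimConfig", "DynamicsConfig", "BaselinePredicate", "generate_cohort",
    "apply_missingness", "inject_heterogeneous_effect", "SUBTYPES",
]

SUBTYPES = ["IgG", "IgA", "IgD", "IgE", "IgM", "biclonal", "no_heavy_chain"]

# Newly-diagnosed trial arm marginals: counts over 703 patients.
_SUBTYPE_COUNTS = {"IgG": 403, "IgA": 142, "IgD": 10, "IgE": 3, "IgM": 3,
                   "biclonal": 23, "no_heavy_chain": 119}
DEFAULT_SUBTYPE_PROBS = {k: v / 703.0 for k, v in _SUBTYPE_COUNTS.items()}

# variable -> (intercept, burden loading, base emission noise sd), clinical units
_EMISSIONS = {
    "m_protein": (1.0, 6.0, 0.5),      # g/L
    "kappa_flc": (20.0, 150.0, 10.0),  # mg/L
    "hemoglobin": (135.0, -25.0, 5.0),  # g/L
    "creatinine": (70.0, 30.0, 8.0),   # umol/L
    "calcium": (2.3, 0.3, 0.08),       # mmol/L
    "albumin": (42.0, -6.0, 2.0),      # g/L
}

TREATMENT_NAMES = ["lenalidomide", "ixazomib", "dexamethasone"]
# per-period dosage rows for the control (Rd) and triplet (IRd) arms
_DOSES = {0: (25.0, 0.0, 40.0), 1: (25.0, 4.0, 40.0)}

_DEFAULT_HAZARDS = {
    # event -> (beta_0, beta_burden, beta_arm_extra_toxicity)
    "pfs": (-4.0, 2.0, 0.0),
    "os": (-5.0, 1.5, 0.0),
    "acute_renal_failure": (-5.0, 0.5, 0.0),
    "cardiac_arrhythmias": (-5.5, 0.0, 0.0),
    "diarrhea": (-4.5, 0.0, 0.3),
    "heart_failure": (-5.5, 0.2, 0.0),
    "hypotension": (-5.0, 0.3, 0.0),
    "liver_impairment": (-5.5, 0.0, 0.1),
    "nausea": (-4.8, 0.0, 0.2),
    "neutropenia": (-4.5, 0.3, 0.2),
    "peripheral_neuropathies": (-5.0, 0.0, 0.4),
    "rash": (-5.0, 0.0, 0.4),
    "thrombocytopenia": (-4.8, 0.4, 0.3),
    "vomiting": (-5.2, 0.0, 0.2),
}


@dataclass
class DynamicsConfig:
    """Arm-specific burden decay: multiplicative per 28-day period."""

    decay_rd: float = 0.95
    decay_ird: float = 0.88
    rebound: float = 0.0       # additive drift, e.g. resistance re-growth
    process_noise: float = 0.05

    def decay(self, arm: int) -> float:
        return self.decay_ird if arm == 1 else self.decay_rd


@dataclass(frozen=True)
class BaselinePredicate:
    """Equality rule on a single baseline column, e.g. ig_subtype == 'IgA'."""

    column: str
    value: object

    def __call__(self, baseline: pd.DataFrame) -> np.ndarray:
        return (baseline[self.column] == self.value).to_numpy()


@dataclass
class SimConfig:
    n_patients: int = 500
    n_periods: int = 18
    subtype_probs: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_PROBS))
    arm_prob: float = 0.5
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    noise_sd: float = 1.0       # global multiplier on emission + process noise
    baseline_hazards: dict = field(default_factory=lambda: dict(_DEFAULT_HAZARDS))
    effect_log_hr: dict = field(default_factory=lambda: {"pfs": -0.3, "os": -0.15})
    censor_rate: float = 0.02   # per-period random-censoring probability
    missingness: float | dict = 0.10     # per-variable longitudinal missing prob
    baseline_missingness: float = 0.02
    missingness_mechanism: str = "mcar"  # "mcar" | "monotone"
    subgroup_effect: tuple | None = None  # (BaselinePredicate, extra_log_hr) on PFS
    seed: int = 0

    def __post_init__(self):
        probs = np.array([self.subtype_probs[s] for s in SUBTYPES])
        if np.any(probs < 0):
            raise ValueError("subtype probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"subtype_probs must sum to 1, got {probs.sum()!r}")
        if not 0.0 <= self.arm_prob <= 1.0:
            raise ValueError("arm_prob must lie in [0, 1]")
        if self.noise_sd < 0 or self.censor_rate < 0:
            raise ValueError("rates must be non-negative")
        rates = (self.missingness.values() if isinstance(self.missingness, dict)
                 else [self.missingness])
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("missingness rates must lie in [0, 1]")
        if self.missingness_mechanism not in ("mcar", "monotone"):
            raise ValueError("missingness_mechanism must be 'mcar' or 'monotone'")

    def copy(self) -> "SimConfig":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.subgroup_effect is not None:
            pred, extra = self.subgroup_effect
            d["subgroup_effect"] = {"column": pred.column, "value": pred.value,
                                    "extra_log_hr": extra}
        return d


def _hazard(beta0, beta_b, beta_arm_tox, burden, arm, log_hr_arm, extra):
    lin = beta0 + beta_b * burden + (log_hr_arm + beta_arm_tox + extra) * arm
    return 1.0 - np.exp(-np.exp(lin))


def _sample_event(rng, hazards):
    """First period (1-based) where a uniform draw falls under the hazard."""
    T = hazards.shape[1]
    u = rng.uniform(size=hazards.shape)
    hit = u < hazards
    t = np.where(hit.any(axis=1), hit.argmax(axis=1) + 1, T + 1)
    return t


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a full synthetic cohort; bit-identical given the same config."""
    rng = np.random.default_rng(config.seed)
    n, T = config.n_patients, config.n_periods

    # ----- baseline covariates (independent of randomized arm) ---------------
    subtype = rng.choice(SUBTYPES, size=n, p=[config.subtype_probs[s] for s in SUBTYPES])
    sex = rng.choice(["F", "M"], size=n, p=[0.499, 0.501])
    age = np.clip(np.round(rng.normal(73, 7, size=n)), 48, 90)
    iss = rng.choice(["I", "II", "III"], size=n, p=[0.461, 0.374, 0.165])
    light_chain = rng.choice(["kappa", "lambda"], size=n, p=[0.62, 0.38])
    b0 = np.maximum(0.05, rng.normal(1.0, 0.4, size=n))
    arm = (rng.uniform(size=n) < config.arm_prob).astype(int)

    baseline = pd.DataFrame({
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "ig_subtype": subtype,
        "light_chain": light_chain,
        "iss_stage": iss,
        "flc_baseline": 20.0 + 150.0 * b0 + rng.normal(0, 10 * config.noise_sd, n),
        "creatinine_baseline": 70.0 + 30.0 * b0 + rng.normal(0, 8 * config.noise_sd, n),
        "albumin_baseline": 42.0 - 6.0 * b0 + rng.normal(0, 2 * config.noise_sd, n),
        "arm": arm,
    })

    # ----- latent burden ----------------------------------------------------
    dyn = config.dynamics
    decay = np.where(arm == 1, dyn.decay_ird, dyn.decay_rd)
    burden = np.empty((n, T))
    burden[:, 0] = b0
    proc_sd = dyn.process_noise * config.noise_sd
    for t in range(1, T):
        eta = rng.normal(0, proc_sd, size=n) if proc_sd > 0 else 0.0
        burden[:, t] = np.maximum(0.0, decay * burden[:, t - 1] + dyn.rebound + eta)

    # ----- biomarker emissions ----------------------------------------------
    variables = list(_EMISSIONS)
    X = np.empty((n, T, len(variables)))
    for j, v in enumerate(variables):
        a, c, sd = _EMISSIONS[v]
        noise = (rng.normal(0, sd * config.noise_sd, size=(n, T))
                 if config.noise_sd > 0 else 0.0)
        X[:, :, j] = a + c * burden + noise
    M = np.ones_like(X)

    A = np.empty((n, T, len(TREATMENT_NAMES)))
    for a_val, doses in _DOSES.items():
        A[arm == a_val] = np.array(doses)

    panel = LongitudinalPanel(X, M, A, variables, list(TREATMENT_NAMES),
                              baseline["patient_id"].to_numpy())

    # ----- events -----------------------------------------------------------
    in_subgroup = np.zeros(n, dtype=bool)
    extra_log_hr = 0.0
    if config.subgroup_effect is not None:
        pred, extra_log_hr = config.subgroup_effect
        in_subgroup = pred(baseline)

    censor = _sample_censoring(rng, n, T, config.censor_rate)
    outcomes = {}
    for event, (beta0, beta_b, beta_tox) in config.baseline_hazards.items():
        log_hr = config.effect_log_hr.get(event, 0.0)
        extra = np.where(in_subgroup, extra_log_hr, 0.0) if event == "pfs" else 0.0
        haz = _hazard(beta0, beta_b, beta_tox, burden, arm[:, None],
                      log_hr, np.asarray(extra).reshape(-1, 1) if event == "pfs" else 0.0)
        t_event = _sample_event(rng, haz)
        y = np.minimum.reduce([t_event, censor, np.full(n, T)])
        delta = (t_event <= np.minimum(censor, T)).astype(int)
        outcomes[event] = SurvivalOutcomes(y, delta)

    # ----- missingness ------------------------------------------------------
    panel = apply_missingness(panel, config.missingness,
                              seed=int(rng.integers(2**31)),
                              mechanism=config.missingness_mechanism)
    if config.baseline_missingness > 0:
        miss_cols = ["flc_baseline", "creatinine_baseline", "albumin_baseline"]
        for c in miss_cols:
            drop = rng.uniform(size=n) < config.baseline_missingness
            baseline.loc[drop, c] = np.nan

    truth = {
        "burden": burden,
        "true_cate": _true_cate(config, b0, in_subgroup, extra_log_hr),
        "config": config.to_dict(),
    }
    return Cohort(baseline, panel, outcomes, truth)


def _sample_censoring(rng, n, T, rate):
    """Random per-period censoring (geometric) on top of administrative end T."""
    if rate <= 0:
        return np.full(n, T)
    u = rng.uniform(size=(n, T))
    hit = u < rate
    c = np.where(hit.any(axis=1), hit.argmax(axis=1) + 1, T)
    return np.minimum(c, T)


def _true_cate(config: SimConfig, b0, in_subgroup, extra_log_hr) -> np.ndarray:
    """Noise-free difference in cumulative progression probability by end of
    follow-up, triplet minus control (negative = triplet protective)."""
    beta0, beta_b, beta_tox = config.baseline_hazards["pfs"]
    log_hr = config.effect_log_hr.get("pfs", 0.0)
    T = config.n_periods
    probs = {}
    for a in (0, 1):
        b = b0.copy()
        surv = np.ones_like(b0)
        extra = np.where(in_subgroup, extra_log_hr, 0.0) * a
        for _ in range(T):
            h = 1.0 - np.exp(-np.exp(beta0 + beta_b * b + (log_hr + beta_tox) * a + extra))
            surv *= 1.0 - h
            b = np.maximum(0.0, config.dynamics.decay(a) * b + config.dynamics.rebound)
        probs[a] = 1.0 - surv
    return probs[1] - probs[0]


def apply_missingness(panel: LongitudinalPanel, rates, seed: int = 0,
                      mechanism: str = "mcar") -> LongitudinalPanel:
    """Flip observation-mask entries to 0.  Values are retained internally
    (flagged unobserved), so ground truth remains available to the simulator.

    MCAR flips entries independently at the per-variable rate; the monotone
    mechanism drops each (patient, variable) stream from a geometric dropout
    period onward.
    """
    if isinstance(rates, dict):
        rate_vec = np.array([rates.get(v, 0.0) for v in panel.variables])
    else:
        rate_vec = np.full(len(panel.variables), float(rates))
    if np.any((rate_vec < 0) | (rate_vec > 1)):
        raise ValueError("missingness rates must lie in [0, 1]")
    out = panel.copy()
    if np.all(rate_vec == 0):
        return out
    rng = np.random.default_rng(seed)
    n, T, J = panel.values.shape
    if mechanism == "mcar":
        drop = rng.uniform(size=(n, T, J)) < rate_vec
    elif mechanism == "monotone":
        # dropout period ~ geometric with the per-variable rate; later entries missing
        u = rng.uniform(size=(n, J))
        with np.errstate(divide="ignore"):
            start = np.where(rate_vec > 0,
                             np.ceil(np.log(u) / np.log1p(-np.clip(rate_vec, 0, 1 - 1e-12))),
                             np.inf)
        drop = np.arange(T)[None, :, None] >= start[:, None, :]
    else:
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    out.mask = np.where(drop, 0.0, out.mask)
    return out


def inject_heterogeneous_effect(config: SimConfig,
                                subgroup_predicate: BaselinePredicate,
                                extra_log_hr: float) -> SimConfig:
    """Return a config whose progression log hazard ratio for treatment is
    shifted by `extra_log_hr` inside the baseline-defined subgroup."""
    probe = generate_cohort(SimConfig(n_patients=2, n_periods=2, missingness=0.0,
                                      baseline_missingness=0.0, seed=0))
    if subgroup_predicate.column in probe.panel.variables:
        raise ValueError(
            f"subgroup predicate must reference baseline fields only, got "
            f"longitudinal variable {subgroup_predicate.column!r}")
    if subgroup_predicate.column not in probe.baseline.columns:
        raise ValueError(f"unknown baseline field {subgroup_predicate.column!r}")
    out = config.copy()
    out.subgroup_effect = (subgroup_predicate, float(extra_log_hr))
    return out
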