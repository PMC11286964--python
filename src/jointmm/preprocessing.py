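"""Normalization, imputation, variable filtering and sample splitting.

Longitudinal labs are mapped through a clinical normal-range transform: a
variable with normal range (alpha, beta) is rescaled so the range covers
[-2, 2], optionally shrunk for variables that run far above their normal
range (free light chains, urine proteins, urate), then passed through an
invertible sigmoid squashing onto (-3.5, 3.5).  Unlike z-scoring against
the baseline distribution, this keeps late-course variability visible for
markers (immunoglobulins, M-protein) that start far out of range and fall
quickly under therapy.

Baseline covariates are standardized with train-fold statistics only;
categoricals are one-hot encoded.  All transformers follow sklearn
fit/transform conventions so they compose with pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "normalize_range", "squash", "inverse_squash", "NormalRangeTable",
    "NormalRangeScaler", "normalize_longitudinal", "denormalize_longitudinal",
    "BaselineStandardizer", "standardize_baseline", "impute_cohort",
    "filter_variables", "SplitPlan", "split_cohort", "load_default_ranges",
]

_SQUASH_SCALE = 7.0
_SQUASH_RATE = 0.25
_SQUASH_BOUND = _SQUASH_SCALE / 2.0  # 3.5


def normalize_range(x, alpha: float, beta: float):
    """Map a clinical value so the normal range [alpha, beta] covers [-2, 2]."""
    if beta <= alpha:
        raise ValueError(f"upper bound {beta} must exceed lower bound {alpha}")
    x = np.asarray(x, dtype=float)
    out = 4.0 * (x - alpha) / (beta - alpha) - 2.0
    return out if out.ndim else float(out)


def inverse_normalize_range(x_star, alpha: float, beta: float):
    if beta <= alpha:
        raise ValueError(f"upper bound {beta} must exceed lower bound {alpha}")
    x_star = np.asarray(x_star, dtype=float)
    out = (x_star + 2.0) * (beta - alpha) / 4.0 + alpha
    return out if out.ndim else float(out)


def squash(x_star):
    """Invertible sigmoid squashing: output strictly inside (-3.5, 3.5)."""
    x_star = np.asarray(x_star, dtype=float)
    out = _SQUASH_SCALE / (1.0 + np.exp(-_SQUASH_RATE * x_star)) - _SQUASH_BOUND
    return out if out.ndim else float(out)


def inverse_squash(x_dagger):
    x_dagger = np.asarray(x_dagger, dtype=float)
    if np.any(np.abs(x_dagger) >= _SQUASH_BOUND):
        raise ValueError(f"inverse_squash domain is (-{_SQUASH_BOUND}, {_SQUASH_BOUND})")
    p = (x_dagger + _SQUASH_BOUND) / _SQUASH_SCALE
    out = np.log(p / (1.0 - p)) / _SQUASH_RATE
    return out if out.ndim else float(out)


@dataclass
class NormalRangeTable:
    """Per-variable clinical normal ranges plus an optional extra scale.

    The extra scale (default 1, conventionally 1/5 for free light chains,
    urine proteins and urate) shrinks the range-normalized value before
    squashing, to keep variables that run far above their normal range out
    of the sigmoid's saturated tails.
    """

    table: pd.DataFrame  # columns: alpha, beta, extra_scale; index: variable

    def __post_init__(self):
        bad = self.table[self.table["beta"] <= self.table["alpha"]]
        if len(bad):
            raise ValueError(f"beta <= alpha for variables: {list(bad.index)}")
        if (self.table["extra_scale"] <= 0).any():
            raise ValueError("extra_scale must be positive")

    @classmethod
    def from_csv(cls, path) -> "NormalRangeTable":
        df = pd.read_csv(path)
        if "extra_scale" not in df.columns:
            df["extra_scale"] = 1.0
        df["extra_scale"] = df["extra_scale"].fillna(1.0)
        return cls(df.set_index("variable")[["alpha", "beta", "extra_scale"]])

    def to_csv(self, path):
        self.table.reset_index().to_csv(path, index=False)

    def params(self, variable: str) -> tuple[float, float, float]:
        if variable not in self.table.index:
            raise KeyError(f"no normal range configured for variable {variable!r}")
        row = self.table.loc[variable]
        return float(row["alpha"]), float(row["beta"]), float(row["extra_scale"])

    @property
    def variables(self) -> list[str]:
        return list(self.table.index)


def load_default_ranges() -> NormalRangeTable:
    """Editable default ranges shipped with the package (adult reference intervals)."""
    with resources.files("jointmm.data").joinpath("normal_ranges.csv").open() as fh:
        return NormalRangeTable.from_csv(fh)


class NormalRangeScaler(TransformerMixin, BaseEstimator):
    """sklearn transformer applying range-normalize -> extra scale -> squash.

    Operates on arrays of shape (..., n_variables) whose last axis is ordered
    like `variables`.  Stateless apart from configuration: `fit` only
    validates that every variable has a range.
    """

    def __init__(self, ranges: NormalRangeTable | None = None,
                 variables: list[str] | None = None,
                 scale_before_squash: bool = True):
        self.ranges = ranges
        self.variables = variables
        self.scale_before_squash = scale_before_squash

    def fit(self, X, y=None):
        ranges = self.ranges if self.ranges is not None else load_default_ranges()
        X = np.asarray(X, dtype=float)
        variables = self.variables
        if variables is None:
            variables = ranges.variables[: X.shape[-1]]
        missing = [v for v in variables if v not in ranges.table.index]
        if missing:
            raise KeyError(f"variables without a configured normal range: {missing}")
        self.variables_ = list(variables)
        self.alpha_ = np.array([ranges.params(v)[0] for v in variables])
        self.beta_ = np.array([ranges.params(v)[1] for v in variables])
        self.extra_scale_ = np.array([ranges.params(v)[2] for v in variables])
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        x_star = 4.0 * (X - self.alpha_) / (self.beta_ - self.alpha_) - 2.0
        if self.scale_before_squash:
            x_star = x_star * self.extra_scale_
        return squash(x_star)

    def inverse_transform(self, X):
        x_star = inverse_squash(np.asarray(X, dtype=float))
        if self.scale_before_squash:
            x_star = x_star / self.extra_scale_
        return (x_star + 2.0) * (self.beta_ - self.alpha_) / 4.0 + self.alpha_


def normalize_longitudinal(panel, ranges: NormalRangeTable,
                           scale_before_squash: bool = True):
    """Return a copy of the panel with values on the squashed normalized scale.

    Masks are untouched; NaN (never-defined) entries stay NaN.
    """
    scaler = NormalRangeScaler(ranges, variables=panel.variables,
                               scale_before_squash=scale_before_squash)
    scaler.fit(panel.values)
    out = panel.copy()
    with np.errstate(invalid="ignore"):
        out.values = scaler.transform(panel.values)
    return out


def denormalize_longitudinal(values: np.ndarray, variables: list[str],
                             ranges: NormalRangeTable,
                             scale_before_squash: bool = True) -> np.ndarray:
    """Map squashed normalized values back to clinical units."""
    scaler = NormalRangeScaler(ranges, variables=variables,
                               scale_before_squash=scale_before_squash)
    scaler.fit(np.zeros((1, len(variables))))
    return scaler.inverse_transform(values)


class BaselineStandardizer(TransformerMixin, BaseEstimator):
    """Center/scale continuous baseline covariates, one-hot encode categoricals.

    Statistics come exclusively from the rows passed to `fit` (the training
    fold); `transform` never re-estimates them.
    """

    def __init__(self, categorical: list[str] | None = None):
        self.categorical = categorical

    def fit(self, B: pd.DataFrame, y=None):
        cat = self.categorical
        if cat is None:
            cat = [c for c in B.columns
                   if B[c].dtype == object or isinstance(B[c].dtype, pd.CategoricalDtype)
                   or B[c].dtype == bool]
        self.categorical_ = list(cat)
        self.continuous_ = [c for c in B.columns if c not in self.categorical_]
        self.mean_ = B[self.continuous_].mean()
        sd = B[self.continuous_].std(ddof=0)
        zero = sd[sd == 0].index.tolist()
        if zero:
            warnings.warn(f"zero-variance baseline columns scaled by 1: {zero}")
            sd[sd == 0] = 1.0
        self.scale_ = sd
        self.categories_ = {c: sorted(B[c].dropna().astype(str).unique())
                            for c in self.categorical_}
        return self

    def transform(self, B: pd.DataFrame) -> pd.DataFrame:
        cont = (B[self.continuous_] - self.mean_) / self.scale_
        pieces = [cont]
        for c in self.categorical_:
            vals = B[c].astype(str)
            for level in self.categories_[c]:
                pieces.append((vals == level).astype(float).rename(f"{c}={level}"))
        return pd.concat(pieces, axis=1)

    def get_feature_names_out(self, input_features=None):
        names = list(self.continuous_)
        for c in self.categorical_:
            names += [f"{c}={level}" for level in self.categories_[c]]
        return np.asarray(names, dtype=object)


def standardize_baseline(B: pd.DataFrame, stats_from: np.ndarray,
                         categorical: list[str] | None = None):
    """Standardize `B` with statistics from rows `stats_from` (train indices)."""
    std = BaselineStandardizer(categorical=categorical)
    std.fit(B.iloc[np.asarray(stats_from)])
    return std.transform(B), std


def impute_cohort(B: pd.DataFrame, panel, train_idx: np.ndarray | None = None):
    """Baseline: mode (categorical) / mean (continuous); longitudinal:
    train-mean at period 0, then last observation carried forward."""
    if train_idx is None:
        train_idx = np.arange(len(B))
    train_idx = np.asarray(train_idx)

    B_out = B.copy()
    B_train = B.iloc[train_idx]
    for c in B.columns:
        if not B_out[c].isna().any():
            continue
        if B[c].dtype == object or isinstance(B[c].dtype, pd.CategoricalDtype):
            fill = B_train[c].mode(dropna=True)
            if len(fill) == 0:
                raise ValueError(f"baseline column {c!r} entirely missing in train fold")
            B_out[c] = B_out[c].fillna(fill.iloc[0])
        else:
            B_out[c] = B_out[c].fillna(B_train[c].mean())

    out = panel.copy()
    X, M = out.values, out.mask
    n, T, J = X.shape
    obs = (M == 1) & np.isfinite(X)
    never = ~obs.any(axis=(0, 1))
    if never.any():
        raise ValueError(
            "variables never observed for any patient at any time: "
            f"{[panel.variables[j] for j in np.flatnonzero(never)]}")
    Xf = np.where(obs, X, np.nan)
    # period-0 gaps take the train-fold mean at period 0 (fallback: overall train mean)
    for j in range(J):
        col0 = Xf[train_idx, 0, j]
        mean0 = np.nanmean(col0) if np.isfinite(col0).any() else np.nanmean(Xf[train_idx, :, j])
        miss0 = ~np.isfinite(Xf[:, 0, j])
        Xf[miss0, 0, j] = mean0
    # forward fill later gaps
    for t in range(1, T):
        gap = ~np.isfinite(Xf[:, t, :])
        Xf[:, t, :] = np.where(gap, Xf[:, t - 1, :], Xf[:, t, :])
    out.values = Xf
    return B_out, out


def filter_variables(B: pd.DataFrame, panel, baseline_thresh: float = 0.15,
                     longitudinal_thresh: float = 0.70):
    """Drop baseline variables with missing fraction above `baseline_thresh`
    and longitudinal variables with missing fraction (over the whole
    follow-up) above `longitudinal_thresh`."""
    for th in (baseline_thresh, longitudinal_thresh):
        if not 0.0 <= th <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    b_missing = B.isna().mean()
    keep_b = [c for c in B.columns if b_missing[c] <= baseline_thresh]
    long_missing = 1.0 - panel.mask.mean(axis=(0, 1))
    keep_j = [j for j in range(len(panel.variables))
              if long_missing[j] <= longitudinal_thresh]
    if not keep_b and not keep_j:
        raise ValueError("all variables dropped by missingness filtering")
    out = panel.copy()
    out.values = out.values[:, :, keep_j]
    out.mask = out.mask[:, :, keep_j]
    out.variables = [panel.variables[j] for j in keep_j]
    return B[keep_b], out, {"baseline": keep_b, "longitudinal": out.variables}


@dataclass
class SplitPlan:
    """One 80/20 train/test split plus five 75/25 resplits of the 80%."""

    test: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    seed: int = 0

    @property
    def train_full(self) -> np.ndarray:
        return np.sort(np.concatenate(self.folds[0]))

    def validate(self, n: int):
        test = set(self.test.tolist())
        for tr, va in self.folds:
            tr_s, va_s = set(tr.tolist()), set(va.tolist())
            assert not (tr_s & va_s), "train/validation overlap"
            assert not (tr_s & test) and not (va_s & test), "test leakage"
            assert tr_s | va_s == set(self.train_full.tolist())


def split_cohort(n: int, seed: int = 0, test_frac: float = 0.20,
                 val_frac: float = 0.25, n_folds: int = 5) -> SplitPlan:
    if n < 10:
        raise ValueError("need at least 10 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(np.floor(n * test_frac))
    test = np.sort(perm[:n_test])
    train_full = perm[n_test:]
    folds = []
    for k in range(n_folds):
        sub = np.random.default_rng((seed, k)).permutation(train_full)
        n_val = int(np.floor(len(sub) * val_frac))
        folds.append((np.sort(sub[n_val:]), np.sort(sub[:n_val])))
    plan = SplitPlan(test=test, folds=folds, seed=seed)
    plan.validate(n)
    return plan
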