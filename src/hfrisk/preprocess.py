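"""Cohort preprocessing: stratified splitting, the two imputation
strategies, and quantile normalization.

The two model families use different imputation schemes: the penalized
linear model imputes with chained equations (a single completed dataset),
while the neural hazard model imputes with the training mean and keeps a
binary "was missing" flag column per affected covariate, followed by a
quantile transform of the continuous columns to a standard normal shape.
Every state here is fitted on training rows only and applied unchanged to
validation and test rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.preprocessing import QuantileTransformer

from .cohort import CohortTable

logger = logging.getLogger(__name__)

FLAG_SUFFIX = "_missing"


def _is_binary(values: np.ndarray) -> bool:
    v = values[~np.isnan(values)]
    return np.isin(np.unique(v), (0.0, 1.0)).all()


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

@dataclass
class SplitIndex:
    """Disjoint, exhaustive train/validation/test assignment per subject."""
    assignment: pd.Series  # subject_id -> {"train","validation","test"}
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, part: str) -> np.ndarray:
        return self.assignment.index[self.assignment == part].to_numpy()

    def apply(self, cohort: CohortTable) -> tuple[CohortTable, CohortTable, CohortTable]:
        sid = pd.Series(np.arange(cohort.n), index=cohort.subject_id)
        parts = []
        for part in ("train", "validation", "test"):
            idx = np.sort(sid.loc[self.ids(part)].to_numpy())
            parts.append(cohort.subset(idx))
        return tuple(parts)


def _apportion(n: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items to the fractions."""
    raw = n * fractions
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def split_cohort(cohort: CohortTable,
                 fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                 seed: int = 0) -> SplitIndex:
    """Random train/validation/test split stratified by event status.

    Allocation is done separately within events and censored subjects with
    largest-remainder rounding, so each part's event fraction matches the
    overall fraction as closely as the integers allow.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three positive numbers summing to 1")
    if cohort.n_events == 0 or cohort.n_events == cohort.n:
        raise ValueError("degenerate cohort: need both events and censored subjects")

    rng = np.random.default_rng(seed)
    labels = np.empty(cohort.n, dtype=object)
    names = np.array(["train", "validation", "test"], dtype=object)
    for stratum in (1, 0):
        pos = np.flatnonzero(cohort.event == stratum)
        pos = rng.permutation(pos)
        counts = _apportion(len(pos), np.asarray(fractions))
        bounds = np.cumsum(counts)
        labels[pos[: bounds[0]]] = names[0]
        labels[pos[bounds[0]: bounds[1]]] = names[1]
        labels[pos[bounds[1]:]] = names[2]

    return SplitIndex(
        assignment=pd.Series(labels, index=pd.Index(cohort.subject_id, name="subject_id")),
        fractions=fractions,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Mean + flag imputer (neural model family)
# ---------------------------------------------------------------------------

@dataclass
class MeanFlagImputer:
    """Impute with the training mean; add one binary flag column per
    covariate that had missing values in training."""
    means: dict[str, float] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)

    def transform(self, cohort: CohortTable) -> CohortTable:
        cov = cohort.covariates.copy()
        flags = {}
        for name in self.flagged:
            flags[name + FLAG_SUFFIX] = cov[name].isna().astype(float) \
                if name in cov.columns else pd.Series(0.0, index=cov.index)
        for name, mean in self.means.items():
            if name in cov.columns:
                cov[name] = cov[name].fillna(mean)
        for fname, fcol in flags.items():
            if fname not in cov.columns:  # idempotent on already-flagged data
                cov[fname] = fcol
        if cov.isna().any().any():
            bad = sorted(cov.columns[cov.isna().any()])
            raise ValueError(f"columns missing in data but never seen at fit: {bad}")
        return cohort.with_covariates(cov)


def fit_mean_flag_imputer(train: CohortTable) -> MeanFlagImputer:
    means, flagged = {}, []
    for name in train.covariate_names:
        col = train.covariates[name]
        if col.isna().all():
            raise ValueError(f"covariate {name!r} is entirely missing in training data")
        means[name] = float(col.mean())
        if col.isna().any():
            flagged.append(name)
    return MeanFlagImputer(means=means, flagged=flagged)


# ---------------------------------------------------------------------------
# Chained-equation imputer (linear model family)
# ---------------------------------------------------------------------------

@dataclass
class ChainedImputer:
    """Single-dataset chained-equation imputation.

    From a mean/mode initialization, each covariate with training
    missingness is regressed on all the others (linear model for continuous
    columns, logistic for binary) and its missing entries replaced by the
    prediction; the cycle repeats ``n_iterations`` times. The fitted
    per-column models from the final cycle are reused to transform new data,
    so the imputation of validation/test rows depends on training rows only.
    Deterministic: predictions are conditional means/modes, no draws.
    """
    n_iterations: int = 10
    seed: int = 0
    columns: list[str] = field(default_factory=list)
    means: dict[str, float] = field(default_factory=dict)
    binary: dict[str, bool] = field(default_factory=dict)
    models: dict[str, object] = field(default_factory=dict)  # name -> fitted sklearn model or None

    def _initial_fill(self, cov: pd.DataFrame) -> pd.DataFrame:
        out = cov.copy()
        for name in self.columns:
            fill = round(self.means[name]) if self.binary[name] else self.means[name]
            out[name] = out[name].fillna(fill)
        return out

    def _predict_column(self, name: str, completed: pd.DataFrame) -> np.ndarray:
        model = self.models.get(name)
        others = [c for c in self.columns if c != name]
        if model is None:  # mean fallback (collinear or degenerate fit)
            return np.full(len(completed), self.means[name])
        X = completed[others].to_numpy(dtype=float)
        if self.binary[name]:
            return model.predict_proba(X)[:, 1].round()
        return model.predict(X)

    def transform(self, cohort: CohortTable) -> CohortTable:
        cov = cohort.covariates[self.columns].copy()
        missing = cov.isna()
        if not missing.any().any():
            return cohort.with_covariates(cov)
        completed = self._initial_fill(cov)
        for _ in range(self.n_iterations):
            for name in self.columns:
                m = missing[name].to_numpy()
                if m.any():
                    completed.loc[m, name] = self._predict_column(name, completed)[m]
        return cohort.with_covariates(completed)


def fit_chained_imputer(train: CohortTable, n_iterations: int = 10,
                        seed: int = 0) -> ChainedImputer:
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if len(train.covariate_names) < 2:
        raise ValueError("chained imputation needs at least two covariates")

    cols = train.covariate_names
    cov = train.covariates.copy()
    state = ChainedImputer(n_iterations=n_iterations, seed=seed, columns=cols)
    for name in cols:
        col = cov[name]
        if col.isna().all():
            raise ValueError(f"covariate {name!r} is entirely missing in training data")
        state.binary[name] = _is_binary(col.to_numpy(dtype=float))
        state.means[name] = float(col.mean())

    missing = cov.isna()
    targets = [c for c in cols if missing[c].any()]
    completed = state._initial_fill(cov)
    for _ in range(n_iterations):
        for name in targets:
            others = [c for c in cols if c != name]
            obs = ~missing[name].to_numpy()
            X = completed.loc[obs, others].to_numpy(dtype=float)
            y = completed.loc[obs, name].to_numpy(dtype=float)
            model = None
            try:
                if state.binary[name]:
                    if len(np.unique(y)) < 2:
                        raise ValueError("single observed class")
                    model = LogisticRegression(max_iter=200).fit(X, y)
                else:
                    model = LinearRegression().fit(X, y)
                    if not np.all(np.isfinite(model.coef_)):
                        raise ValueError("non-finite coefficients")
            except Exception as exc:  # collinear/degenerate -> mean fallback
                warnings.warn(
                    f"chained imputer: falling back to mean for {name!r} ({exc})",
                    stacklevel=2)
                model = None
            state.models[name] = model
            m = missing[name].to_numpy()
            completed.loc[m, name] = state._predict_column(name, completed)[m]
    for name in cols:
        state.models.setdefault(name, None)
    return state


# ---------------------------------------------------------------------------
# Quantile normalizer (continuous columns -> standard normal shape)
# ---------------------------------------------------------------------------

@dataclass
class QuantileNormalizer:
    """Per-column monotone map of continuous covariates to N(0, 1) via
    empirical quantiles; binary and flag columns pass through unchanged.
    Out-of-range values clip to the extreme training quantiles."""
    transformers: dict[str, object] = field(default_factory=dict)  # name -> QT or "constant"
    continuous: list[str] = field(default_factory=list)

    def transform(self, cohort: CohortTable) -> CohortTable:
        cov = cohort.covariates.copy()
        for name in self.continuous:
            if name not in cov.columns:
                continue
            qt = self.transformers[name]
            vals = cov[name].to_numpy(dtype=float)
            obs = ~np.isnan(vals)
            if qt == "constant":
                vals = np.where(obs, 0.0, vals)
            elif obs.any():
                vals[obs] = qt.transform(vals[obs].reshape(-1, 1)).ravel()
            cov[name] = vals
        return cohort.with_covariates(cov)


def fit_quantile_normalizer(train: CohortTable,
                            continuous: list[str] | None = None) -> QuantileNormalizer:
    """Fit empirical-quantile -> standard-normal maps on training rows.

    ``continuous`` defaults to every covariate that is not 0/1-valued in
    training. Constant columns map to zero with a warning.
    """
    state = QuantileNormalizer()
    for name in train.covariate_names:
        vals = train.covariates[name].to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if continuous is None:
            if len(obs) == 0 or _is_binary(vals) or name.endswith(FLAG_SUFFIX):
                continue
        elif name not in continuous:
            continue
        if len(np.unique(obs)) <= 1:
            warnings.warn(f"quantile normalizer: constant column {name!r} mapped to zeros",
                          stacklevel=2)
            state.transformers[name] = "constant"
        else:
            qt = QuantileTransformer(
                n_quantiles=min(1000, len(obs)),
                output_distribution="normal",
                subsample=None,
            )
            qt.fit(obs.reshape(-1, 1))
            state.transformers[name] = qt
        state.continuous.append(name)
    return state


# ---------------------------------------------------------------------------
# Per-model-family convenience pipelines
# ---------------------------------------------------------------------------

@dataclass
class NeuralPreprocessor:
    """Mean+flag imputation followed by quantile normalization, the
    preparation the neural hazard model trains on."""
    imputer: MeanFlagImputer
    normalizer: QuantileNormalizer

    def transform(self, cohort: CohortTable) -> CohortTable:
        return self.normalizer.transform(self.imputer.transform(cohort))


def fit_neural_preprocessor(train: CohortTable) -> NeuralPreprocessor:
    imputer = fit_mean_flag_imputer(train)
    normalizer = fit_quantile_normalizer(imputer.transform(train))
    return NeuralPreprocessor(imputer=imputer, normalizer=normalizer)
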