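"""Greedy forward feature selection by validation c-index.

At each step every remaining candidate is added in turn to the current set,
a model is fitted on the training rows, and the candidate giving the highest
validation c-index is kept. Selection stops when the best step-to-step gain
stays below ``min_gain`` for ``patience_steps`` consecutive steps, when
``max_features`` is reached, or when candidates run out. Ties are broken by
candidate name order. The validation set is disjoint from training and the
test set is never consulted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .evaluate import harrell_cindex
from .linear_cox import fit_cox
from .neural_hazard import NetworkArch, TrainingConfig, train_phnn

logger = logging.getLogger(__name__)

__all__ = ["StopRule", "SelectionTrace", "forward_select",
           "cox_model_factory", "phnn_model_factory"]


@dataclass
class StopRule:
    """"Substantial improvement" quantified: stop after ``patience_steps``
    consecutive steps whose best gain is below ``min_gain``."""
    min_gain: float = 0.002
    patience_steps: int = 2
    max_features: int = 25


@dataclass
class SelectionTrace:
    selected: list[str]
    steps: pd.DataFrame            # step, candidate, cindex, gain
    candidate_table: pd.DataFrame  # step, candidate, cindex (all evaluated)
    stopping_reason: str

    def to_csv(self, path) -> None:
        self.candidate_table.to_csv(path, index=False)


def cox_model_factory():
    """Factory fitting an unpenalized proportional-hazards model on the
    candidate subset (fast ranking of candidates)."""
    def factory(train: CohortTable, validation: CohortTable, seed: int):
        return fit_cox_adapter(train)
    return factory


class _CoxAdapter:
    def __init__(self, fit, names):
        self._fit = fit
        self._names = names

    def predict_log_hazard(self, covariates: pd.DataFrame) -> np.ndarray:
        X = covariates[self._names].to_numpy(dtype=float)
        return X @ self._fit.beta.to_numpy()


def fit_cox_adapter(train: CohortTable) -> _CoxAdapter:
    fit = fit_cox(train, ridge=1e-8)
    return _CoxAdapter(fit, train.covariate_names)


def phnn_model_factory(arch: NetworkArch | None = None,
                       selection_epochs: int = 150,
                       learning_rate: float = 1e-2,
                       patience: int = 30):
    """Factory training a reduced-epoch PHNN: during selection only the
    ranking of candidates matters, so a short training run suffices; the
    chosen set is refit fully afterwards."""
    arch = arch or NetworkArch()

    def factory(train: CohortTable, validation: CohortTable, seed: int):
        hyper = TrainingConfig(learning_rate=learning_rate,
                               max_epochs=selection_epochs, patience=patience)
        return train_phnn(train, validation, arch=arch, hyper=hyper, seed=seed)
    return factory


def forward_select(candidates: list[str], train: CohortTable,
                   validation: CohortTable, model_factory,
                   stop_rule: StopRule | None = None, seed: int = 0,
                   selected: list[str] | None = None) -> SelectionTrace:
    """Run the greedy forward search.

    ``model_factory(train, validation, seed)`` receives cohorts restricted
    to the candidate subset and returns a fitted object exposing
    ``predict_log_hazard``. A factory failure on one candidate skips that
    candidate with a warning. ``selected`` allows continuing from an
    existing set.

    The returned ``selected`` list drops features added during a trailing
    run of below-threshold steps (they were only probed while waiting out
    the patience window); the full path, including those steps, is in
    ``steps`` and ``candidate_table``.
    """
    stop_rule = stop_rule or StopRule()
    unknown = [c for c in candidates if c not in train.covariate_names]
    if unknown:
        raise ValueError(f"unknown candidate covariates: {unknown}")
    selected = list(selected or [])
    remaining = sorted(c for c in set(candidates) - set(selected))
    if not candidates:
        raise ValueError("need at least one candidate")

    def fit_score(features: list[str]) -> float:
        tr = train.with_covariates(train.covariates[features])
        va = validation.with_covariates(validation.covariates[features])
        model = model_factory(tr, va, seed)
        return harrell_cindex(va.time, va.event,
                              model.predict_log_hazard(va.covariates))

    steps, cand_rows = [], []
    best_so_far = 0.5  # uninformative baseline
    low_gain_streak = 0
    reason = "max_features"
    step = 0
    while True:
        if not remaining:
            reason = "no candidates"
            break
        if len(selected) >= stop_rule.max_features:
            reason = "max_features"
            break
        step += 1
        best_cand, best_c = None, -np.inf
        for cand in remaining:  # name order ⇒ deterministic tie-break
            try:
                c = fit_score(selected + [cand])
            except Exception as exc:
                warnings.warn(f"candidate {cand!r} skipped: {exc}", stacklevel=2)
                cand_rows.append((step, cand, np.nan))
                continue
            cand_rows.append((step, cand, c))
            if c > best_c:
                best_cand, best_c = cand, c
        if best_cand is None:
            reason = "no candidates"
            break
        gain = best_c - best_so_far
        steps.append((step, best_cand, best_c, gain))
        selected.append(best_cand)
        remaining.remove(best_cand)
        best_so_far = max(best_so_far, best_c)
        if gain < stop_rule.min_gain:
            low_gain_streak += 1
            if low_gain_streak >= stop_rule.patience_steps:
                reason = "no substantial improvement"
                break
        else:
            low_gain_streak = 0

    steps_df = pd.DataFrame(steps, columns=["step", "candidate", "cindex", "gain"])
    # trim the trailing below-threshold probes from the final set
    kept = list(steps_df.candidate)
    while kept and steps_df.gain.iloc[len(kept) - 1] < stop_rule.min_gain:
        kept.pop()
    n_probed = len(steps_df) - len(kept)
    final = selected[: len(selected) - n_probed] if n_probed else selected
    return SelectionTrace(
        selected=final,
        steps=steps_df,
        candidate_table=pd.DataFrame(cand_rows, columns=["step", "candidate", "cindex"]),
        stopping_reason=reason,
    )
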