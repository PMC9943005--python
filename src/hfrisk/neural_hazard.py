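"""Proportional-hazards neural network (PHNN).

The relative hazard is r(X) = exp(f(X)) with f a fully connected
feed-forward network (default hidden sizes 128, 64, 32, 15, rectifier
nonlinearity, dropout 0.5 after every hidden activation, single linear
output). The weights minimize the negative Cox partial likelihood of the
network scores over the training set — the same Breslow partial likelihood
the linear model uses, with beta . X replaced by f(X) — trained full-batch
with Adam and early stopping on validation loss.

The network, its backpropagation and the optimizer are implemented here on
numpy: the partial-likelihood gradient with respect to the per-subject
scores comes in closed form from ``linear_cox.partial_loglik_scores`` and is
chained through the layers analytically. Dropout is inverted (activations
rescaled at train time) and disabled at inference, so predictions are
deterministic. Absolute survival uses a Breslow baseline estimated on the
training scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .linear_cox import (BreslowBaseline, breslow_baseline, design_matrix,
                         partial_loglik_scores)

__all__ = ["NetworkArch", "TrainingConfig", "NeuralHazardModel",
           "neural_partial_loss", "train_phnn"]


@dataclass
class NetworkArch:
    hidden: tuple[int, ...] = (128, 64, 32, 15)
    dropout: float = 0.5

    def validate(self) -> None:
        if any(h <= 0 for h in self.hidden):
            raise ValueError("hidden layer widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainingConfig:
    """Full-batch Adam settings. One epoch is one exact gradient step, so
    convergence with heavy dropout takes hundreds of epochs and the early
    stopping patience is sized accordingly."""
    learning_rate: float = 1e-2
    max_epochs: int = 5000
    patience: int = 300
    min_delta: float = 0.0


def neural_partial_loss(scores: np.ndarray, data: CohortTable) -> float:
    """Negative Breslow partial log-likelihood of an arbitrary per-subject
    log-hazard score vector (shift-invariant in the scores)."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite score")
    return -partial_loglik_scores(scores, data.time, data.event)


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

class _MLP:
    """Feed-forward net with ReLU hidden layers, inverted dropout, Adam."""

    def __init__(self, n_inputs: int, arch: NetworkArch, rng: np.random.Generator):
        self.arch = arch
        dims = [n_inputs, *arch.hidden, 1]
        self.weights = [rng.standard_normal((dims[i], dims[i + 1]))
                        * np.sqrt(2.0 / dims[i]) for i in range(len(dims) - 1)]
        self.biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_t = 0

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Scores (n,) plus the caches backprop needs when training."""
        a = X
        activations, masks = [X], []
        keep = 1.0 - self.arch.dropout
        for li in range(len(self.weights) - 1):
            z = a @ self.weights[li] + self.biases[li]
            a = np.maximum(z, 0.0)
            if training and self.arch.dropout > 0.0:
                mask = (rng.random(a.shape) < keep) / keep
                a = a * mask
            else:
                mask = None
            masks.append(mask)
            activations.append(a)
        scores = (a @ self.weights[-1] + self.biases[-1]).ravel()
        return scores, activations, masks

    def backward(self, grad_scores: np.ndarray, activations, masks):
        """Gradients of the loss w.r.t. every weight and bias."""
        gw = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        delta = grad_scores.reshape(-1, 1)  # (n, 1) at the output unit
        gw[-1] = activations[-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        back = delta @ self.weights[-1].T
        for li in range(len(self.weights) - 2, -1, -1):
            a = activations[li + 1]
            if masks[li] is not None:
                back = back * masks[li]
            back = back * (a > 0.0)  # ReLU gate (post-dropout a keeps the sign)
            gw[li] = activations[li].T @ back
            gb[li] = back.sum(axis=0)
            if li > 0:
                back = back @ self.weights[li].T
        return gw, gb

    def adam_step(self, gw, gb, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        params = self.weights + self.biases
        grads = gw + gb
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = beta1 * self._adam_m[i] + (1 - beta1) * g
            self._adam_v[i] = beta2 * self._adam_v[i] + (1 - beta2) * g * g
            mhat = self._adam_m[i] / (1 - beta1 ** self._adam_t)
            vhat = self._adam_v[i] / (1 - beta2 ** self._adam_t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def get_weights(self):
        return ([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def set_weights(self, saved):
        ws, bs = saved
        self.weights = [w.copy() for w in ws]
        self.biases = [b.copy() for b in bs]


# ---------------------------------------------------------------------------
# Fitted model
# ---------------------------------------------------------------------------

@dataclass
class NeuralHazardModel:
    """Trained PHNN: log-relative-hazard f(X) plus a Breslow baseline for
    absolute survival prediction at any horizon."""
    arch: NetworkArch
    schema: list[str]
    net: _MLP = field(repr=False)
    baseline: BreslowBaseline
    training_log: pd.DataFrame = field(repr=False)

    def _matrix(self, covariates: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.schema if c not in covariates.columns]
        extra = [c for c in covariates.columns if c not in self.schema]
        if missing or extra:
            raise ValueError(
                f"covariate schema mismatch: missing {missing}, extra {extra}")
        X = covariates[self.schema].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing covariate values at predict time")
        return X

    def predict_log_hazard(self, covariates: pd.DataFrame) -> np.ndarray:
        """Deterministic inference-mode scores (dropout disabled)."""
        scores, _, _ = self.net.forward(self._matrix(covariates), training=False)
        return scores

    def predict_survival(self, covariates: pd.DataFrame, t) -> np.ndarray:
        h0 = self.baseline(t)
        rel = np.exp(self.predict_log_hazard(covariates))
        return np.exp(-np.outer(rel, h0)).squeeze()

    def predict_risk(self, covariates: pd.DataFrame, t) -> np.ndarray:
        return 1.0 - self.predict_survival(covariates, t)

    # -- persistence (text-only: schema, weights and baseline as JSON) -----

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "schema.json").write_text(json.dumps({
            "schema": self.schema,
            "hidden": list(self.arch.hidden),
            "dropout": self.arch.dropout,
        }))
        (d / "weights.json").write_text(json.dumps({
            "weights": [w.tolist() for w in self.net.weights],
            "biases": [b.tolist() for b in self.net.biases],
        }))
        (d / "baseline.json").write_text(json.dumps({
            "times": self.baseline.times.tolist(),
            "cumhaz": self.baseline.cumhaz.tolist(),
        }))
        self.training_log.to_csv(d / "training_log.csv", index=False)

    @classmethod
    def load(cls, directory) -> "NeuralHazardModel":
        d = Path(directory)
        meta = json.loads((d / "schema.json").read_text())
        arch = NetworkArch(hidden=tuple(meta["hidden"]), dropout=meta["dropout"])
        net = _MLP(len(meta["schema"]), arch, np.random.default_rng(0))
        wb = json.loads((d / "weights.json").read_text())
        net.weights = [np.asarray(w, dtype=float) for w in wb["weights"]]
        net.biases = [np.asarray(b, dtype=float) for b in wb["biases"]]
        base = json.loads((d / "baseline.json").read_text())
        return cls(
            arch=arch, schema=meta["schema"], net=net,
            baseline=BreslowBaseline(np.asarray(base["times"], dtype=float),
                                     np.asarray(base["cumhaz"], dtype=float)),
            training_log=pd.read_csv(d / "training_log.csv"),
        )


def train_phnn(train: CohortTable, validation: CohortTable,
               arch: NetworkArch | None = None,
               hyper: TrainingConfig | None = None,
               seed: int = 0) -> NeuralHazardModel:
    """Train the PHNN by full-batch Adam on the negative partial likelihood.

    Inputs must already be preprocessed (imputed, flagged, quantile
    normalized). Each epoch evaluates the exact partial likelihood over the
    whole training risk structure (risk sets are global, so full-batch
    avoids the bias of minibatched partial likelihoods at this scale), then
    the validation loss in inference mode. The weights returned are those of
    the best validation epoch; training stops once the validation loss has
    not improved for more than ``patience`` consecutive epochs.
    """
    arch = arch or NetworkArch()
    hyper = hyper or TrainingConfig()
    arch.validate()
    if validation.n == 0 or validation.n_events == 0:
        raise ValueError("validation set must be nonempty and contain events")

    X_tr, names = design_matrix(train)
    X_va, va_names = design_matrix(validation)
    if va_names != names:
        raise ValueError("train and validation covariate schemas differ")

    rng = np.random.default_rng(seed)
    net = _MLP(X_tr.shape[1], arch, rng)
    n_ev = max(train.n_events, 1)
    n_ev_va = max(validation.n_events, 1)

    def val_loss() -> float:
        s, _, _ = net.forward(X_va, training=False)
        return neural_partial_loss(s, validation) / n_ev_va

    log = []
    best = np.inf
    best_weights = net.get_weights()
    wait = 0
    for epoch in range(hyper.max_epochs):
        scores, acts, masks = net.forward(X_tr, training=True, rng=rng)
        ll, g = partial_loglik_scores(scores, train.time, train.event,
                                      return_grad=True)
        loss = -ll / n_ev
        if not np.isfinite(loss):
            raise RuntimeError(
                "training diverged (non-finite loss); lower the learning rate")
        gw, gb = net.backward(-g / n_ev, acts, masks)
        net.adam_step(gw, gb, hyper.learning_rate)

        vl = val_loss()
        log.append((epoch, loss, vl))
        if vl < best - hyper.min_delta:
            best = vl
            best_weights = net.get_weights()
            wait = 0
        else:
            wait += 1
            if wait > hyper.patience:
                break

    net.set_weights(best_weights)
    final_scores, _, _ = net.forward(X_tr, training=False)
    baseline = breslow_baseline(final_scores, train.time, train.event)
    return NeuralHazardModel(
        arch=arch, schema=names, net=net, baseline=baseline,
        training_log=pd.DataFrame(log, columns=["epoch", "train_loss", "val_loss"]),
    )
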