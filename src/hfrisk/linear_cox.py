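"""Elastic-net penalized proportional-hazards model.

The hazard is factorized as h(t|X) = h0(t) exp(beta . X). Coefficients are
estimated by penalized partial-likelihood maximization over a decreasing
lambda path, with the working lambda chosen by 10-fold cross-validation
under the one-standard-error rule: the largest (most parsimonious) lambda
whose CV error is within one standard error of the minimum. Breslow's
estimator of the baseline cumulative hazard turns the relative-hazard score
into absolute survival probabilities, and scaled Schoenfeld residuals
provide the graphical proportional-hazards diagnostic.

The partial log-likelihood, its gradient and Hessian (Breslow ties), the
cross-validation rule, the baseline estimator and the residuals are
implemented here; the coordinate-descent elastic-net path itself is
delegated to scikit-survival's Coxnet solver.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .cohort import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "cox_partial_loglik", "partial_loglik_scores", "fit_cox", "CoxFit",
    "fit_penalized_cox", "CoxPath", "cv_select_lambda", "one_se_lambda",
    "breslow_baseline", "BreslowBaseline", "LinearCoxModel",
    "fit_elastic_net_cox", "scaled_schoenfeld", "hazard_ratio_table",
    "design_matrix",
]


def design_matrix(cohort: CohortTable) -> tuple[np.ndarray, list[str]]:
    """Complete covariate matrix as float array; errors on missing values."""
    cov = cohort.covariates
    if cov.isna().any().any():
        bad = sorted(cov.columns[cov.isna().any()])
        raise ValueError(f"covariates contain missing values (impute first): {bad}")
    return cov.to_numpy(dtype=float), list(cov.columns)


# ---------------------------------------------------------------------------
# Partial likelihood (Breslow ties) on an arbitrary score vector
# ---------------------------------------------------------------------------

def _risk_structure(time: np.ndarray, event: np.ndarray):
    """Sorted-order bookkeeping shared by likelihood/gradient computations.

    Returns ascending sort order, tie-group start index per sorted position
    (risk set of a subject = all positions >= its group start) and group end
    index (exclusive) per sorted position.
    """
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    starts = np.searchsorted(t_sorted, t_sorted, side="left")
    ends = np.searchsorted(t_sorted, t_sorted, side="right")
    return order, t_sorted, starts, ends


def partial_loglik_scores(scores: np.ndarray, time: np.ndarray,
                          event: np.ndarray,
                          return_grad: bool = False):
    """Cox partial log-likelihood of a per-subject log-hazard score vector.

    sum over events i of  s_i - log sum_{j : t_j >= t_i} exp(s_j),
    with Breslow handling of tied event times (each tied event contributes
    the full tie-group risk set). Optionally also returns the gradient with
    respect to the scores, which is what the neural model backpropagates.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if scores.shape != time.shape:
        raise ValueError("scores must be one value per subject")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite score")
    if event.sum() == 0:
        raise ValueError("no events: partial likelihood undefined")

    order, _, starts, ends = _risk_structure(time, event)
    s = scores[order]
    d = event[order].astype(float)

    smax = s.max()
    w = np.exp(s - smax)
    # risk-set sums from the right, then indexed at each tie group's start
    revcum = np.cumsum(w[::-1])[::-1]
    S = revcum[starts]  # risk-set sum (shifted scale) per sorted position

    loglik = float(np.sum(d * (s - (np.log(S) + smax))))

    if not return_grad:
        return loglik

    # gradient: d_j - exp(s_j) * sum_{event times tau <= t_j} D_tau / S_tau.
    # A subject is at risk for events in its own tie group, so the cumulative
    # sum is taken through the END of the group.
    cum = np.cumsum(d / S)
    grad_sorted = d - w * cum[ends - 1]
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return loglik, grad


def cox_partial_loglik(beta: np.ndarray, data: CohortTable) -> float:
    """Partial log-likelihood of coefficient vector ``beta`` on a cohort."""
    X, _ = design_matrix(data)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(f"beta must have length {X.shape[1]}")
    return partial_loglik_scores(X @ beta, data.time, data.event)


def _neg_loglik_grad_hess(beta, X, time, event, hess: bool = False):
    """Negative partial log-likelihood, gradient and (optionally) Hessian in
    beta, by a single descending sweep maintaining risk-set sums."""
    n, p = X.shape
    scores = X @ beta
    ll, gs = partial_loglik_scores(scores, time, event, return_grad=True)
    grad = -(X.T @ gs)
    if not hess:
        return -ll, grad, None

    order = np.argsort(-time, kind="stable")  # descending: grow the risk set
    t_s = time[order]
    X_s = X[order]
    d_s = event[order].astype(float)
    w_s = np.exp(scores[order] - scores.max())

    H = np.zeros((p, p))
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:  # absorb the full tie group first
            S0 += w_s[j]
            S1 += w_s[j] * X_s[j]
            S2 += w_s[j] * np.outer(X_s[j], X_s[j])
            j += 1
        D = d_s[i:j].sum()
        if D > 0:
            xbar = S1 / S0
            H += D * (S2 / S0 - np.outer(xbar, xbar))
        i = j
    return -ll, grad, H


@dataclass
class CoxFit:
    """Unpenalized or ridge-penalized proportional-hazards fit."""
    beta: pd.Series
    se: pd.Series
    loglik: float
    ridge: float
    covariance: np.ndarray = field(repr=False)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.beta)


def fit_cox(data: CohortTable, ridge: float = 0.0, tol: float = 1e-9) -> CoxFit:
    """Maximize the (optionally L2-penalized) partial likelihood by L-BFGS
    with the analytic gradient; standard errors from the inverse observed
    information at the optimum."""
    X, names = design_matrix(data)
    time, event = data.time, data.event
    if event.sum() == 0:
        raise ValueError("no events")

    def obj(b):
        nll, g, _ = _neg_loglik_grad_hess(b, X, time, event)
        return nll + 0.5 * ridge * float(b @ b), g + ridge * b

    res = minimize(obj, np.zeros(X.shape[1]), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "gtol": tol, "ftol": 1e-12})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError("Cox fit did not converge to finite coefficients")
    nll, _, H = _neg_loglik_grad_hess(res.x, X, time, event, hess=True)
    info = H + ridge * np.eye(X.shape[1])
    cov = np.linalg.inv(info)
    return CoxFit(
        beta=pd.Series(res.x, index=names),
        se=pd.Series(np.sqrt(np.diag(cov)), index=names),
        loglik=-nll,
        ridge=ridge,
        covariance=cov,
    )


# ---------------------------------------------------------------------------
# Elastic-net path and cross-validated lambda selection
# ---------------------------------------------------------------------------

@dataclass
class CoxPath:
    """Solution path beta(lambda) of the elastic-net penalized model."""
    alphas: np.ndarray          # decreasing lambda grid
    coefs: np.ndarray           # shape (n_lambda, p)
    l1_ratio: float
    feature_names: list[str]

    def beta_at(self, lam: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.alphas - lam)))
        return self.coefs[i]


def fit_penalized_cox(train: CohortTable, l1_ratio: float = 0.5,
                      alphas: np.ndarray | None = None,
                      n_alphas: int = 100,
                      alpha_min_ratio: float = 0.001) -> CoxPath:
    """Fit the elastic-net Cox path on a 100-point log-spaced lambda grid
    from the all-zero solution down to 0.001 of it (unless a grid is given)."""
    X, names = design_matrix(train)
    y = Surv.from_arrays(event=train.event.astype(bool), time=train.time)
    est = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio,
        alphas=None if alphas is None else np.asarray(alphas, dtype=float),
        n_alphas=n_alphas,
        alpha_min_ratio=alpha_min_ratio,
        fit_baseline_model=False,
    )
    est.fit(X, y)
    return CoxPath(
        alphas=np.asarray(est.alphas_, dtype=float),
        coefs=np.asarray(est.coef_).T.copy(),
        l1_ratio=l1_ratio,
        feature_names=names,
    )


def one_se_lambda(lambdas: np.ndarray, mean_err: np.ndarray,
                  se_err: np.ndarray) -> float:
    """One-standard-error rule: the largest lambda whose CV error is within
    one SE of the minimizing lambda's error. Always >= the minimizer."""
    lambdas = np.asarray(lambdas, dtype=float)
    mean_err = np.asarray(mean_err, dtype=float)
    se_err = np.asarray(se_err, dtype=float)
    imin = int(np.argmin(mean_err))
    thresh = mean_err[imin] + se_err[imin]
    ok = mean_err <= thresh
    return float(lambdas[ok].max())


def _stratified_folds(event: np.ndarray, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    fold = np.empty(len(event), dtype=int)
    for stratum in (0, 1):
        pos = rng.permutation(np.flatnonzero(event == stratum))
        fold[pos] = np.arange(len(pos)) % k
    return fold


def cv_select_lambda(path: CoxPath, train: CohortTable, k: int = 10,
                     rule: str = "one_se", seed: int = 0):
    """K-fold cross-validated lambda selection on the path's grid.

    The CV error per fold is the Verweij–van Houwelingen held-out deviance
    contribution: -2 [pll(full data; beta_fold) - pll(training folds;
    beta_fold)], which is well defined even for folds with few events.
    Folds are event-stratified; a fold that ends up with zero events
    triggers one refold with a shifted seed (logged).

    Returns (lambda_star, curve) where curve is a DataFrame with columns
    lam / mean / se.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if train.n_events < k:
        raise ValueError("need at least k events for k-fold CV")
    if rule not in ("one_se", "min"):
        raise ValueError("rule must be 'one_se' or 'min'")

    X, _ = design_matrix(train)
    time, event = train.time, train.event

    fold = _stratified_folds(event, k, seed)
    for attempt in range(10):
        bad = [f for f in range(k) if event[fold == f].sum() == 0]
        if not bad:
            break
        logger.warning("fold(s) %s contain no events; refolding", bad)
        fold = _stratified_folds(event, k, seed + attempt + 1)

    errors = np.zeros((k, len(path.alphas)))
    full = train
    for f in range(k):
        keep = fold != f
        sub = train.subset(keep)
        with warnings.catch_warnings():
            # the largest grid alpha legitimately zeroes all coefficients
            warnings.filterwarnings("ignore", message="all coefficients are zero")
            sub_path = fit_penalized_cox(sub, l1_ratio=path.l1_ratio,
                                         alphas=path.alphas)
        for j, lam in enumerate(path.alphas):
            beta = sub_path.beta_at(lam)
            pll_full = partial_loglik_scores(X @ beta, full.time, full.event)
            pll_sub = partial_loglik_scores(
                X[keep] @ beta, sub.time, sub.event)
            errors[f, j] = -2.0 * (pll_full - pll_sub)

    mean = errors.mean(axis=0)
    se = errors.std(axis=0, ddof=1) / np.sqrt(k)
    if rule == "min":
        lam_star = float(path.alphas[int(np.argmin(mean))])
    else:
        lam_star = one_se_lambda(path.alphas, mean, se)
    curve = pd.DataFrame({"lam": path.alphas, "mean": mean, "se": se})
    return lam_star, curve


# ---------------------------------------------------------------------------
# Breslow baseline and the assembled model
# ---------------------------------------------------------------------------

@dataclass
class BreslowBaseline:
    """Step-function estimate of the baseline cumulative hazard:
    H0(t) = sum_{event times <= t} D_tau / sum_{j at risk} exp(score_j)."""
    times: np.ndarray
    cumhaz: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        if self.times.size and np.any(t > self.times[-1]):
            logger.info("horizon beyond last observed event time; "
                        "returning the last baseline value")
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[0.0], self.cumhaz])
        return vals[idx]


def breslow_baseline(scores: np.ndarray, time: np.ndarray,
                     event: np.ndarray) -> BreslowBaseline:
    scores = np.asarray(scores, dtype=float)
    order, t_sorted, starts, _ = _risk_structure(time, event)
    s = scores[order]
    d = event[order].astype(float)
    w = np.exp(s)
    revcum = np.cumsum(w[::-1])[::-1]
    S = revcum[starts]

    ev = d > 0
    ev_times, first = np.unique(t_sorted[ev], return_index=True)
    # per unique event time: D / S (S identical within a tie group)
    increments = []
    for tau in ev_times:
        in_group = t_sorted == tau
        D = d[in_group].sum()
        S_tau = S[np.flatnonzero(in_group)[0]]
        increments.append(D / S_tau)
    return BreslowBaseline(times=ev_times, cumhaz=np.cumsum(increments))


@dataclass
class LinearCoxModel:
    """Fitted penalized proportional-hazards model with absolute-risk
    support: log-relative-hazard score beta . X plus a Breslow baseline."""
    beta: pd.Series
    lambda_: float
    l1_ratio: float
    baseline: BreslowBaseline
    cv_curve: pd.DataFrame | None = None

    @property
    def selected(self) -> list[str]:
        return list(self.beta.index[self.beta != 0.0])

    @property
    def excluded(self) -> list[str]:
        return list(self.beta.index[self.beta == 0.0])

    def _scores(self, covariates: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.beta.index if c not in covariates.columns]
        if missing:
            raise ValueError(f"covariates absent at predict time: {missing}")
        X = covariates[list(self.beta.index)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing covariate values at predict time")
        return X @ self.beta.to_numpy()

    def predict_log_hazard(self, covariates: pd.DataFrame) -> np.ndarray:
        return self._scores(covariates)

    def predict_survival(self, covariates: pd.DataFrame, t) -> np.ndarray:
        """S(t | X) = exp(-H0(t) exp(beta . X)); rows x horizons."""
        h0 = self.baseline(t)
        rel = np.exp(self._scores(covariates))
        return np.exp(-np.outer(rel, h0)).squeeze()

    def predict_risk(self, covariates: pd.DataFrame, t) -> np.ndarray:
        return 1.0 - self.predict_survival(covariates, t)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "lambda": self.lambda_,
            "l1_ratio": self.l1_ratio,
            "baseline_times": self.baseline.times.tolist(),
            "baseline_cumhaz": self.baseline.cumhaz.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearCoxModel":
        return cls(
            beta=pd.Series(d["beta"]),
            lambda_=d["lambda"],
            l1_ratio=d["l1_ratio"],
            baseline=BreslowBaseline(
                times=np.asarray(d["baseline_times"], dtype=float),
                cumhaz=np.asarray(d["baseline_cumhaz"], dtype=float)),
        )


def fit_elastic_net_cox(train: CohortTable, l1_ratio: float = 0.5,
                        k: int = 10, rule: str = "one_se",
                        seed: int = 0) -> LinearCoxModel:
    """Full elastic-net workflow: path fit, 10-fold CV with the one-SE rule,
    Breslow baseline at the selected lambda."""
    path = fit_penalized_cox(train, l1_ratio=l1_ratio)
    lam, curve = cv_select_lambda(path, train, k=k, rule=rule, seed=seed)
    beta = pd.Series(path.beta_at(lam), index=path.feature_names)
    X, _ = design_matrix(train)
    baseline = breslow_baseline(X @ beta.to_numpy(), train.time, train.event)
    return LinearCoxModel(beta=beta, lambda_=lam, l1_ratio=l1_ratio,
                          baseline=baseline, cv_curve=curve)


def hazard_ratio_table(model: LinearCoxModel) -> pd.DataFrame:
    """Nonzero coefficients as hazard ratios, sorted by effect magnitude."""
    b = model.beta[model.beta != 0.0]
    tab = pd.DataFrame({
        "covariate": b.index,
        "coefficient": b.to_numpy(),
        "hazard_ratio": np.exp(b.to_numpy()),
    })
    return tab.reindex(tab.coefficient.abs().sort_values(ascending=False).index) \
              .reset_index(drop=True)


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostics
# ---------------------------------------------------------------------------

def scaled_schoenfeld(model, data: CohortTable) -> pd.DataFrame:
    """Scaled Schoenfeld residuals per event, indexed by event time.

    Unscaled residual at an event: the subject's covariates minus the
    risk-set weighted mean. Scaling follows Grambsch–Therneau:
    r* = d * I^{-1} r + beta, with I the observed information at beta and d
    the number of events; under proportional hazards the residuals show no
    time trend.
    """
    beta = model.beta.to_numpy() if hasattr(model, "beta") else np.asarray(model)
    names = list(model.beta.index) if hasattr(model, "beta") else list(data.covariate_names)
    X = data.covariates[names].to_numpy(dtype=float)
    time, event = data.time, data.event
    if event.sum() < 2:
        raise ValueError("need at least two events for Schoenfeld diagnostics")

    scores = X @ beta
    order, t_sorted, starts, _ = _risk_structure(time, event)
    X_s = X[order]
    d_s = event[order].astype(int)
    w = np.exp(scores[order] - scores.max())
    revcum_w = np.cumsum(w[::-1])[::-1]
    revcum_wx = np.cumsum((w[:, None] * X_s)[::-1], axis=0)[::-1]

    resid, ev_times = [], []
    for i in np.flatnonzero(d_s):
        g = starts[i]
        xbar = revcum_wx[g] / revcum_w[g]
        resid.append(X_s[i] - xbar)
        ev_times.append(t_sorted[i])
    resid = np.asarray(resid)

    _, _, info = _neg_loglik_grad_hess(beta, X, time, event, hess=True)
    try:
        scaled = resid @ np.linalg.inv(info).T * len(resid) + beta
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular information matrix: {exc}") from exc
    out = pd.DataFrame(scaled, columns=names)
    out.insert(0, "event_time", ev_times)
    return out.sort_values("event_time").reset_index(drop=True)
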