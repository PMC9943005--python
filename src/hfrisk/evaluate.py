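"""Validation suite for right-censored risk models.

Discrimination: Harrell's concordance index (with a 10-fold cross-validated
standard error) and time-dependent cumulative/dynamic ROC AUC at fixed
horizons, censoring handled by inverse-probability-of-censoring weights from
a Kaplan-Meier estimate of the censoring distribution, with bootstrap
confidence intervals and a paired-bootstrap AUC comparison between models.

Calibration: decile plots of predicted versus Kaplan-Meier observed risk and
the integrated calibration index (ICI) — the mean absolute difference
between predicted risk and a smooth estimate of observed risk, the mean over
subjects realizing the weighting by the empirical density of the predicted
risks.

Also: Kaplan-Meier and Aalen-Johansen cumulative-incidence estimators and
Youden-index threshold metrics at a horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .linear_cox import breslow_baseline, fit_cox

logger = logging.getLogger(__name__)

__all__ = [
    "harrell_cindex", "cv_cindex", "time_dependent_auc", "compare_auc",
    "calibration_deciles", "ici", "kaplan_meier", "cumulative_incidence",
    "threshold_metrics", "ValidationReport", "validate_model", "StepFunction",
]


# ---------------------------------------------------------------------------
# Nonparametric survival estimators
# ---------------------------------------------------------------------------

@dataclass
class StepFunction:
    """Right-continuous step function with value 1 before the first jump."""
    times: np.ndarray
    values: np.ndarray
    start_value: float = 1.0

    def __call__(self, t, side: str = "right") -> np.ndarray:
        """side="right": value at t (right-continuous). side="left": value
        just before t (left limit)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right" if side == "right" else "left")
        vals = np.concatenate([[self.start_value], self.values])
        return vals[idx]


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> StepFunction:
    """Product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty sample")
    if np.any(times < 0):
        raise ValueError("negative times")
    order = np.argsort(times, kind="stable")
    t_s, e_s = times[order], events[order]
    uniq = np.unique(t_s[e_s == 1])
    n = len(t_s)
    surv, s = [], 1.0
    for tau in uniq:
        at_risk = n - np.searchsorted(t_s, tau, side="left")
        d = int(((t_s == tau) & (e_s == 1)).sum())
        s *= 1.0 - d / at_risk
        surv.append(s)
    return StepFunction(times=uniq, values=np.asarray(surv))


def cumulative_incidence(times: np.ndarray, events: np.ndarray,
                         competing_events: np.ndarray | None = None) -> StepFunction:
    """Aalen-Johansen cumulative incidence of the primary event.

    ``competing_events`` marks subjects whose follow-up ended with the
    competing event; with none, the estimate equals 1 - Kaplan-Meier
    exactly.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("negative times")
    comp = np.zeros_like(events) if competing_events is None \
        else np.asarray(competing_events, dtype=int)
    if np.any((events == 1) & (comp == 1)):
        raise ValueError("a subject cannot have both the primary and competing event")

    any_event = ((events == 1) | (comp == 1)).astype(int)
    order = np.argsort(times, kind="stable")
    t_s = times[order]
    e_s = events[order]
    a_s = any_event[order]
    n = len(t_s)
    uniq = np.unique(t_s[a_s == 1])
    cif, f, s_minus = [], 0.0, 1.0
    for tau in uniq:
        at_risk = n - np.searchsorted(t_s, tau, side="left")
        tie = t_s == tau
        d_any = int(a_s[tie].sum())
        d_1 = int(e_s[tie].sum())
        f += s_minus * d_1 / at_risk
        s_minus *= 1.0 - d_any / at_risk
        cif.append(f)
    return StepFunction(times=uniq, values=np.asarray(cif), start_value=0.0)


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

def harrell_cindex(times, events, risk_scores) -> float:
    """Harrell's concordance: over pairs (i, j) with t_i < t_j and subject i
    an event, the fraction where i has the higher risk score, counting tied
    scores as one half."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risk = np.asarray(risk_scores, dtype=float)
    conc = 0.0
    npairs = 0
    for i in np.flatnonzero(events == 1):
        later = times > times[i]
        npairs += int(later.sum())
        conc += float((risk[i] > risk[later]).sum())
        conc += 0.5 * float((risk[i] == risk[later]).sum())
    if npairs == 0:
        raise ValueError("no comparable pairs")
    return conc / npairs


def _stratified_folds(event: np.ndarray, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    fold = np.empty(len(event), dtype=int)
    for stratum in (0, 1):
        pos = rng.permutation(np.flatnonzero(event == stratum))
        fold[pos] = np.arange(len(pos)) % k
    return fold


def cv_cindex(model_factory, cohort: CohortTable, k: int = 10,
              seed: int = 0) -> tuple[float, float, np.ndarray]:
    """Out-of-fold c-index over event-stratified folds.

    ``model_factory(train_cohort, seed)`` must return an object with
    ``predict_log_hazard``. Returns (mean, SE = sd/sqrt(k), per-fold
    values). A fold without comparable pairs triggers a refold (logged).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if cohort.n_events < k:
        raise ValueError("need at least k events")
    fold = _stratified_folds(cohort.event, k, seed)
    for attempt in range(10):
        ok = all(cohort.event[fold == f].sum() > 0 and
                 (cohort.event[fold == f] == 0).sum() > 0 for f in range(k))
        if ok:
            break
        logger.warning("degenerate fold; refolding")
        fold = _stratified_folds(cohort.event, k, seed + attempt + 1)

    vals = []
    for f in range(k):
        tr = cohort.subset(fold != f)
        te = cohort.subset(fold == f)
        model = model_factory(tr, seed)
        scores = model.predict_log_hazard(te.covariates)
        vals.append(harrell_cindex(te.time, te.event, scores))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(k)), vals


def _censoring_km(times, events) -> StepFunction:
    """KM of the censoring distribution (censoring treated as the event)."""
    return kaplan_meier(times, 1 - np.asarray(events, dtype=int))


def _ipcw_auc_point(times, events, risk, horizon) -> float:
    cases = (times <= horizon) & (events == 1)
    controls = times > horizon
    if not cases.any():
        raise ValueError("no cases by the horizon")
    if not controls.any():
        raise ValueError("no controls at the horizon")
    G = _censoring_km(times, events)
    w = 1.0 / np.maximum(G(times[cases], side="left"), 1e-12)
    rc = risk[cases]
    rk = risk[controls]
    # weighted probability a case outranks a control (ties count 1/2)
    gt = (rc[:, None] > rk[None, :]).sum(axis=1)
    eq = (rc[:, None] == rk[None, :]).sum(axis=1)
    num = float(np.sum(w * (gt + 0.5 * eq)))
    return num / (float(w.sum()) * len(rk))


def time_dependent_auc(times, events, risk_scores, horizon: float,
                       n_boot: int = 500, seed: int = 0,
                       ci_level: float = 0.95):
    """Cumulative-cases / dynamic-controls AUC at a horizon with IPCW.

    Cases are subjects with an event by the horizon, controls those still
    at risk beyond it; case pairs are weighted by the inverse KM estimate of
    the censoring survival at the case's event time (left limit). The
    confidence interval is a seeded percentile bootstrap.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risk = np.asarray(risk_scores, dtype=float)
    if horizon > times.max():
        raise ValueError("horizon lies beyond the observed follow-up")
    auc = _ipcw_auc_point(times, events, risk, horizon)
    if n_boot <= 0:
        return auc, (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(times), len(times))
        try:
            boots.append(_ipcw_auc_point(times[idx], events[idx], risk[idx], horizon))
        except ValueError:
            continue
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return auc, (float(lo), float(hi))


def compare_auc(model_a_scores, model_b_scores, times, events,
                horizon: float, n_boot: int = 500, seed: int = 0) -> float:
    """Two-sided paired-bootstrap p-value for equal time-dependent AUC.

    Both score vectors are evaluated on the same rows; each bootstrap
    resample is shared, so the difference distribution respects the pairing.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable p-value")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    a = np.asarray(model_a_scores, dtype=float)
    b = np.asarray(model_b_scores, dtype=float)
    if not (len(a) == len(b) == len(times)):
        raise ValueError("score vectors must cover the same evaluation rows")

    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(times), len(times))
        try:
            da = _ipcw_auc_point(times[idx], events[idx], a[idx], horizon)
            db = _ipcw_auc_point(times[idx], events[idx], b[idx], horizon)
        except ValueError:
            continue
        deltas.append(da - db)
    deltas = np.asarray(deltas)
    if len(deltas) == 0:
        raise ValueError("no valid bootstrap resamples")
    p_low = (deltas <= 0).mean()
    p_high = (deltas >= 0).mean()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibration_deciles(predicted_risk_at_t, times, events,
                        horizon: float) -> pd.DataFrame:
    """Predicted vs Kaplan-Meier observed risk across deciles of the
    predicted probabilities (groups of near-equal size)."""
    p = np.asarray(predicted_risk_at_t, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted risks must lie in [0, 1]")
    if np.ptp(p) < 1e-12:
        logger.warning("all predictions identical; single calibration group")
        groups = [np.arange(len(p))]
    else:
        order = np.argsort(p, kind="stable")
        groups = np.array_split(order, 10)
    rows = []
    for g, idx in enumerate(groups, start=1):
        km = kaplan_meier(times[idx], events[idx])
        rows.append({
            "decile": g,
            "n": len(idx),
            "mean_predicted": float(p[idx].mean()),
            "observed": float(1.0 - km(horizon)),
        })
    return pd.DataFrame(rows)


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear tails), columns: x + one term
    per interior knot."""
    k = knots
    kd = (k[-1] - k[0]) ** (2 / 3)
    xx = (x[:, None] - k[None, :-2]) / kd
    t1 = np.maximum(xx, 0.0) ** 3
    t2 = np.maximum((x[:, None] - k[-2]) / kd, 0.0) ** 3 \
        * ((k[-1] - k[:-2]) / (k[-1] - k[-2]))[None, :]
    t3 = np.maximum((x[:, None] - k[-1]) / kd, 0.0) ** 3 \
        * ((k[-2] - k[:-2]) / (k[-1] - k[-2]))[None, :]
    return np.column_stack([x, t1 - t2 + t3])


def ici(predicted_risk_at_t, times, events, horizon: float) -> float:
    """Integrated calibration index at a horizon.

    A flexible calibration model — a proportional-hazards fit of the
    outcome on a restricted cubic spline of the complementary log-log of
    the predicted risk — yields a smoothed observed risk per subject; the
    ICI is the subject-wise mean of |smoothed - predicted|, which realizes
    the weighting by the empirical density of the predictions.
    """
    p = np.asarray(predicted_risk_at_t, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted risks must lie in [0, 1]")
    pc = np.clip(p, 1e-10, 1 - 1e-10)
    x = np.log(-np.log(1.0 - pc))  # cloglog of predicted risk

    if np.std(x) < 1e-8:
        # constant predictions: only calibration-in-the-large is estimable
        observed = 1.0 - kaplan_meier(times, events)(horizon)
        return float(np.mean(np.abs(observed - p)))

    knots = np.unique(np.quantile(x, [0.05, 0.35, 0.65, 0.95]))
    try:
        if len(knots) < 3:
            raise np.linalg.LinAlgError("too few distinct knots")
        B = _rcs_basis(x, knots)
        cal_cohort = CohortTable(
            subject_id=np.array([str(i) for i in range(len(x))], dtype=object),
            time=times, event=events,
            covariates=pd.DataFrame(B, columns=[f"b{j}" for j in range(B.shape[1])]),
        )
        fit = fit_cox(cal_cohort, ridge=1e-6)
        scores = B @ fit.beta.to_numpy()
        base = breslow_baseline(scores, times, events)
        smoothed = 1.0 - np.exp(-base(horizon) * np.exp(scores))
    except Exception as exc:
        # local-regression fallback on the cloglog scale
        logger.warning("ICI spline calibration failed (%s); lowess fallback", exc)
        from statsmodels.nonparametric.smoothers_lowess import lowess
        y = ((times <= horizon) & (events == 1)).astype(float)
        sm = lowess(y, x, frac=0.6, return_sorted=False)
        smoothed = np.clip(sm, 0.0, 1.0)
    return float(np.mean(np.abs(smoothed - p)))


# ---------------------------------------------------------------------------
# Threshold (Youden) metrics
# ---------------------------------------------------------------------------

@dataclass
class ThresholdMetrics:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden: float
    n_excluded: int


def threshold_metrics(predicted_risk_at_t, times, events,
                      horizon: float) -> ThresholdMetrics:
    """Classification metrics at the cutoff maximizing Youden's index
    (sensitivity + specificity - 1) for the binary status "event by the
    horizon". Subjects censored before the horizon have undefined status and
    are excluded (count reported)."""
    p = np.asarray(predicted_risk_at_t, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    excluded = (times < horizon) & (events == 0)
    if excluded.any():
        logger.info("threshold_metrics: excluding %d subjects censored "
                    "before the horizon", int(excluded.sum()))
    keep = ~excluded
    y = ((times <= horizon) & (events == 1))[keep]
    pk = p[keep]
    if y.sum() == 0:
        raise ValueError("no cases at the horizon")
    if (~y).sum() == 0:
        raise ValueError("no controls at the horizon")

    best = None
    for cut in np.unique(pk):
        pred = pk >= cut
        tp = int((pred & y).sum())
        fn = int((~pred & y).sum())
        tn = int((~pred & ~y).sum())
        fp = int((pred & ~y).sum())
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            ppv = tp / (tp + fp) if tp + fp else np.nan
            npv = tn / (tn + fn) if tn + fn else np.nan
            best = (j, cut, sens, spec, ppv, npv)
    j, cut, sens, spec, ppv, npv = best
    return ThresholdMetrics(cutoff=float(cut), sensitivity=sens,
                            specificity=spec, ppv=ppv, npv=npv, youden=j,
                            n_excluded=int(excluded.sum()))


# ---------------------------------------------------------------------------
# Assembled report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Discrimination and calibration summary for one fitted model."""
    cindex: float
    cindex_se: float | None
    horizons: dict[float, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"cindex": self.cindex, "cindex_se": self.cindex_se, "horizons": {}}
        for h, d in self.horizons.items():
            out["horizons"][str(h)] = {
                "auc": d["auc"], "auc_ci": list(d["auc_ci"]), "ici": d["ici"],
                "deciles": d["deciles"].to_dict(orient="records"),
            }
        return out


def validate_model(model, test: CohortTable, horizons=(24.0, 60.0),
                   n_boot: int = 500, seed: int = 0,
                   cindex_se: float | None = None) -> ValidationReport:
    """Score a fitted hazard model (anything with predict_log_hazard and
    predict_risk) on held-out rows."""
    scores = model.predict_log_hazard(test.covariates)
    report = ValidationReport(
        cindex=harrell_cindex(test.time, test.event, scores),
        cindex_se=cindex_se,
    )
    for h in horizons:
        risk = np.atleast_1d(model.predict_risk(test.covariates, h))
        auc, ci = time_dependent_auc(test.time, test.event, scores, h,
                                     n_boot=n_boot, seed=seed)
        report.horizons[float(h)] = {
            "auc": auc,
            "auc_ci": ci,
            "ici": ici(risk, test.time, test.event, h),
            "deciles": calibration_deciles(risk, test.time, test.event, h),
        }
    return report
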