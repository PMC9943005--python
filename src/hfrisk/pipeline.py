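"""End-to-end orchestration: simulate (or load) a cohort, split, preprocess
per model family, optionally forward-select features for the neural model,
fit both model families, explain the neural model with partial-dependence
curves, and validate both on the held-out test set.

The test split is read exactly once, by the evaluation stage; a stage-access
audit trail is kept in the run log. One global seed fans out to per-stage
seeds (stage name hashed), so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortTable
from .evaluate import compare_auc, cv_cindex, validate_model
from .explain import partial_dependence_all
from .feature_select import StopRule, forward_select, phnn_model_factory
from .linear_cox import (LinearCoxModel, breslow_baseline, design_matrix,
                         fit_elastic_net_cox, fit_penalized_cox,
                         hazard_ratio_table)
from .neural_hazard import NetworkArch, TrainingConfig, train_phnn
from .preprocess import (FLAG_SUFFIX, fit_chained_imputer,
                         fit_neural_preprocessor, split_cohort)
from .synthetic_cohort import SimConfig, generate_cohort, paper_like_config

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    out_dir: str = "hfrisk_run"
    seed: int = 0
    # cohort source: synthetic by default, or a CSV path in real-cohort mode
    sim: SimConfig | None = None
    n_subjects: int = 10614
    cohort_path: str | None = None
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    horizons: tuple[float, ...] = (24.0, 60.0)
    # linear model
    l1_ratio: float = 0.5
    cv_folds: int = 10
    mice_iterations: int = 10
    # neural model
    arch_hidden: tuple[int, ...] = (128, 64, 32, 15)
    dropout: float = 0.5
    learning_rate: float = 1e-2
    max_epochs: int = 5000
    patience: int = 300
    # forward selection (neural family)
    selection: bool = True
    selection_candidates: list[str] | None = None
    selection_epochs: int = 150
    min_gain: float = 0.002
    patience_steps: int = 2
    max_features: int = 25
    # evaluation
    n_boot: int = 500
    cv_cindex_folds: int = 10
    write_cohort: bool = False

    def validate(self, cohort: CohortTable) -> None:
        if any(h <= 0 for h in self.horizons):
            raise ValueError("horizons must be positive")
        if self.selection_candidates:
            unknown = [c for c in self.selection_candidates
                       if c not in cohort.covariate_names]
            if unknown:
                raise ValueError(f"selection candidates not in cohort: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig.from_dict(raw["sim"])
        for key in ("fractions", "horizons", "arch_hidden"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _with_flags(names: list[str], available: list[str]) -> list[str]:
    out = list(names)
    for n in names:
        f = n + FLAG_SUFFIX
        if f in available and f not in out:
            out.append(f)
    return out


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report bundle and writes every
    artifact (selection trace, hazard-ratio table, PDP curves, validation
    reports, calibration tables, run log) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit: list[str] = []

    def log(msg: str) -> None:
        audit.append(msg)
        logger.info(msg)

    try:
        # ------------------------------------------------------ cohort
        if config.cohort_path is not None:
            path = Path(config.cohort_path)
            if not path.exists():
                raise ValueError(f"cohort file not found: {path}")
            cohort = CohortTable.read_csv(path)
            truth = None
            log(f"stage cohort: loaded {cohort.n} subjects from {path}")
        else:
            sim = config.sim or paper_like_config(
                config.n_subjects, seed=stage_seed(config.seed, "simulate"))
            cohort, truth = generate_cohort(sim)
            log(f"stage cohort: simulated {cohort.n} subjects, "
                f"{cohort.n_events} events")
        config.validate(cohort)
        if config.write_cohort:
            cohort.to_csv(out / "cohort.csv")

        # ------------------------------------------------------ split
        split = split_cohort(cohort, config.fractions,
                             seed=stage_seed(config.seed, "split"))
        train, val, test = split.apply(cohort)
        log(f"stage split: train={train.n} validation={val.n} test={test.n}; "
            "test rows sealed until evaluation")

        # ------------------------------------------------------ linear model
        stage = "linear_cox"
        imputer = fit_chained_imputer(train, n_iterations=config.mice_iterations,
                                      seed=stage_seed(config.seed, "mice"))
        train_cox = imputer.transform(train)
        cox = fit_elastic_net_cox(train_cox, l1_ratio=config.l1_ratio,
                                  k=config.cv_folds,
                                  seed=stage_seed(config.seed, stage))
        hazard_ratio_table(cox).to_csv(out / "cox_hazard_ratios.csv", index=False)
        cox.cv_curve.to_csv(out / "cox_cv_curve.csv", index=False)
        log(f"stage linear_cox: lambda={cox.lambda_:.5g}, "
            f"{len(cox.selected)} nonzero coefficients")

        # ------------------------------------------------------ neural model
        prep = fit_neural_preprocessor(train)
        train_nn = prep.transform(train)
        val_nn = prep.transform(val)

        trace = None
        if config.selection:
            candidates = config.selection_candidates or cohort.covariate_names
            factory = phnn_model_factory(
                NetworkArch(hidden=config.arch_hidden, dropout=config.dropout),
                selection_epochs=config.selection_epochs,
                learning_rate=config.learning_rate)
            trace = forward_select(
                candidates, train_nn, val_nn, factory,
                StopRule(config.min_gain, config.patience_steps,
                         config.max_features),
                seed=stage_seed(config.seed, "select"))
            trace.to_csv(out / "selection_trace.csv")
            features = trace.selected or candidates
            log(f"stage select: {len(trace.selected)} features "
                f"({trace.stopping_reason})")
        else:
            features = [c for c in train_nn.covariate_names
                        if not c.endswith(FLAG_SUFFIX)]
        features = _with_flags(features, train_nn.covariate_names)

        arch = NetworkArch(hidden=config.arch_hidden, dropout=config.dropout)
        hyper = TrainingConfig(learning_rate=config.learning_rate,
                               max_epochs=config.max_epochs,
                               patience=config.patience)
        tr_sel = train_nn.with_covariates(train_nn.covariates[features])
        va_sel = val_nn.with_covariates(val_nn.covariates[features])
        phnn = train_phnn(tr_sel, va_sel, arch=arch, hyper=hyper,
                          seed=stage_seed(config.seed, "phnn"))
        phnn.training_log.to_csv(out / "phnn_training_log.csv", index=False)
        log(f"stage phnn: trained on {len(features)} inputs, "
            f"{len(phnn.training_log)} epochs")

        # ------------------------------------------------------ explain
        pdp_feats = [f for f in features if not f.endswith(FLAG_SUFFIX)]
        pdp = partial_dependence_all(phnn, tr_sel, covariates=pdp_feats)
        pdp.to_csv(out / "phnn_pdp.csv", index=False)
        log(f"stage explain: PDP curves for {len(pdp_feats)} covariates")

        # ------------------------------------------------------ CV c-index SE
        stage = "cv_cindex"
        lam = cox.lambda_

        def cox_factory(tr, seed):
            tr_i = imputer.transform(tr)
            path = fit_penalized_cox(tr_i, l1_ratio=config.l1_ratio,
                                     alphas=np.asarray([lam]))
            X, _ = design_matrix(tr_i)
            import pandas as pd
            beta = pd.Series(path.beta_at(lam), index=path.feature_names)
            base = breslow_baseline(X @ beta.to_numpy(), tr_i.time, tr_i.event)
            return _ImputingModel(LinearCoxModel(beta, lam, config.l1_ratio, base),
                                  imputer)

        def phnn_factory(tr, seed):
            tr_p = prep.transform(tr)
            tr_p = tr_p.with_covariates(tr_p.covariates[features])
            hy = TrainingConfig(learning_rate=config.learning_rate,
                                max_epochs=config.max_epochs,
                                patience=config.patience)
            m = train_phnn(tr_p, va_sel, arch=arch, hyper=hy, seed=seed)
            return _PreprocessingModel(m, prep, features)

        dev = train  # development rows only; test stays sealed
        cox_cv_mean, cox_cv_se, _ = cv_cindex(
            cox_factory, dev, k=config.cv_cindex_folds,
            seed=stage_seed(config.seed, stage))
        phnn_cv_mean, phnn_cv_se, _ = cv_cindex(
            phnn_factory, dev, k=config.cv_cindex_folds,
            seed=stage_seed(config.seed, stage))
        log(f"stage cv_cindex: cox {cox_cv_mean:.3f}+-{cox_cv_se:.3f}, "
            f"phnn {phnn_cv_mean:.3f}+-{phnn_cv_se:.3f}")

        # ------------------------------------------------------ evaluate
        log("stage evaluate: first and only access to test rows")
        test_cox = imputer.transform(test)
        test_nn = prep.transform(test)
        test_nn_sel = test_nn.with_covariates(test_nn.covariates[features])

        eval_seed = stage_seed(config.seed, "evaluate")
        report_cox = validate_model(cox, test_cox, config.horizons,
                                    n_boot=config.n_boot, seed=eval_seed,
                                    cindex_se=cox_cv_se)
        report_phnn = validate_model(phnn, test_nn_sel, config.horizons,
                                     n_boot=config.n_boot, seed=eval_seed,
                                     cindex_se=phnn_cv_se)
        comparison = {}
        s_cox = cox.predict_log_hazard(test_cox.covariates)
        s_phnn = phnn.predict_log_hazard(test_nn_sel.covariates)
        for h in config.horizons:
            comparison[str(h)] = compare_auc(
                s_phnn, s_cox, test.time, test.event, h,
                n_boot=max(config.n_boot, 100), seed=eval_seed)

        (out / "validation_cox.json").write_text(
            json.dumps(report_cox.to_dict(), indent=2))
        (out / "validation_phnn.json").write_text(
            json.dumps(report_phnn.to_dict(), indent=2))
        (out / "auc_comparison.json").write_text(json.dumps(comparison, indent=2))
        for h in config.horizons:
            report_cox.horizons[h]["deciles"].to_csv(
                out / f"calibration_cox_{int(h)}m.csv", index=False)
            report_phnn.horizons[h]["deciles"].to_csv(
                out / f"calibration_phnn_{int(h)}m.csv", index=False)
        log(f"stage evaluate: cox c={report_cox.cindex:.3f}, "
            f"phnn c={report_phnn.cindex:.3f}")
    except Exception as exc:
        stage_name = audit[-1].split(":")[0] if audit else "startup"
        audit.append(f"ABORTED after {stage_name}: {exc}")
        (out / "run_log.txt").write_text("\n".join(audit) + "\n")
        raise

    (out / "run_log.txt").write_text("\n".join(audit) + "\n")
    return {
        "cohort": cohort,
        "truth": truth,
        "split": split,
        "cox_model": cox,
        "phnn_model": phnn,
        "features": features,
        "selection_trace": trace,
        "pdp": pdp,
        "report_cox": report_cox,
        "report_phnn": report_phnn,
        "auc_comparison": comparison,
        "audit": audit,
    }


class _ImputingModel:
    """Model wrapper applying a fitted imputer before prediction."""

    def __init__(self, model, imputer):
        self.model = model
        self.imputer = imputer

    def predict_log_hazard(self, covariates):
        import pandas as pd
        from .cohort import CohortTable as _CT
        n = len(covariates)
        tmp = _CT(np.array([str(i) for i in range(n)], dtype=object),
                  np.ones(n), np.zeros(n, dtype=int), covariates)
        return self.model.predict_log_hazard(self.imputer.transform(tmp).covariates)


class _PreprocessingModel:
    """Model wrapper applying the neural preprocessing before prediction."""

    def __init__(self, model, prep, features):
        self.model = model
        self.prep = prep
        self.features = features

    def predict_log_hazard(self, covariates):
        from .cohort import CohortTable as _CT
        n = len(covariates)
        tmp = _CT(np.array([str(i) for i in range(n)], dtype=object),
                  np.ones(n), np.zeros(n, dtype=int), covariates)
        t = self.prep.transform(tmp)
        return self.model.predict_log_hazard(t.covariates[self.features])
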