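# hfrisk

Prognostic survival modelling for incident heart failure in right-censored
EHR-style cohorts — for biostatisticians and clinical data scientists who
want to compare a classical penalized survival model with a deep
proportional-hazards model on the same tabular baseline data, with a full
discrimination/calibration validation suite and explainability built in.

Both model families share the proportional-hazards factorization

    h(t | X) = h0(t) · exp(f(X))

and are trained by maximizing the Cox partial likelihood (Breslow ties):

- **Elastic-net Cox** — `f(X) = β·X` with a combined L1+L2 penalty; the
  penalty weight λ is chosen by 10-fold cross-validation under the
  one-standard-error rule (largest λ with CV error within one SE of the
  minimum), yielding a sparse, parsimonious coefficient set.
- **PHNN** — a proportional-hazards neural network: `f(X) = f_θ(X)` is a
  feed-forward network (hidden sizes 128, 64, 32, 15, ReLU, dropout 0.5)
  trained full-batch with Adam on the negative partial likelihood, with
  early stopping on a validation set. Greedy forward selection by
  validation c-index picks its covariates; partial-dependence curves
  `pd_k(x) = (1/n) Σ_i f_θ(x, x_other^(i))` expose each covariate's
  marginal effect on the log-hazard.

Absolute risks at clinical horizons (default 2 and 5 years) come from
Breslow's baseline cumulative-hazard estimator. The validation suite
provides Harrell's c-index with a cross-validated SE, IPCW time-dependent
ROC/AUC with bootstrap confidence intervals and paired-bootstrap model
comparison, decile calibration plots, the integrated calibration index
(ICI), Kaplan–Meier / Aalen–Johansen estimators, scaled Schoenfeld
diagnostics and Youden-index threshold metrics.

Because the cohort that motivated this package (diabetic patients under
cardiological follow-up) is not publicly available, `hfrisk` ships a
synthetic cohort generator with known ground truth: realistic mixed-type
covariate marginals, Gaussian-copula correlation, a Weibull-baseline hazard
with linear, U-shaped and binary effects, administrative censoring (~17%
events over a ~65-month median follow-up at the defaults) and per-covariate
MCAR missingness. Every estimator in the package is tested against this
ground truth or against brute-force oracles. See `docs/methods.md` for the
full model and design documentation.

## Worked example

A cohort whose hazard is dominated by a U-shaped effect — the classic risk
profile of hemoglobin or glycemia — separates the two model families:

```python
import numpy as np
from hfrisk import (SimConfig, generate_cohort, split_cohort, fit_cox,
                    train_phnn, harrell_cindex, partial_dependence)
from hfrisk.synthetic_cohort import (BaselineHazard, Censoring,
                                     CovariateSpec, EffectSpec)

covariates = [CovariateSpec(f"x{i}", "continuous", "normal",
                            {"mean": 0.0, "sd": 1.0}) for i in range(5)]
effects = [EffectSpec("x0", "u_shape", {"c": 0.8, "x0": 0.0}),
           EffectSpec("x1", "linear", {"beta": 0.3})]
config = SimConfig(3000, covariates, effects,
                   BaselineHazard(shape=1.2, scale=200.0),
                   Censoring(max_followup=120.0, entry_window=60.0), seed=11)
cohort, truth = generate_cohort(config)
train, val, test = split_cohort(cohort, seed=1).apply(cohort)

cox = fit_cox(train)
phnn = train_phnn(train, val, seed=2)

c_cox = harrell_cindex(test.time, test.event,
                       test.covariates.to_numpy() @ cox.beta.to_numpy())
c_phnn = harrell_cindex(test.time, test.event,
                        phnn.predict_log_hazard(test.covariates))
print(f"linear Cox test c-index : {c_cox:.3f}")
print(f"PHNN test c-index       : {c_phnn:.3f}")

curve = partial_dependence(phnn, train, "x0")
g = truth.component("x0")(curve.grid)
rho = np.corrcoef(curve.centered(), g - g.mean())[0, 1]
print(f"PDP vs true U-shape corr: {rho:.3f}")
```

Output:

```
linear Cox test c-index : 0.534
PHNN test c-index       : 0.745
PDP vs true U-shape corr: 0.960
```

The linear model cannot represent the quadratic term, so it ranks subjects
barely better than chance; the network recovers both the ranking and — via
the partial-dependence curve — the shape of the true component. On purely
linear cohorts the two models agree to within ~0.01 c-index, which is the
expected behaviour, not a failure.

## Command line

```bash
# synthetic cohort with ground truth
hfrisk simulate --n 10614 --seed 7 --out cohort.csv --truth truth.json

# full pipeline: simulate -> split -> preprocess -> select -> fit both
# models -> explain -> validate; artifacts land in ./report
hfrisk run-all --out-dir report --seed 7 --n 6000
```

`run-all` writes the selection trace, the Cox hazard-ratio table, PHNN
partial-dependence curves, per-model validation reports (c-index ± SE,
2-/5-year AUC with CI, ICI), calibration decile tables and a run log with a
stage-access audit. A YAML `RunConfig` (see `hfrisk.pipeline.RunConfig`)
exposes every knob, including real-cohort mode (`cohort_path`) for your own
CSV with columns `subject_id,time,event,<covariates...>` (times in months,
missing values as empty fields).

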