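# Methods

`hfrisk` implements two prognostic-model families for incident heart
failure in right-censored cohorts, a validation suite, and a synthetic
cohort generator that provides ground truth for every downstream stage.
This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## The proportional-hazards backbone

Both model families assume

    h(t | X) = h0(t) · exp(f(X))

with `h0` an unspecified baseline hazard and `f` the log-relative-hazard.
Training maximizes the Cox partial likelihood, which eliminates `h0`:

    pl(f) = Σ_{i : event} [ f(X_i) − log Σ_{j : t_j ≥ t_i} exp(f(X_j)) ]

Tied event times are handled with Breslow's approximation everywhere (each
tied event contributes the full tie-group risk set); Efron ties, stratified
baselines and time-varying covariates are out of scope. Absolute risk at a
horizon uses Breslow's baseline estimator on the training scores,

    Ĥ0(t) = Σ_{t_i ≤ t} d_i / Σ_{j at risk} exp(f(X_j)),
    S(t | X) = exp(−Ĥ0(t) · exp(f(X))),

with the step function held constant beyond the last observed event time
(logged when queried there).

## Linear family: elastic-net Cox

`f(X) = β·X`, fitted by penalized partial-likelihood maximization over a
decreasing λ grid (100 log-spaced points from the all-zero solution down to
0.001 of it; the coordinate-descent path is scikit-survival's Coxnet). The
working λ comes from 10-fold event-stratified cross-validation under the
one-standard-error rule — the largest λ whose CV error is within one SE of
the minimum — using the Verweij–van Houwelingen held-out deviance
`−2·[pl(full; β_fold) − pl(training folds; β_fold)]`, which stays well
defined when a fold holds few events. The elastic-net mixing ratio defaults
to 0.5 (an L1 path against a fixed L2 component); both the mixing ratio and
λ are exposed because the two standard parametrizations of "the L2 penalty
was fixed" cannot be distinguished without the original code. Unpenalized
and pure-ridge fits use an in-package L-BFGS solver with the analytic
gradient; standard errors come from the inverse observed information at the
optimum.

Proportional-hazards diagnostics use scaled Schoenfeld residuals with the
Grambsch–Therneau scaling `r* = d · I⁻¹ r + β̂`; under proportional hazards
the residual-versus-time trend is flat, and simulations with an effect that
switches on mid-follow-up show the expected positive trend.

## Neural family: proportional-hazards neural network (PHNN)

`f(X) = f_θ(X)` is a fully connected feed-forward network: hidden widths
128, 64, 32, 15, rectifier activations, dropout 0.5 after every hidden
activation (not on the input), one linear output unit. The network,
backpropagation and the Adam optimizer are implemented on numpy; the loss
gradient with respect to the per-subject scores is the closed-form partial-
likelihood gradient, chained through the layers analytically.

Training is full batch: risk sets are global, so evaluating the exact
partial likelihood on all training rows gives one unbiased gradient per
epoch and avoids the bias of minibatched risk sets at these cohort sizes
(n ≤ ~10⁵ is well within one CPU). The consequence, which drives the
optimizer defaults, is that one epoch is a single gradient step: with
dropout 0.5 the loss surface is noisy and convergence takes on the order of
500–1500 epochs. Defaults: learning rate 1e-2, at most 5000 epochs, early
stopping on the validation partial likelihood (evaluated in inference mode)
with patience 300; the returned weights are those of the best validation
epoch. Much smaller patience values stop training while the network is
still near its random initialization. Dropout is inverted (activations
rescaled during training) and disabled at inference, so predictions are
bit-for-bit deterministic; weight initialization and dropout masks come
from a seeded generator, making the final model reproducible. Without
dropout, training is invariant to row order up to float summation; with
dropout, permuting rows reassigns masks to subjects, so exact
row-permutation invariance is only asserted for dropout-free
configurations.

Preprocessing per the two families: the linear model imputes missing
covariates with chained equations (single completed dataset, 10 cycles,
linear models for continuous columns and logistic for binary ones,
mean/mode initialization; no Rubin-rules pooling since a single coefficient
set is reported). The neural model imputes with the training mean, adds a
binary "was missing" flag column per affected covariate, and quantile-
transforms continuous columns to a standard normal shape (up to 1000
empirical quantiles, linear interpolation, out-of-range values clipped to
the extreme training quantiles). Every state is fitted on training rows
only.

## Forward feature selection

Greedy search over candidates by validation c-index: at each step every
remaining candidate is added to the current set, a model is fitted on
training rows, and the best candidate is kept; ties break by name order.
The search stops at `max_features` (25), when candidates run out, or when
the best step gain stays below `min_gain` (0.002) for `patience_steps` (2)
consecutive steps; features added during that trailing low-gain window were
only probes and are trimmed from the final set (the full path stays in the
trace). During selection the per-candidate model may be a reduced-epoch
PHNN, since only the ranking matters; the chosen set is refitted fully.

Two properties of the greedy criterion at desk scale are worth stating
plainly. First, the step-1 "gain" is the maximum validation c-index over
all candidates minus 0.5, so with many pure-noise candidates it exceeds any
small `min_gain`; termination under noise comes from the following steps.
Second, on study-like cohorts at n≈6000 the validation c-index plateaus
after roughly 6–8 covariates: low-prevalence binary risk factors each add
less than the gain threshold individually, so the selected set is
substantially smaller than what the same procedure reportedly finds on
larger cohorts, and truncating the neural model's inputs this way can cost
it a few c-index points relative to the linear model fitted on all columns.

## Partial-dependence explainability

For covariate k, the covariate is clamped to each grid value in every row
(others at observed values) and the predicted log-hazard is averaged:
`pd_k(x) = (1/n) Σ_i f(x, x_other^(i))`. The automatic grid is {0, 1} for
binary covariates and 20 equispaced points between the 1st and 99th
percentiles otherwise. When a covariate carries a missingness flag, the
flag is held at 0 while clamping — the curve describes the counterfactual
in which the value was observed. Curves are computed on the training set by
default and are exact (no sampling), hence row-permutation invariant; for a
linear model they collapse to the coefficient line.

## Validation suite

- **Harrell c-index**: comparable pairs are (i, j) with `t_i < t_j` and
  subject i an event; tied scores count 1/2. Pairs with exactly tied times
  are not comparable, a convention that differs from some implementations
  only in the presence of ties. The cross-validated standard error is
  sd/√k over out-of-fold c-indices from event-stratified folds.
- **Time-dependent AUC** (cumulative cases / dynamic controls) at fixed
  horizons, with inverse-probability-of-censoring weights `1/G(T_i⁻)` from
  a Kaplan–Meier estimate of the censoring distribution; confidence
  intervals by seeded percentile bootstrap (default 500 resamples), and the
  between-model comparison by paired bootstrap (shared resamples, two-sided
  p-value). The bootstrap was chosen over analytic influence-function
  variance because it is assumption-light and directly testable.
- **Calibration**: decile plots compare mean predicted risk with
  within-decile Kaplan–Meier observed risk (consistent under independent
  censoring; subjects censored before the horizon therefore still
  contribute). The integrated calibration index (ICI) fits a flexible
  calibration model — a proportional-hazards fit of the outcome on a
  restricted cubic spline (4 knots at the 5/35/65/95 percentiles) of the
  complementary log-log of predicted risk — converts it to smoothed
  observed risk at the horizon, and averages |smoothed − predicted| over
  subjects, which realizes the weighting by the empirical density of the
  predictions. Near-constant predictions degrade gracefully to
  calibration-in-the-large; a spline failure falls back to a lowess
  smoother with a logged warning.
- **Kaplan–Meier / Aalen–Johansen**: product-limit survival and cumulative
  incidence under competing risks; with zero competing events the CIF
  equals 1 − KM exactly.
- **Youden threshold metrics**: subjects censored before the horizon have
  undefined binary status and are excluded (count reported); the cutoff
  maximizes sensitivity + specificity − 1 over unique predicted values.

## Synthetic cohort generator

The generator emulates a diabetic EHR cohort under cardiological follow-up:
~37 mixed-type covariates whose marginals follow the published baseline
table (age ≈ 72 ± 11, BMI ≈ 28.7, GFR ≈ 76 mL/min, comorbidity and therapy
prevalences), a Gaussian copula giving modest (ρ = 0.2) block correlation
among laboratory and echocardiographic variables, and a hazard mixing
linear clinical gradients (age, GFR, wall-motion index, tissue-doppler E
wave), U-shaped lab effects `c·(x − x0)²` (hemoglobin, glycated
hemoglobin) and binary risk factors. Event times are exact inverse-
transform draws from the Weibull-baseline model; censoring is purely
administrative (study end at 122 months, uniform entry offsets over 95
months); missingness is MCAR per covariate (0.10–0.30 for labs and echo
features, none for age/sex/administrative indicators — the real per-feature
rates are not published, so these are declared defaults). The Weibull
baseline (shape 1.3, scale 725 months) and the enrolment window were
calibrated once against the published outcome profile — ≈17.3% events over
a ≈65-month median follow-up — and then frozen; at n = 10614 the defaults
give 17.4–17.7% events and a 65.7–66.3-month median across seeds.

What the generator does **not** emulate: visit-level longitudinal
structure, informative (dropout-driven) censoring, missingness that depends
on health status (MNAR), coding noise in diagnoses, competing mortality,
and interactions between covariates. Passing tests on these cohorts
demonstrate internal correctness and recovery under the stated model — not
performance on real EHR data.

## Pipeline and reproducibility

`run_all` chains simulate/load → stratified 70/15/15 split → per-family
preprocessing → optional forward selection → both model fits → partial
dependence → validation, writing every artifact (selection trace, hazard-
ratio table, PDP curves, Table-2-style validation reports, calibration
deciles, run log). The test split is read exactly once, by the evaluation
stage, and the run log records a stage-access audit. A single global seed
fans out to per-stage seeds by hashing the stage name, so each stage is
independently reproducible; every stochastic procedure (weight
initialization, dropout, fold assignment, bootstrap) is seeded, and rerunning
a configuration reproduces the numeric outputs byte for byte. The
out-of-fold c-index SE in the pipeline refits each model family per fold on
the development rows with the already-selected hyperparameters (λ, feature
set); preprocessing states fitted on the full training split are reused
across folds, a deliberate simplification that leaves the held-out test
evaluation untouched.

Default problem sizes in the shipped experiments (n = 3000 for recovery
and U-shape studies, n = 6000 for the end-to-end pipeline, n = 10000 for
calibration checks) keep a full run on one CPU in the tens of minutes while
leaving Monte-Carlo error well inside the asserted margins.

## Known limitations

- Breslow ties only; heavy tie structure will bias β slightly versus Efron.
- The ICI depends on the spline calibration model; pathological prediction
  distributions fall back to lowess, which ignores censoring past the
  horizon.
- Greedy forward selection is noisy at small validation sizes and is not
  guaranteed to find the optimal subset; its stopping scale depends on
  cohort size (see above).
- The PHNN learning-rate/patience defaults assume full-batch training; they
  are not appropriate for a minibatch variant.
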