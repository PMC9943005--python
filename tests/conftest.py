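"""Shared fixtures: small deterministic cohorts and (expensive) trained
models reused across module and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hfrisk.cohort import CohortTable
from hfrisk.linear_cox import fit_cox
from hfrisk.neural_hazard import train_phnn
from hfrisk.preprocess import split_cohort
from hfrisk.synthetic_cohort import (BaselineHazard, Censoring, CovariateSpec,
                                     EffectSpec, SimConfig, generate_cohort,
                                     paper_like_config)


def make_cohort(time, event, covariates: dict) -> CohortTable:
    """Tiny hand-specified cohort for oracle tests."""
    n = len(time)
    return CohortTable(
        subject_id=np.array([f"s{i}" for i in range(n)], dtype=object),
        time=np.asarray(time, dtype=float),
        event=np.asarray(event, dtype=int),
        covariates=pd.DataFrame({k: np.asarray(v, dtype=float)
                                 for k, v in covariates.items()}),
    )


def gaussian_config(n: int, seed: int, effects: list[EffectSpec],
                    n_covariates: int = 5,
                    baseline=(1.2, 200.0), censoring=(120.0, 60.0),
                    missing_rate: float = 0.0) -> SimConfig:
    """Cohort of independent standard-normal covariates with the given
    ground-truth effects."""
    covs = [CovariateSpec(f"x{i}", "continuous", "normal",
                          {"mean": 0.0, "sd": 1.0}, missing_rate)
            for i in range(n_covariates)]
    return SimConfig(
        n_subjects=n, covariate_specs=covs, effect_specs=effects,
        baseline_hazard=BaselineHazard(*baseline),
        censoring=Censoring(*censoring), seed=seed,
    )


LINEAR_BETAS = {"x0": 0.8, "x1": -0.5, "x2": 0.3, "x3": 0.2}


@pytest.fixture(scope="session")
def linear_cohort():
    """n=3000 cohort with a purely linear proportional-hazards signal."""
    effects = [EffectSpec(k, "linear", {"beta": b})
               for k, b in LINEAR_BETAS.items()]
    cohort, truth = generate_cohort(gaussian_config(3000, 21, effects))
    split = split_cohort(cohort, seed=1)
    train, val, test = split.apply(cohort)
    return {"cohort": cohort, "truth": truth,
            "train": train, "val": val, "test": test}


@pytest.fixture(scope="session")
def linear_models(linear_cohort):
    """Unpenalized linear fit and PHNN trained on the linear cohort."""
    cox = fit_cox(linear_cohort["train"])
    phnn = train_phnn(linear_cohort["train"], linear_cohort["val"], seed=2)
    return {"cox": cox, "phnn": phnn}


@pytest.fixture(scope="session")
def ushape_cohort():
    """n=3000 cohort dominated by a U-shaped (quadratic) effect that a
    linear log-hazard cannot represent."""
    effects = [EffectSpec("x0", "u_shape", {"c": 0.8, "x0": 0.0}),
               EffectSpec("x1", "linear", {"beta": 0.3})]
    cohort, truth = generate_cohort(gaussian_config(3000, 11, effects))
    split = split_cohort(cohort, seed=1)
    train, val, test = split.apply(cohort)
    return {"cohort": cohort, "truth": truth,
            "train": train, "val": val, "test": test}


@pytest.fixture(scope="session")
def ushape_models(ushape_cohort):
    cox = fit_cox(ushape_cohort["train"])
    phnn = train_phnn(ushape_cohort["train"], ushape_cohort["val"], seed=2)
    return {"cox": cox, "phnn": phnn}


@pytest.fixture(scope="session")
def calibration_cohort():
    """n=10000 cohort with linear signal for oracle-calibration checks."""
    effects = [EffectSpec("x0", "linear", {"beta": 0.7}),
               EffectSpec("x1", "linear", {"beta": -0.4})]
    cohort, truth = generate_cohort(
        gaussian_config(10000, 5, effects, n_covariates=3,
                        baseline=(1.2, 300.0)))
    return {"cohort": cohort, "truth": truth}


@pytest.fixture(scope="session")
def paper_cohort():
    """Full-size study-like cohort (defaults of the generator)."""
    cohort, truth = generate_cohort(paper_like_config(10614, seed=3))
    return {"cohort": cohort, "truth": truth}
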