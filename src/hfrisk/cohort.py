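"""Right-censored cohort container used by every stage of the pipeline.

A cohort is one row per subject: an opaque id, follow-up time in months
(from the index visit to event or censoring), a 0/1 event indicator and a
named covariate matrix. Missing covariate values are NaN; the missingness
mask is derived, never stored separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("subject_id", "time", "event")


@dataclass
class CohortTable:
    """Analysis-ready baseline table for a right-censored cohort.

    Parameters
    ----------
    subject_id : array of str
    time : array of float, months, strictly positive
    event : array of int, 1 = event observed, 0 = censored
    covariates : DataFrame, one named column per covariate; NaN = missing
    """

    subject_id: np.ndarray
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.subject_id)
        if not (len(self.time) == len(self.event) == len(self.covariates) == n):
            raise ValueError("subject_id, time, event and covariates must share length")
        if np.any(self.time <= 0):
            raise ValueError("follow-up time must be > 0 for every subject")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        if self.covariates.columns.duplicated().any():
            raise ValueError("covariate names must be unique")
        for col in RESERVED_COLUMNS:
            if col in self.covariates.columns:
                raise ValueError(f"covariate name {col!r} is reserved")
        self.covariates = self.covariates.reset_index(drop=True)

    # -- basic views ------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.covariates.isna()

    def subset(self, index: np.ndarray) -> "CohortTable":
        """Row subset (positional indices or boolean mask), order preserved."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CohortTable(
            subject_id=self.subject_id[index],
            time=self.time[index],
            event=self.event[index],
            covariates=self.covariates.iloc[index].reset_index(drop=True),
        )

    def with_covariates(self, covariates: pd.DataFrame) -> "CohortTable":
        """Same outcomes, new covariate matrix (used by preprocessing)."""
        return CohortTable(self.subject_id.copy(), self.time.copy(),
                           self.event.copy(), covariates.reset_index(drop=True))

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "subject_id": self.subject_id,
            "time": self.time,
            "event": self.event,
        })
        return pd.concat([out, self.covariates.reset_index(drop=True)], axis=1)

    def to_csv(self, path) -> None:
        # missing values serialize to empty fields
        self.to_frame().to_csv(path, index=False, na_rep="")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortTable":
        for col in RESERVED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"cohort table requires a {col!r} column")
        cov = df.drop(columns=list(RESERVED_COLUMNS))
        return cls(
            subject_id=df["subject_id"].astype(str).to_numpy(dtype=object),
            time=df["time"].to_numpy(dtype=float),
            event=df["event"].to_numpy(dtype=int),
            covariates=cov,
        )

    @classmethod
    def read_csv(cls, path) -> "CohortTable":
        return cls.from_frame(pd.read_csv(path))
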