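"""Panel dataset container: per-subject (time, state) sequences plus
baseline covariates, observed only at discrete visit times."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import FIVE_STATE, StateSpace

REQUIRED_COLUMNS = ("subject_id", "time_years", "state")


class PanelDataError(ValueError):
    """The panel violates a structural requirement."""


@dataclass
class PanelDataset:
    """Long-format panel data: one row per subject per observation.

    Parameters
    ----------
    data
        DataFrame with columns ``subject_id``, ``time_years``, ``state``
        plus zero or more baseline covariate columns (constant within
        subject).
    covariates
        Names of the covariate columns; defaults to every column beyond
        the three required ones.
    space
        State space the ``state`` column is checked against.
    """

    data: pd.DataFrame
    covariates: tuple[str, ...] = ()
    space: StateSpace = field(default=FIVE_STATE)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise PanelDataError(f"panel is missing required columns {missing}")
        if not self.covariates:
            self.covariates = tuple(c for c in df.columns if c not in REQUIRED_COLUMNS)
        else:
            absent = [c for c in self.covariates if c not in df.columns]
            if absent:
                raise PanelDataError(f"covariate columns not in panel: {absent}")
        if df[list(REQUIRED_COLUMNS)].isna().any().any():
            raise PanelDataError("missing values in required columns")

        valid = set(self.space.labels)
        bad = set(df["state"].unique()) - valid
        if bad:
            raise PanelDataError(
                f"unknown state labels {sorted(bad)}; allowed labels are "
                f"{dict(sorted(self.space.labels.items()))}"
            )
        df = df.sort_values(["subject_id", "time_years"], kind="stable").reset_index(drop=True)

        g = df.groupby("subject_id", sort=False)
        dt = g["time_years"].diff().dropna()
        if (dt <= 0).any():
            offenders = df.loc[dt.index[dt <= 0], "subject_id"].unique()[:5]
            raise PanelDataError(
                f"observation times must be strictly increasing within subject "
                f"(offending subjects include {list(offenders)})"
            )
        # no observation may follow an absorbing state
        for a in self.space.absorbing:
            after_absorbing = g["state"].shift(1).eq(a)
            if after_absorbing.any():
                raise PanelDataError(
                    f"observations recorded after absorbing state "
                    f"{self.space.name(a)} for subjects "
                    f"{df.loc[after_absorbing, 'subject_id'].unique()[:5].tolist()}"
                )
        self.data = df

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def wave_times(self) -> np.ndarray:
        return np.sort(self.data["time_years"].unique())

    def baseline(self) -> pd.DataFrame:
        """First observation of each subject."""
        return self.data.groupby("subject_id", sort=False).head(1)

    def baseline_state_counts(self) -> pd.Series:
        return self.baseline()["state"].value_counts().sort_index()

    def transition_pairs(self) -> pd.DataFrame:
        """Consecutive observation pairs: columns from_state, to_state,
        dt, subject_id plus the subject's covariates."""
        df = self.data
        g = df.groupby("subject_id", sort=False)
        out = pd.DataFrame(
            {
                "subject_id": df["subject_id"],
                "from_state": g["state"].shift(1),
                "to_state": df["state"],
                "dt": g["time_years"].diff(),
            }
        )
        out = out.dropna(subset=["from_state", "dt"])
        out["from_state"] = out["from_state"].astype(int)
        for c in self.covariates:
            out[c] = df.loc[out.index, c].values
        return out.reset_index(drop=True)

    def subset(self, subject_ids) -> "PanelDataset":
        df = self.data[self.data["subject_id"].isin(subject_ids)].copy()
        return PanelDataset(df, self.covariates, self.space)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PanelDataset):
            return NotImplemented
        return (
            self.covariates == other.covariates
            and self.data.shape == other.data.shape
            and bool(
                np.all(
                    self.data[list(REQUIRED_COLUMNS) + list(self.covariates)].values
                    == other.data[list(REQUIRED_COLUMNS) + list(other.covariates)].values
                )
            )
        )
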