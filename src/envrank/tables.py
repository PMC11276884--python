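"""Dated design-matrix container shared by every pipeline stage.

A :class:`FeatureTable` holds a gap-free daily calendar, a numeric feature
matrix and one or more non-negative integer admission-count targets.  All
stages (decomposition, screening, model fitting, importance estimation)
consume and return this container, so validation lives here and runs once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]


@dataclass
class FeatureTable:
    """Daily environmental features plus admission-count targets.

    Parameters
    ----------
    dates
        Strictly increasing daily calendar, one entry per row.
    features
        ``n x d`` numeric frame; column names identify the features.
    targets
        ``n x t`` frame of non-negative integer daily counts
        (e.g. ``CVD``, ``RD``).
    """

    dates: pd.DatetimeIndex
    features: pd.DataFrame
    targets: pd.DataFrame
    validate_on_init: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.features = self.features.reset_index(drop=True)
        self.targets = self.targets.reset_index(drop=True)
        if self.validate_on_init:
            self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.dates)
        if n == 0:
            raise ValueError("FeatureTable is empty (no rows)")
        if self.features.shape[1] == 0:
            raise ValueError("FeatureTable has no feature columns")
        if len(self.features) != n or len(self.targets) != n:
            raise ValueError(
                f"row mismatch: {n} dates, {len(self.features)} feature rows, "
                f"{len(self.targets)} target rows"
            )
        deltas = np.diff(self.dates.values.astype("datetime64[D]").astype(int))
        if len(deltas) and not np.all(deltas == 1):
            bad = int(np.flatnonzero(deltas != 1)[0])
            raise ValueError(
                f"dates must advance by exactly one day; violation after "
                f"{self.dates[bad].date()}"
            )
        for frame, kind in ((self.features, "feature"), (self.targets, "target")):
            for col in frame.columns:
                vals = frame[col]
                if not pd.api.types.is_numeric_dtype(vals):
                    raise ValueError(f"{kind} column {col!r} is not numeric")
                if vals.isna().any():
                    rows = vals.index[vals.isna()].tolist()[:5]
                    raise ValueError(
                        f"{kind} column {col!r} has missing values at rows {rows}"
                    )
        for col in self.targets.columns:
            vals = self.targets[col].to_numpy()
            if np.any(vals < 0):
                raise ValueError(f"target column {col!r} has negative counts")
            if not np.allclose(vals, np.round(vals)):
                raise ValueError(f"target column {col!r} is not integer-valued")

    # -- conveniences -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.dates)

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def target_names(self) -> list[str]:
        return list(self.targets.columns)

    def select_features(self, names: list[str]) -> "FeatureTable":
        """Return a copy restricted to the given feature columns (order kept)."""
        missing = [f for f in names if f not in self.features.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        # rows were validated on construction; skip re-validation so that
        # non-contiguous subsets (e.g. a random train split) stay selectable
        return FeatureTable(
            self.dates,
            self.features[list(names)].copy(),
            self.targets.copy(),
            validate_on_init=False,
        )

    def take(self, idx: np.ndarray) -> "FeatureTable":
        """Row subset by positional index; dates need not stay contiguous."""
        return FeatureTable(
            self.dates[idx],
            self.features.iloc[idx].reset_index(drop=True),
            self.targets.iloc[idx].reset_index(drop=True),
            validate_on_init=False,
        )

    def to_frame(self) -> pd.DataFrame:
        """Single frame: ``date`` column first, then features, then targets."""
        out = pd.DataFrame({"date": self.dates.strftime("%Y-%m-%d")})
        for col in self.features.columns:
            out[col] = self.features[col].to_numpy()
        for col in self.targets.columns:
            out[col] = self.targets[col].to_numpy()
        return out

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.dates.equals(other.dates)
            and self.features.equals(other.features)
            and self.targets.equals(other.targets)
        )
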