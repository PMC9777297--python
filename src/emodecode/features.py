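"""Window x feature matrices with per-column descriptors."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FEATURE_TYPES = ("band_power", "faa", "corr")


@dataclass(frozen=True)
class FeatureDescriptor:
    """What one feature column measures: type, band, channel or channel pair."""

    feature_type: str
    band: str
    channel: str | None = None
    pair: tuple[str, str] | None = None
    zero_variance: bool = False

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")

    @property
    def label(self) -> str:
        where = self.channel if self.channel else "-".join(self.pair or ())
        return f"{self.feature_type}:{where}:{self.band}"


@dataclass(frozen=True)
class FeatureArray:
    """Feature matrix (n_windows x n_features) with labels and trial groups."""

    X: np.ndarray
    descriptors: tuple[FeatureDescriptor, ...]
    labels: np.ndarray
    groups: np.ndarray
    participant_id: int = 0

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count must equal feature column count")
        if self.X.shape[0] != len(self.labels) or len(self.labels) != len(self.groups):
            raise ValueError("labels/groups must match n_windows")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def hstack(self, other: "FeatureArray") -> "FeatureArray":
        if not np.array_equal(self.labels, other.labels) or \
           not np.array_equal(self.groups, other.groups):
            raise ValueError("feature arrays index different windows")
        return FeatureArray(np.hstack([self.X, other.X]),
                            self.descriptors + other.descriptors,
                            self.labels, self.groups, self.participant_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[d.label for d in self.descriptors])
        df.insert(0, "group", self.groups)
        df.insert(0, "label", self.labels)
        return df

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def flag_zero_variance(descriptors: tuple[FeatureDescriptor, ...],
                       X: np.ndarray) -> tuple[FeatureDescriptor, ...]:
    """Return descriptors with ``zero_variance`` set from the data."""
    if X.shape[0] == 0:
        return descriptors
    const = X.std(axis=0) == 0
    from dataclasses import replace
    return tuple(replace(d, zero_variance=bool(c))
                 for d, c in zip(descriptors, const))
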