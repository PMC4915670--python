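"""Labelled in-memory containers for morphometric data.

Two kinds of raw data flow through the pipeline:

* landmark configurations (2-D coordinates per specimen record), used by the
  geometric methods GMB (body) and GMS (scale);
* linear distance measurements plus standard length SL, used by the
  distance-based methods TRU (truss network on image) and TRA (caliper).

Every record carries the full crossed study design as labels:
(species, site, individual, measurer, repeat).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical label columns, in canonical order
LABEL_COLUMNS = ["species", "site", "individual", "measurer", "repeat"]

METHODS = ("TRA", "TRU", "GMB", "GMS")


class SchemaError(ValueError):
    """A table does not match the expected layout."""


def _check_labels(labels: pd.DataFrame, n: int) -> pd.DataFrame:
    missing = [c for c in LABEL_COLUMNS if c not in labels.columns]
    if missing:
        raise SchemaError(f"label table is missing columns: {missing}")
    if len(labels) != n:
        raise SchemaError(f"label table has {len(labels)} rows, expected {n}")
    return labels.reset_index(drop=True)


@dataclass
class LandmarkDataset:
    """Labelled 2-D landmark configurations for one geometric method.

    Parameters
    ----------
    labels
        One row per specimen record with the columns in :data:`LABEL_COLUMNS`.
    coords
        Array of shape ``(n_records, n_landmarks, 2)`` in image units.
    landmark_names
        ``K`` landmark labels, in digitization order.
    method
        ``"GMB"`` or ``"GMS"``.
    """

    labels: pd.DataFrame
    coords: np.ndarray
    landmark_names: list[str] = field(default_factory=list)
    method: str = "GMB"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise SchemaError(
                f"coords must have shape (n, K, 2), got {self.coords.shape}"
            )
        self.labels = _check_labels(self.labels, self.coords.shape[0])
        if not self.landmark_names:
            self.landmark_names = [f"lm{i + 1}" for i in range(self.coords.shape[1])]
        if len(self.landmark_names) != self.coords.shape[1]:
            raise SchemaError("landmark_names length does not match coords")
        if np.isnan(self.coords).any():
            bad = np.unique(
                self.labels["individual"].values[np.isnan(self.coords).any(axis=(1, 2))]
            )
            raise SchemaError(f"missing landmark coordinates for individuals: {list(bad)}")

    @property
    def n_records(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: label columns then x1,y1..xK,yK."""
        cols = {}
        for i in range(self.n_landmarks):
            cols[f"x{i + 1}"] = self.coords[:, i, 0]
            cols[f"y{i + 1}"] = self.coords[:, i, 1]
        return pd.concat([self.labels, pd.DataFrame(cols)], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, method: str = "GMB",
                   landmark_names: list[str] | None = None) -> "LandmarkDataset":
        coord_cols = [c for c in frame.columns if c not in LABEL_COLUMNS]
        k, rem = divmod(len(coord_cols), 2)
        if rem or k < 1:
            raise SchemaError("expected paired x/y coordinate columns")
        xs = [f"x{i + 1}" for i in range(k)]
        ys = [f"y{i + 1}" for i in range(k)]
        if not set(xs + ys) <= set(frame.columns):
            raise SchemaError(f"expected coordinate columns x1..x{k}, y1..y{k}")
        coords = np.stack(
            [frame[xs].to_numpy(float), frame[ys].to_numpy(float)], axis=2
        )
        return cls(frame[LABEL_COLUMNS].copy(), coords,
                   landmark_names or [], method)

    def subset(self, mask) -> "LandmarkDataset":
        mask = np.asarray(mask)
        return LandmarkDataset(
            self.labels.loc[mask].reset_index(drop=True),
            self.coords[mask],
            list(self.landmark_names),
            self.method,
        )


@dataclass
class DistanceDataset:
    """Labelled linear measurements (mm) plus standard length SL for one method."""

    labels: pd.DataFrame
    sl: np.ndarray
    values: pd.DataFrame
    method: str = "TRU"

    def __post_init__(self) -> None:
        self.sl = np.asarray(self.sl, dtype=float)
        self.labels = _check_labels(self.labels, len(self.sl))
        self.values = self.values.reset_index(drop=True)
        if len(self.values) != len(self.sl):
            raise SchemaError("values and SL length mismatch")
        if (self.sl <= 0).any():
            bad = self.labels["individual"].values[self.sl <= 0]
            raise SchemaError(f"non-positive SL for individuals: {list(np.unique(bad))}")
        if (self.values.to_numpy(float) < 0).any():
            raise SchemaError("negative distance measurements")

    @property
    def n_records(self) -> int:
        return len(self.sl)

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.labels, pd.Series(self.sl, name="SL"), self.values], axis=1
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, method: str = "TRU") -> "DistanceDataset":
        if "SL" not in frame.columns:
            raise SchemaError("distance table must have an SL column")
        var_cols = [c for c in frame.columns if c not in LABEL_COLUMNS + ["SL"]]
        if not var_cols:
            raise SchemaError("distance table has no measurement columns")
        return cls(frame[LABEL_COLUMNS].copy(), frame["SL"].to_numpy(float),
                   frame[var_cols].astype(float).copy(), method)

    def subset(self, mask) -> "DistanceDataset":
        mask = np.asarray(mask)
        return DistanceDataset(
            self.labels.loc[mask].reset_index(drop=True),
            self.sl[mask],
            self.values.loc[mask].reset_index(drop=True),
            self.method,
        )
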