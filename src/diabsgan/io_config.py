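"""Dataset container, CSV I/O, run configuration and seeded RNG plumbing.

The central container is :class:`TabularDataset`: a dense real-valued
feature matrix with named columns, optional integer class labels, and a
boolean missingness mask (true = treat the cell as missing).  Missingness is
kept as a mask rather than NaN so that zero-coded missing values (the
convention in the PIMA diabetes data, where e.g. BMI = 0 encodes "not
measured") can be flagged without destroying the raw value.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TabularDataset",
    "RunConfig",
    "read_csv_dataset",
    "write_csv_dataset",
    "spawn_rngs",
    "get_logger",
]

PIMA_FEATURES = [
    "Pregnancies",
    "Glucose",
    "BloodPressure",
    "SkinThickness",
    "Insulin",
    "BMI",
    "DiabetesPedigreeFunction",
    "Age",
]

# Features whose zeros are physiologically impossible and encode missingness.
ZERO_MISSING_DEFAULT = frozenset(
    {"Glucose", "BloodPressure", "SkinThickness", "Insulin", "BMI"}
)


def get_logger(stage: str) -> logging.Logger:
    """Stage-tagged logger writing to standard error."""
    logger = logging.getLogger(f"diabsgan.{stage}")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


@dataclass
class TabularDataset:
    """Feature matrix with names, optional integer labels, and a missing mask."""

    features: np.ndarray
    feature_names: list[str]
    labels: np.ndarray | None = None
    label_names: dict[int, str] = field(default_factory=dict)
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, p = self.features.shape
        if len(self.feature_names) != p:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(set(self.feature_names)) != p:
            raise ValueError("feature_names must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("label vector length must equal row count")
        if self.missing_mask is None:
            self.missing_mask = np.zeros_like(self.features, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.features.shape:
                raise ValueError("missing_mask shape must equal features shape")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.features[:, self.column_index(name)]

    def column_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    def copy(self) -> "TabularDataset":
        return TabularDataset(
            features=self.features.copy(),
            feature_names=list(self.feature_names),
            labels=None if self.labels is None else self.labels.copy(),
            label_names=dict(self.label_names),
            missing_mask=self.missing_mask.copy(),
        )

    def subset(self, indices: np.ndarray) -> "TabularDataset":
        """Row subset preserving names, labels and mask."""
        indices = np.asarray(indices)
        return TabularDataset(
            features=self.features[indices],
            feature_names=list(self.feature_names),
            labels=None if self.labels is None else self.labels[indices],
            label_names=dict(self.label_names),
            missing_mask=self.missing_mask[indices],
        )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; one master seed feeds every stage."""

    zero_missing_features: frozenset[str] = ZERO_MISSING_DEFAULT
    skew_threshold: float = 0.5
    cap_features: frozenset[str] | None = None  # None = all features
    cv_folds: int = 10
    seed: int = 0
    resample: "object | None" = None  # ResampleConfig, set by caller
    gan: "object | None" = None  # DCSGANConfig, set by caller
    resample_before_split: bool = False

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.skew_threshold < 0:
            raise ValueError("skew_threshold must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "zero_missing_features": sorted(self.zero_missing_features),
            "skew_threshold": self.skew_threshold,
            "cap_features": None if self.cap_features is None else sorted(self.cap_features),
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "resample_before_split": self.resample_before_split,
        }
        Path(path).write_text(yaml.safe_dump(payload))


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one master seed into ``n`` independent per-stage generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def read_csv_dataset(path: str | Path, label_column: str | None = "Outcome") -> TabularDataset:
    """Read a header-ful CSV into a TabularDataset.

    All non-label cells must parse as numbers; the missing mask starts all
    false (zero-coded missingness is assigned later by
    :func:`diabsgan.preprocess.detect_missing`).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if label_column is not None and label_column not in frame.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels = None
    label_names: dict[int, str] = {}
    if label_column is not None:
        labels = frame[label_column].to_numpy()
        try:
            labels = labels.astype(int)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"label column {label_column!r} is not integer") from exc
        frame = frame.drop(columns=[label_column])
        label_names = {int(c): str(c) for c in np.unique(labels)}
    feature_names = [str(c) for c in frame.columns]
    try:
        features = frame.to_numpy(dtype=float)
    except (TypeError, ValueError):
        # locate the first offending cell for the error message
        for col in frame.columns:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"unparseable cell at row {row}, column {col!r} in {path}"
                ) from None
        raise
    if np.isnan(features).any():
        r, c = np.argwhere(np.isnan(features))[0]
        raise ValueError(
            f"unparseable/empty cell at row {int(r)}, column {feature_names[int(c)]!r} in {path}"
        )
    return TabularDataset(features=features, feature_names=feature_names, labels=labels,
                          label_names=label_names)


def write_csv_dataset(dataset: TabularDataset, path: str | Path,
                      label_column: str = "Outcome") -> None:
    """Write a TabularDataset to CSV (header row; labels as a trailing column).

    ``read_csv_dataset`` inverts the write up to float formatting; values are
    printed with 17 significant digits so the round trip is value-exact.
    """
    frame = pd.DataFrame(dataset.features, columns=dataset.feature_names)
    if dataset.labels is not None:
        frame[label_column] = dataset.labels
    frame.to_csv(path, index=False, float_format="%.17g")
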