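"""Class rebalancing: SMOTE oversampling, ENN cleaning, and their hybrid.

SMOTE synthesizes minority samples by interpolation: for a minority point
x_i, pick one of its k nearest minority neighbours x_nn and emit
x_new = x_i + u·(x_nn − x_i) with u ~ Uniform[0, 1].  ENN then cleans the
combined set by deleting every sample whose label disagrees with the
majority vote of its k nearest neighbours.  The hybrid (SMOTE first, ENN on
the combined data) both grows the minority class and removes borderline or
noisy points of all classes.

Distances are Euclidean on internally standardized features (zero mean,
unit variance, fit on the input): PIMA-like features span orders of
magnitude, and unscaled distances would be dominated by the widest column.
Synthetics are mapped back to the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["ResampleConfig", "smote_oversample", "enn_filter", "smoteenn"]


@dataclass
class ResampleConfig:
    k_smote: int = 5
    k_enn: int = 3
    target_ratio: float = 1.0  # minority:majority after SMOTE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_smote < 1 or self.k_enn < 1:
            raise ValueError("neighbour counts must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must be in (0, 1]")


def _standardizer(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def smote_oversample(
    features: np.ndarray,
    labels: np.ndarray,
    config: ResampleConfig | None = None,
    n_synthetic: dict[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every non-majority class toward the majority count.

    Originals are preserved verbatim; synthetics are appended.  The number
    of synthetics per class is chosen so each class reaches
    ``target_ratio`` × majority count (or pass ``n_synthetic`` to request
    exact counts per class).
    """
    config = config or ResampleConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 and n_synthetic is None:
        raise ValueError("need at least 2 classes to oversample")
    majority = int(counts.max())
    rng = np.random.default_rng(config.seed)
    mu, sd = _standardizer(features)
    scaled = (features - mu) / sd

    new_rows: list[np.ndarray] = []
    new_labels: list[int] = []
    for cls, count in zip(classes, counts):
        if n_synthetic is not None:
            need = int(n_synthetic.get(int(cls), 0))
        else:
            need = max(0, int(round(config.target_ratio * majority)) - int(count))
        if need == 0:
            continue
        if count <= config.k_smote:
            raise ValueError(
                f"class {cls} has {count} samples <= k_smote={config.k_smote}; "
                "lower k_smote"
            )
        idx = np.flatnonzero(labels == cls)
        pts = scaled[idx]
        # k+1 including self; drop the self column
        nn = NearestNeighbors(n_neighbors=config.k_smote + 1).fit(pts)
        neigh = nn.kneighbors(pts, return_distance=False)[:, 1:]
        base = rng.integers(0, len(idx), size=need)
        pick = rng.integers(0, config.k_smote, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        x_i = pts[base]
        x_nn = pts[neigh[base, pick]]
        synth = x_i + u[:, None] * (x_nn - x_i)
        new_rows.append(synth * sd + mu)
        new_labels.extend([int(cls)] * need)

    if not new_rows:
        return features.copy(), labels.copy()
    aug_features = np.vstack([features] + new_rows)
    aug_labels = np.concatenate([labels, np.asarray(new_labels, dtype=int)])
    return aug_features, aug_labels


def enn_filter(features: np.ndarray, labels: np.ndarray, k_enn: int = 3) -> np.ndarray:
    """Indices retained by edited-nearest-neighbours cleaning.

    A sample is removed iff the majority label among its ``k_enn`` nearest
    neighbours (itself excluded) differs from its own; ties are broken
    toward keeping the sample.  Applied to all classes; returned indices
    keep the original order.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if n <= k_enn + 1:
        raise ValueError(f"need more than k_enn+1={k_enn + 1} samples")
    mu, sd = _standardizer(features)
    scaled = (features - mu) / sd
    nn = NearestNeighbors(n_neighbors=k_enn + 1).fit(scaled)
    neigh = nn.kneighbors(scaled, return_distance=False)[:, 1:]
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        votes = labels[neigh[i]]
        own = int((votes == labels[i]).sum())
        # removed only if some other label strictly outvotes the sample's own
        vals, cnts = np.unique(votes, return_counts=True)
        rival = int(cnts[vals != labels[i]].max()) if (vals != labels[i]).any() else 0
        if rival > own:
            keep[i] = False
    return np.flatnonzero(keep)


def smoteenn(
    features: np.ndarray, labels: np.ndarray, config: ResampleConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE then ENN on the combined data; deterministic given the seed."""
    config = config or ResampleConfig()
    aug_f, aug_l = smote_oversample(features, labels, config)
    kept = enn_filter(aug_f, aug_l, config.k_enn)
    return aug_f[kept], aug_l[kept]


def imbalance_ratio(labels: np.ndarray) -> float:
    """Minority:majority class-count ratio (1.0 = balanced)."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    return float(counts.min() / counts.max())
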