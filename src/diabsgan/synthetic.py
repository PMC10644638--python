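"""Synthetic PIMA-like data generators for end-to-end testing.

``generate_pima_like`` emulates the structure of the PIMA diabetes data:
eight clinical features, a ~500:268 two-class imbalance, heavy right tails
(Insulin is class-conditionally lognormal), injected multiplicative
outliers, and zero-coded missingness in the five features where a zero is
physiologically impossible.  Class-conditional locations are shifted so
glucose, BMI, age and pedigree carry real signal — the generated data is
classifiable but not trivially separable.

``generate_separable_gaussians`` is a known-truth fixture: balanced classes
with unit-variance Gaussian clusters centred ``separation`` apart along
coordinate axes, so the Bayes accuracy is computable from Gaussian tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io_config import TabularDataset

__all__ = ["SyntheticSpec", "generate_pima_like", "generate_separable_gaussians"]


def _default_features() -> dict:
    # distribution: normal | lognormal | mixture (two normals)
    # params are per class {0: (loc, scale), 1: (loc, scale)};
    # lognormal params are on the log scale.
    return {
        "Pregnancies": {"distribution": "normal", "params": {0: (3.0, 2.8), 1: (4.6, 3.4)},
                        "round": True, "floor": 0.0},
        "Glucose": {"distribution": "normal", "params": {0: (110.0, 24.0), 1: (142.0, 30.0)},
                    "floor": 40.0},
        "BloodPressure": {"distribution": "normal", "params": {0: (68.0, 11.0), 1: (72.0, 12.0)},
                          "floor": 20.0},
        "SkinThickness": {"distribution": "normal", "params": {0: (27.0, 9.0), 1: (31.0, 10.0)},
                          "floor": 5.0},
        "Insulin": {"distribution": "lognormal", "params": {0: (4.6, 0.55), 1: (5.0, 0.6)}},
        "BMI": {"distribution": "normal", "params": {0: (30.5, 6.5), 1: (35.0, 6.5)},
                "floor": 15.0},
        "DiabetesPedigreeFunction": {"distribution": "lognormal",
                                     "params": {0: (-0.95, 0.6), 1: (-0.73, 0.6)}},
        "Age": {"distribution": "mixture", "params": {0: (28.0, 6.0), 1: (40.0, 11.0)},
                "mixture_second": (55.0, 8.0), "mixture_weight": 0.2,
                "round": True, "floor": 21.0},
    }


@dataclass
class SyntheticSpec:
    """Generative description of a PIMA-like dataset."""

    n_per_class: dict[int, int] = field(default_factory=lambda: {0: 500, 1: 268})
    features: dict = field(default_factory=_default_features)
    zero_missing_rate: dict[str, float] = field(default_factory=lambda: {
        "Glucose": 0.007, "BloodPressure": 0.045, "SkinThickness": 0.30,
        "Insulin": 0.49, "BMI": 0.014,
    })
    outlier_rate: float = 0.01
    outlier_multiplier: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.n_per_class.values()):
            raise ValueError("class counts must be positive")
        if not all(0 <= r <= 1 for r in self.zero_missing_rate.values()):
            raise ValueError("zero_missing_rate entries must lie in [0, 1]")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must lie in [0, 1]")
        if self.outlier_multiplier <= 1:
            raise ValueError("outlier_multiplier must exceed 1")

    def to_yaml(self, path: str | Path) -> None:
        """Truth sidecar recording every generative parameter."""
        payload = {
            "n_per_class": {int(k): int(v) for k, v in self.n_per_class.items()},
            "zero_missing_rate": dict(self.zero_missing_rate),
            "outlier_rate": self.outlier_rate,
            "outlier_multiplier": self.outlier_multiplier,
            "seed": self.seed,
            "features": {
                name: {
                    "distribution": f["distribution"],
                    "params": {int(c): [float(a), float(b)] for c, (a, b) in f["params"].items()},
                }
                for name, f in self.features.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(payload))


def _draw(rng: np.random.Generator, spec: dict, cls: int, n: int) -> np.ndarray:
    loc, scale = spec["params"][cls]
    kind = spec["distribution"]
    if kind == "normal":
        vals = rng.normal(loc, scale, size=n)
    elif kind == "lognormal":
        vals = rng.lognormal(loc, scale, size=n)
    elif kind == "mixture":
        loc2, scale2 = spec.get("mixture_second", (loc, scale))
        w = spec.get("mixture_weight", 0.5)
        pick = rng.uniform(size=n) < w
        vals = np.where(pick, rng.normal(loc2, scale2, size=n), rng.normal(loc, scale, size=n))
    else:
        raise ValueError(f"unknown distribution {kind!r}")
    if "floor" in spec:
        vals = np.maximum(vals, spec["floor"])
    if spec.get("round"):
        vals = np.round(vals)
    return vals


def generate_pima_like(spec: SyntheticSpec | None = None) -> TabularDataset:
    """Draw a PIMA-like dataset with exact class counts, outliers and zeros.

    Outliers are injected by multiplying a random subset of cells by
    ``outlier_multiplier``; zero-coded missingness is injected afterwards so
    detection sees a realistic mixture.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    names = list(spec.features.keys())
    blocks, labels = [], []
    for cls in sorted(spec.n_per_class):
        n_c = spec.n_per_class[cls]
        cols = [_draw(rng, spec.features[name], cls, n_c) for name in names]
        blocks.append(np.column_stack(cols))
        labels.append(np.full(n_c, cls, dtype=int))
    features = np.vstack(blocks)
    labels = np.concatenate(labels)
    n = features.shape[0]
    order = rng.permutation(n)
    features, labels = features[order], labels[order]

    if spec.outlier_rate > 0:
        hit = rng.uniform(size=features.shape) < spec.outlier_rate
        features = np.where(hit, features * spec.outlier_multiplier, features)

    for name, rate in spec.zero_missing_rate.items():
        j = names.index(name)
        zero = rng.uniform(size=n) < rate
        features[zero, j] = 0.0

    return TabularDataset(
        features=features, feature_names=names, labels=labels,
        label_names={0: "non-diabetic", 1: "diabetic"},
    )


def generate_separable_gaussians(
    n: int, p: int, separation: float, n_classes: int = 2, seed: int = 0
) -> TabularDataset:
    """Balanced unit-variance Gaussian clusters, class c centred at separation·e_c."""
    if n <= 0 or p <= 0 or n_classes < 2 or n_classes > p:
        raise ValueError("need n > 0, p > 0, 2 <= n_classes <= p")
    if n % n_classes:
        raise ValueError("n must be divisible by n_classes")
    rng = np.random.default_rng(seed)
    per = n // n_classes
    features = rng.standard_normal((n, p))
    labels = np.repeat(np.arange(n_classes), per)
    for c in range(n_classes):
        features[labels == c, c] += separation
    order = rng.permutation(n)
    return TabularDataset(
        features=features[order],
        feature_names=[f"f{j}" for j in range(p)],
        labels=labels[order],
        label_names={c: f"class{c}" for c in range(n_classes)},
    )
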