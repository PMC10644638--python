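"""Preprocessing: zero-as-missing imputation, IQR capping, glucose relabeling.

Three stages, in the order the pipeline runs them:

1. **Missing values.** In the PIMA schema a zero in Glucose, BloodPressure,
   SkinThickness, Insulin or BMI is physiologically impossible and encodes a
   missing measurement.  ``detect_missing`` flags those cells;
   ``fit_imputation`` chooses, per feature, between mean and median filling
   by the skewness of the observed values (mean when the observed
   distribution is roughly symmetric, median when it is skewed — the fill
   then nudges the distribution toward normality rather than away from it);
   ``apply_imputation`` substitutes the fill values.  Pregnancies is never
   imputed: zero pregnancies is a legitimate value.

2. **Outliers.** Tukey-fence capping (winsorization): per feature compute
   Q1, Q3, IQR = Q3 − Q1 and clamp values into
   [Q1 − 1.5·IQR, Q3 + 1.5·IQR].  Capping keeps every row (unlike outright
   removal, which is available as ``remove_outliers`` for comparison).

3. **Relabeling.** The binary diabetes outcome can be replaced by a
   three-class label derived from fasting plasma glucose: ≤ 99 mg/dL normal,
   100–125 prediabetes, ≥ 126 diabetes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from scipy import stats as sps

from .io_config import TabularDataset

__all__ = [
    "ImputationPlan",
    "CapBounds",
    "ThreeClassScheme",
    "detect_missing",
    "fit_imputation",
    "apply_imputation",
    "fit_cap_bounds",
    "fit_cap_bounds_dataset",
    "apply_cap",
    "remove_outliers",
    "relabel_glucose",
]


# ---------------------------------------------------------------- missingness

def detect_missing(
    dataset: TabularDataset, zero_missing_features: Iterable[str]
) -> tuple[TabularDataset, dict[str, int]]:
    """Mark zeros in the designated features as missing.

    Returns a copy of the dataset with the mask set true exactly where a
    designated feature equals 0, plus the per-feature zero counts.
    """
    out = dataset.copy()
    requested = list(zero_missing_features)
    for name in requested:
        out.column_index(name)  # raises KeyError for unknown names
    counts: dict[str, int] = {}
    # column order, so reports are stable regardless of the set's iteration
    for name in (n for n in out.feature_names if n in requested):
        j = out.column_index(name)
        zero = out.features[:, j] == 0.0
        out.missing_mask[:, j] |= zero
        counts[name] = int(zero.sum())
    return out, counts


@dataclass
class ImputationPlan:
    """Per-feature fill strategy chosen by observed skewness.

    ``strategy`` is "mean" when |skewness| of the observed (non-missing)
    values is at most ``skew_threshold``, else "median".  ``fill_value`` is
    computed from observed values only.
    """

    entries: dict[str, dict] = field(default_factory=dict)
    skew_threshold: float = 0.5

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "skew_threshold": self.skew_threshold,
            "entries": {
                k: {kk: (float(vv) if isinstance(vv, (int, float, np.floating)) else vv)
                    for kk, vv in e.items()}
                for k, e in self.entries.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(payload))


def fit_imputation(dataset: TabularDataset, skew_threshold: float = 0.5) -> ImputationPlan:
    """Fit a mean/median joint-filling plan on the masked dataset.

    One entry per feature that has at least one masked cell.  Skewness is
    the adjusted Fisher–Pearson sample skewness of the observed values.
    """
    plan = ImputationPlan(skew_threshold=skew_threshold)
    for j, name in enumerate(dataset.feature_names):
        mask = dataset.missing_mask[:, j]
        if not mask.any():
            continue
        observed = dataset.features[~mask, j]
        if observed.size == 0:
            raise ValueError(f"feature {name!r} is entirely missing")
        if observed.size < 2:
            raise ValueError(f"feature {name!r} has < 2 observed values")
        skew = float(sps.skew(observed, bias=False)) if observed.size > 2 else 0.0
        if abs(skew) <= skew_threshold:
            strategy, fill = "mean", float(np.mean(observed))
        else:
            strategy, fill = "median", float(np.median(observed))
        plan.entries[name] = {
            "strategy": strategy,
            "fill_value": fill,
            "observed_skewness": skew,
        }
    return plan


def apply_imputation(dataset: TabularDataset, plan: ImputationPlan) -> TabularDataset:
    """Substitute fill values at masked cells and clear their mask bits."""
    out = dataset.copy()
    for name, entry in plan.entries.items():
        j = out.column_index(name)
        mask = out.missing_mask[:, j]
        out.features[mask, j] = entry["fill_value"]
        out.missing_mask[mask, j] = False
    return out


# ------------------------------------------------------------------- capping

@dataclass
class CapBounds:
    """Per-feature Tukey fences: q1, q2, q3, iqr, upper, lower.

    upper = Q3 + 1.5·IQR and lower = Q1 − 1.5·IQR; q2 (the median) is stored
    for reporting though the clamp does not use it.
    """

    entries: dict[str, dict] = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        payload = {k: {kk: float(vv) for kk, vv in e.items()}
                   for k, e in self.entries.items()}
        Path(path).write_text(yaml.safe_dump(payload))


def fit_cap_bounds(values: np.ndarray) -> dict:
    """Quartiles and fences for one feature vector.

    Quartiles use linear interpolation between order statistics (position
    (n−1)·p).  Requires at least 4 values and no NaNs.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values to fit cap bounds")
    if np.isnan(values).any():
        raise ValueError("values contain missing entries")
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    return {
        "q1": float(q1),
        "q2": float(q2),
        "q3": float(q3),
        "iqr": float(iqr),
        "upper": float(q3 + 1.5 * iqr),
        "lower": float(q1 - 1.5 * iqr),
    }


def fit_cap_bounds_dataset(
    dataset: TabularDataset, cap_features: Iterable[str] | None = None
) -> CapBounds:
    """Fit fences for each named feature (default: all features)."""
    names = list(dataset.feature_names) if cap_features is None else list(cap_features)
    bounds = CapBounds()
    for name in names:
        bounds.entries[name] = fit_cap_bounds(dataset.column(name))
    return bounds


def apply_cap(dataset: TabularDataset, bounds: CapBounds) -> TabularDataset:
    """Clamp each bounded feature into [lower, upper]; no rows are dropped."""
    out = dataset.copy()
    for name, entry in bounds.entries.items():
        j = out.column_index(name)
        out.features[:, j] = np.clip(out.features[:, j], entry["lower"], entry["upper"])
    return out


def remove_outliers(dataset: TabularDataset, bounds: CapBounds) -> TabularDataset:
    """Alternative to capping: drop rows outside any fence (not the default)."""
    keep = np.ones(dataset.n_samples, dtype=bool)
    for name, entry in bounds.entries.items():
        col = dataset.column(name)
        keep &= (col >= entry["lower"]) & (col <= entry["upper"])
    return dataset.subset(np.flatnonzero(keep))


# ---------------------------------------------------------------- relabeling

@dataclass
class ThreeClassScheme:
    """Fasting-plasma-glucose cut points for the three-class task.

    ``normal_threshold`` is the inclusive upper bound of the normal range
    (default 99 mg/dL); ``diabetes_threshold`` is the exclusive lower bound
    of the diabetic range (default 125: glucose > 125, i.e. ≥ 126, is
    diabetes).  Codes: 0 normal, 1 prediabetes, 2 diabetes.
    """

    diabetes_threshold: float = 125.0
    normal_threshold: float = 99.0

    def __post_init__(self) -> None:
        if not self.normal_threshold < self.diabetes_threshold:
            raise ValueError("normal_threshold must be < diabetes_threshold")

    label_names = {0: "normal", 1: "prediabetes", 2: "diabetes"}


def relabel_glucose(
    dataset: TabularDataset, scheme: ThreeClassScheme | None = None
) -> TabularDataset:
    """Replace labels by the glucose-derived three-class codes."""
    scheme = scheme or ThreeClassScheme()
    out = dataset.copy()
    glucose = out.column("Glucose")  # raises KeyError if absent
    labels = np.ones(out.n_samples, dtype=int)  # prediabetes default
    labels[glucose <= scheme.normal_threshold] = 0
    labels[glucose > scheme.diabetes_threshold] = 2
    out.labels = labels
    out.label_names = dict(ThreeClassScheme.label_names)
    return out
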