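"""Stratified k-fold cross-validation harness and the evaluation metric set.

Per fold, the default protocol fits every data-dependent stage on the
training indices only — imputation plan, cap bounds, optional SMOTE+ENN
resampling — then trains the GAN classifier and scores the untouched test
fold.  A ``resample_before_split`` flag instead resamples the whole dataset
once before splitting; this leaks synthetic neighbours of test points into
training and is provided only for protocol comparison.

Metrics: accuracy, precision, recall, F1 (positive class for binary, macro
average for ≥ 3 classes), ROC AUC (binary: rank statistic with ties counted
½; multiclass: one-vs-rest macro), and the confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from . import preprocess
from .dcsgan import DCSGANConfig, predict, train_dcsgan
from .io_config import RunConfig, TabularDataset, get_logger
from .resample import ResampleConfig, smoteenn

__all__ = ["CVResult", "stratified_folds", "compute_metrics", "run_cv"]

logger = get_logger("evaluate")


@dataclass
class CVResult:
    folds: list[dict]
    means: dict[str, float]
    stds: dict[str, float]
    protocol: dict = field(default_factory=dict)


def stratified_folds(labels: np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """k disjoint test-index sets with per-class counts differing by ≤ 1."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
    positive_class: int | None = None,
) -> dict:
    """Accuracy, precision/recall/F1, AUC and confusion matrix.

    For binary labels precision/recall/F1 refer to the positive class
    (default: the largest label code, diabetes in both PIMA tasks); for
    three or more classes they are macro-averaged, and AUC is one-vs-rest
    macro.  ``scores`` must be a probability matrix with rows summing to 1,
    columns ordered by sorted class code.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred) or len(y_true) != scores.shape[0]:
        raise ValueError("length mismatch")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    accuracy = float(np.mean(y_true == y_pred))
    if classes.size <= 2:
        pos = positive_class if positive_class is not None else int(classes.max())
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=[pos], average=None, zero_division=0.0
        )
        prec, rec, f1 = float(prec[0]), float(rec[0]), float(f1[0])
        present = np.unique(y_true)
        if present.size == 2:
            pos_col = int(np.searchsorted(np.unique(y_true), pos))
            auc = float(roc_auc_score(y_true == pos, scores[:, min(pos_col, scores.shape[1] - 1)]))
        else:
            auc = float("nan")
    else:
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0.0
        )
        prec, rec, f1 = float(prec), float(rec), float(f1)
        try:
            auc = float(roc_auc_score(y_true, scores, multi_class="ovr", average="macro"))
        except ValueError:
            auc = float("nan")
    cm = confusion_matrix(y_true, y_pred, labels=sorted(classes))
    return {
        "accuracy": accuracy,
        "precision": prec,
        "recall": rec,
        "f1": f1,
        "auc": auc,
        "confusion_matrix": cm,
    }


def _preprocess_fold(
    train: TabularDataset, test: TabularDataset, config: RunConfig
) -> tuple[TabularDataset, TabularDataset]:
    """Fit imputation and cap bounds on the training fold; apply to both."""
    train, _ = preprocess.detect_missing(train, config.zero_missing_features)
    test, _ = preprocess.detect_missing(test, config.zero_missing_features)
    plan = preprocess.fit_imputation(train, config.skew_threshold)
    train = preprocess.apply_imputation(train, plan)
    test = preprocess.apply_imputation(test, plan)
    cap_names = config.cap_features
    bounds = preprocess.fit_cap_bounds_dataset(
        train, None if cap_names is None else list(cap_names)
    )
    return preprocess.apply_cap(train, bounds), preprocess.apply_cap(test, bounds)


def run_cv(dataset: TabularDataset, config: RunConfig) -> CVResult:
    """Cross-validated evaluation of the full pipeline.

    Every test prediction comes from a model whose training fold excluded
    that row (default protocol); fold assignment, resampling and GAN
    training all derive from the single run seed.
    """
    if dataset.labels is None:
        raise ValueError("cross-validation requires labels")
    gan_cfg: DCSGANConfig = config.gan or DCSGANConfig(
        n_classes=len(np.unique(dataset.labels))
    )
    rs_cfg: ResampleConfig | None = config.resample

    work = dataset
    if config.resample_before_split and rs_cfg is not None:
        feats, labs = smoteenn(work.features, work.labels, rs_cfg)
        work = TabularDataset(
            features=feats, feature_names=list(work.feature_names),
            labels=labs, label_names=dict(work.label_names),
        )

    folds = stratified_folds(work.labels, config.cv_folds, config.seed)
    all_idx = np.arange(work.n_samples)
    records: list[dict] = []
    for fold_i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        assert np.intersect1d(train_idx, test_idx).size == 0
        train, test = work.subset(train_idx), work.subset(test_idx)
        train, test = _preprocess_fold(train, test, config)

        if rs_cfg is not None and not config.resample_before_split:
            fold_rs = ResampleConfig(
                k_smote=rs_cfg.k_smote, k_enn=rs_cfg.k_enn,
                target_ratio=rs_cfg.target_ratio, seed=config.seed + 1000 + fold_i,
            )
            feats, labs = smoteenn(train.features, train.labels, fold_rs)
            train = TabularDataset(
                features=feats, feature_names=list(train.feature_names),
                labels=labs, label_names=dict(train.label_names),
            )

        fold_gan = DCSGANConfig(
            latent_dim=gan_cfg.latent_dim, gen_hidden=gan_cfg.gen_hidden,
            disc_hidden=gan_cfg.disc_hidden, lambda_c=gan_cfg.lambda_c,
            learning_rate=gan_cfg.learning_rate, epochs=gan_cfg.epochs,
            batch_size=min(gan_cfg.batch_size, train.n_samples),
            n_classes=gan_cfg.n_classes, seed=config.seed + 2000 + fold_i,
        )
        model = train_dcsgan(train, fold_gan)
        y_pred, probs = predict(model, test.features)
        rec = compute_metrics(test.labels, y_pred, probs)
        rec["fold"] = fold_i
        records.append(rec)
        logger.info("fold %d: accuracy=%.4f f1=%.4f", fold_i, rec["accuracy"], rec["f1"])

    metric_keys = ["accuracy", "precision", "recall", "f1", "auc"]
    means = {k: float(np.nanmean([r[k] for r in records])) for k in metric_keys}
    stds = {k: float(np.nanstd([r[k] for r in records])) for k in metric_keys}
    return CVResult(
        folds=records, means=means, stds=stds,
        protocol={
            "cv_folds": config.cv_folds,
            "seed": config.seed,
            "resample": rs_cfg is not None,
            "resample_before_split": bool(config.resample_before_split),
            "averaging": "macro (multiclass) / positive-class (binary)",
        },
    )
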