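"""Leave-one-out cross-validation and classification metrics.

Each of the n folds trains on n - 1 samples and predicts the held-out
one; feature standardization is refit inside :func:`~nirhsi.classifier.
train_classifier` on the training partition only, and the per-fold audit
log records the statistics' provenance so leakage is checkable after the
fact. Headline metric is balanced accuracy (unweighted mean of per-class
recalls), with per-class precision/recall/F1 and the confusion matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .classifier import ClassifierConfig, predict, train_classifier
from .errors import ConfigError, ShapeMismatchError

__all__ = ["CVResult", "loocv", "balanced_accuracy", "class_metrics"]


def _check_labels(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ShapeMismatchError("label vectors differ in length")
    if y_true.size == 0:
        raise ConfigError("empty label vectors")
    return y_true, y_pred


def balanced_accuracy(y_true, y_pred) -> float:
    """Unweighted mean of per-class recalls.

    Every class named in ``y_true`` contributes one recall; a class
    absent from ``y_true`` raises (its recall would be undefined).
    """
    y_true, y_pred = _check_labels(y_true, y_pred)
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ConfigError("balanced accuracy needs >= 2 classes in y_true")
    recalls = [
        float(np.mean(y_pred[y_true == c] == c)) for c in classes
    ]
    return float(np.mean(recalls))


def class_metrics(y_true, y_pred) -> dict:
    """Per-class precision/recall/F1 plus the confusion matrix.

    Zero predicted-positive denominators yield precision 0 with a
    warning, mirroring the undefined-metric convention.
    """
    y_true, y_pred = _check_labels(y_true, y_pred)
    classes = np.unique(np.concatenate([y_true, np.unique(y_true)]))
    cm = _sk_confusion(y_true, y_pred, labels=classes)
    out: dict = {"classes": classes.tolist(), "confusion_matrix": cm.tolist()}
    per_class = {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        if tp + fp == 0:
            warnings.warn(f"class {c}: no predicted positives; precision set to 0")
            prec = 0.0
        else:
            prec = tp / (tp + fp)
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[int(c)] = {
            "precision": float(prec),
            "recall": float(rec),
            "f1": float(f1),
            "support": int(cm[i, :].sum()),
        }
    out["per_class"] = per_class
    return out


@dataclass
class CVResult:
    """Aggregated leave-one-out result."""

    folds: pd.DataFrame  # sample_id, y_true, y_pred, proba_1, degenerate
    balanced_accuracy: float
    metrics: dict
    config: dict
    seed: int
    audit: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "folds": self.folds.to_dict(orient="records"),
            "balanced_accuracy": self.balanced_accuracy,
            "metrics": self.metrics,
            "config": self.config,
            "seed": self.seed,
            "audit": self.audit,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path


def loocv(
    features: pd.DataFrame,
    labels: np.ndarray,
    config: ClassifierConfig | None = None,
) -> CVResult:
    """Leave-one-out cross-validation of the neural classifier.

    Fold i trains on the other n - 1 samples (scaler refit on that
    partition only) and predicts sample i. A training partition missing a
    class is recorded as a degenerate fold predicted by training-majority
    vote, with a warning. Deterministic given ``config.seed``: fold i
    trains with seed ``config.seed + 1000 * (i + 1)``.
    """
    config = config or ClassifierConfig()
    y = np.asarray(labels, dtype=int)
    n = len(features)
    if n < 4:
        raise ConfigError("LOOCV needs >= 4 samples")
    if np.unique(y).size < 2:
        raise ConfigError("both classes must be present")
    ids = (
        list(features.index)
        if isinstance(features, pd.DataFrame)
        else [str(i) for i in range(n)]
    )
    X = np.asarray(features, dtype=np.float64)

    records = []
    audit = []
    from dataclasses import replace

    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        degenerate = np.unique(y_tr).size < 2
        if degenerate:
            warnings.warn(f"fold {i}: single-class training partition; majority vote")
            counts = np.bincount(y_tr, minlength=2)
            pred = int(np.argmax(counts))
            proba1 = counts[1] / counts.sum()
        else:
            fold_cfg = replace(config, seed=config.seed + 1000 * (i + 1))
            model = train_classifier(X_tr, y_tr, fold_cfg)
            labels_pred, proba = predict(model, X[i : i + 1])
            pred = int(labels_pred[0])
            proba1 = float(proba[0, 1])
            audit.append(
                {
                    "fold": i,
                    "held_out": ids[i],
                    "scaler_fit_n": model.train_log["scaler_fit_n"],
                    "scaler_mean_first": float(model.scaler_mean[0]),
                    "train_mean_first": float(X_tr[:, 0].mean()),
                }
            )
        records.append(
            {
                "sample_id": ids[i],
                "y_true": int(y[i]),
                "y_pred": pred,
                "proba_1": proba1,
                "degenerate": bool(degenerate),
            }
        )
    folds = pd.DataFrame(records)
    ba = balanced_accuracy(folds["y_true"], folds["y_pred"])
    metrics = class_metrics(folds["y_true"], folds["y_pred"])
    return CVResult(
        folds=folds,
        balanced_accuracy=ba,
        metrics=metrics,
        config=config.to_dict(),
        seed=config.seed,
        audit=audit,
    )
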