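"""Per-class metrics, cross-validation protocols and hypnogram comparison.

Metrics follow the one-vs-rest confusion-count definitions: for each class
accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), precision = TP/(TP+FP), F1 = 2*prec*sens/(prec+sens); undefined
0/0 ratios are reported as 0 and flagged.  A micro-averaged summary over
pooled one-vs-rest counts accompanies the per-class table.

Cross-validation re-fits min-max scaling and the variance filter inside
every training fold, pools predictions over folds, and computes metrics
once on the pool.  Folds are stratified (seeded) to keep scarce classes
represented in every training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import (
    LeaveOneOut,
    StratifiedKFold,
    StratifiedShuffleSplit,
)

from .errors import ConfigError, DataError
from .features import FeatureMatrix, apply_scaler, fit_scaler, variance_select
from .models import ModelSpec, predict, train
from .types import Hypnogram

log = logging.getLogger(__name__)


@dataclass
class ClassMetrics:
    """Per-class one-vs-rest metrics plus a micro-averaged summary."""

    classes: list[str]
    per_class: dict[str, dict[str, float]]
    counts: dict[str, dict[str, int]]
    micro: dict[str, float]
    overall_accuracy: float
    undefined: list[str] = field(default_factory=list)

    def table(self) -> str:
        """Plain-text table, metrics as rows and classes as columns."""
        metrics = ("accuracy", "sensitivity", "specificity", "precision", "f1")
        width = max(12, *(len(c) + 2 for c in self.classes))
        lines = ["".ljust(12) + "".join(c.rjust(width) for c in self.classes)]
        for m in metrics:
            row = m.capitalize().ljust(12)
            row += "".join(f"{self.per_class[c][m]:{width}.3f}" for c in self.classes)
            lines.append(row)
        lines.append(f"Overall accuracy: {self.overall_accuracy:.3f}")
        return "\n".join(lines)


def _ratio(num: float, den: float, flag: list, label: str) -> float:
    if den == 0:
        flag.append(label)
        return 0.0
    return num / den


def per_class_metrics(y_true, y_pred, classes: list[str] | None = None) -> ClassMetrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise DataError(f"length mismatch: {y_true.size} true vs {y_pred.size} predicted")
    if y_true.size == 0:
        raise DataError("empty label sequences")
    seen = set(np.unique(y_true)) | set(np.unique(y_pred))
    if classes is None:
        classes = sorted(seen)
    elif not seen <= set(classes):
        raise DataError(f"unknown labels {sorted(seen - set(classes))}")

    n = y_true.size
    undefined: list[str] = []
    per_class, counts = {}, {}
    tp_sum = fp_sum = fn_sum = tn_sum = 0
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        tn = n - tp - fp - fn
        counts[c] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
        sens = _ratio(tp, tp + fn, undefined, f"{c}:sensitivity")
        prec = _ratio(tp, tp + fp, undefined, f"{c}:precision")
        per_class[c] = {
            "accuracy": (tp + tn) / n,
            "sensitivity": sens,
            "specificity": _ratio(tn, tn + fp, undefined, f"{c}:specificity"),
            "precision": prec,
            "f1": _ratio(2 * prec * sens, prec + sens, undefined, f"{c}:f1"),
        }
        tp_sum += tp; fp_sum += fp; fn_sum += fn; tn_sum += tn

    micro_sens = _ratio(tp_sum, tp_sum + fn_sum, undefined, "micro:sensitivity")
    micro_prec = _ratio(tp_sum, tp_sum + fp_sum, undefined, "micro:precision")
    micro = {
        "accuracy": (tp_sum + tn_sum) / max(tp_sum + tn_sum + fp_sum + fn_sum, 1),
        "sensitivity": micro_sens,
        "specificity": _ratio(tn_sum, tn_sum + fp_sum, undefined, "micro:specificity"),
        "precision": micro_prec,
        "f1": _ratio(2 * micro_prec * micro_sens, micro_prec + micro_sens,
                     undefined, "micro:f1"),
    }
    return ClassMetrics(
        classes=list(classes), per_class=per_class, counts=counts, micro=micro,
        overall_accuracy=float(np.mean(y_true == y_pred)), undefined=undefined,
    )


def _splitter(scheme: str, k: int, test_fraction: float, seed: int):
    if scheme == "kfold":
        if k < 2:
            raise ConfigError(f"k-fold requires k >= 2, got {k}")
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    if scheme == "holdout":
        if not 0 < test_fraction < 1:
            raise ConfigError(f"test fraction must be in (0,1), got {test_fraction}")
        return StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                      random_state=seed)
    if scheme == "loocv":
        return LeaveOneOut()
    raise ConfigError(f"unknown CV scheme {scheme!r}")


def crossval(
    fm: FeatureMatrix,
    spec: ModelSpec,
    scheme: str = "kfold",
    k: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    variance_threshold: float = 0.2,
    preprocess: bool = True,
) -> tuple[ClassMetrics, np.ndarray, np.ndarray]:
    """Pooled cross-validated metrics on an (unscaled) feature matrix.

    Scaling and variance selection are fitted on each training fold only.
    Returns (metrics, pooled truth, pooled predictions); with the holdout
    scheme the pool is the single test subset.
    """
    X, y = fm.features, np.asarray(fm.stages)
    pooled_true, pooled_pred = [], []
    for train_idx, test_idx in _splitter(scheme, k, test_fraction, seed).split(X, y):
        if np.unique(y[train_idx]).size < np.unique(y).size:
            log.warning("a class is absent from a training fold")
        Xtr, Xte = X.iloc[train_idx], X.iloc[test_idx]
        if preprocess:
            params = fit_scaler(Xtr)
            Xtr = apply_scaler(Xtr, params)
            Xte = apply_scaler(Xte, params)
            Xtr, kept = variance_select(Xtr, variance_threshold)
            Xte = Xte[kept]
        model = train(spec, Xtr, y[train_idx])
        pooled_pred.extend(predict(model, Xte))
        pooled_true.extend(y[test_idx])
    y_true = np.asarray(pooled_true)
    y_pred = np.asarray(pooled_pred)
    return per_class_metrics(y_true, y_pred), y_true, y_pred


def feature_target_correlation(fm: FeatureMatrix, target: str = "REM") -> pd.Series:
    """Pearson r of every feature against the binary target-class indicator.

    Zero-variance features get r = 0 (flagged via a warning)."""
    y = np.asarray(fm.stages)
    if target not in y:
        raise DataError(f"target class {target!r} absent")
    ind = (y == target).astype(float)
    out = {}
    for col in fm.features.columns:
        x = fm.features[col].to_numpy(dtype=float)
        if x.std() == 0 or ind.std() == 0:
            log.warning("zero-variance column %s: correlation reported as 0", col)
            out[col] = 0.0
        else:
            out[col] = float(np.corrcoef(x, ind)[0, 1])
    return pd.Series(out, name=f"pearson_r_{target}")


def hypnogram_compare(true: Hypnogram, predicted: Hypnogram,
                      plot_path: str | Path | None = None) -> float:
    """Epoch-wise agreement fraction; optionally writes a comparison plot."""
    if len(true) != len(predicted):
        raise DataError(f"length mismatch: {len(true)} vs {len(predicted)} epochs")
    agree = float(np.mean([a == b for a, b in zip(true.labels, predicted.labels)]))
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        order = {"N3": 0, "N2": 1, "N1": 2, "REM": 3, "AWA": 4, "UNSCORED": 5}
        t = np.arange(len(true)) * true.epoch_length_s / 60.0
        fig, ax = plt.subplots(figsize=(10, 3))
        ax.step(t, [order[l] for l in true.labels], where="post", label="manual")
        ax.step(t, [order[l] for l in predicted.labels], where="post",
                label="automatic", alpha=0.7)
        ax.set_yticks(range(6), ["N3", "N2", "N1", "REM", "AWA", "UNS"])
        ax.set_xlabel("time (min)")
        ax.legend(loc="upper right")
        ax.set_title(f"hypnogram agreement {agree:.2f}")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return agree
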