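"""Multi-label evaluation metrics with bootstrap confidence intervals."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .calibration import ThresholdSet, f1_score_binary
from .types import CLASS_NAMES

__all__ = ["evaluate_multilabel", "multilabel_summary"]


def _point_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    n, c = y_true.shape
    out = {}
    for i in range(c):
        tp = np.sum((y_pred[:, i] == 1) & (y_true[:, i] == 1))
        fp = np.sum((y_pred[:, i] == 1) & (y_true[:, i] == 0))
        fn = np.sum((y_pred[:, i] == 0) & (y_true[:, i] == 1))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        out[f"precision_{i}"] = prec
        out[f"recall_{i}"] = rec
        out[f"f1_{i}"] = f1_score_binary(y_true[:, i], y_pred[:, i])
    out["macro_f1"] = float(np.mean([out[f"f1_{i}"] for i in range(c)]))
    tp = np.sum((y_pred == 1) & (y_true == 1))
    fp = np.sum((y_pred == 1) & (y_true == 0))
    fn = np.sum((y_pred == 0) & (y_true == 1))
    out["micro_f1"] = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    out["hamming_loss"] = float((y_pred != y_true).mean())
    inter = ((y_pred == 1) & (y_true == 1)).sum(axis=1)
    union = ((y_pred == 1) | (y_true == 1)).sum(axis=1)
    jac = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    out["jaccard"] = float(jac.mean())
    return out


def evaluate_multilabel(pred_probs: np.ndarray, thresholds: ThresholdSet,
                        labels: np.ndarray, classes=CLASS_NAMES,
                        n_bootstrap: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-class precision/recall/F1 + macro/micro F1, Hamming loss,
    sample-averaged Jaccard and per-class AUROC, with percentile bootstrap
    95% CIs (degenerate single-class AUROC reported as missing)."""
    probs = np.asarray(pred_probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if probs.shape != y.shape:
        raise ValueError("probability and label shapes differ")
    pred = thresholds.apply(probs, classes)
    point = _point_metrics(y, pred)
    for i, name in enumerate(classes):
        if len(np.unique(y[:, i])) < 2:
            point[f"auroc_{i}"] = np.nan
        else:
            point[f"auroc_{i}"] = float(roc_auc_score(y[:, i], probs[:, i]))

    rng = np.random.default_rng(seed)
    n = len(y)
    boot: dict[str, list] = {k: [] for k in point}
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        bm = _point_metrics(y[idx], pred[idx])
        for i in range(y.shape[1]):
            if len(np.unique(y[idx, i])) < 2:
                bm[f"auroc_{i}"] = np.nan
            else:
                bm[f"auroc_{i}"] = roc_auc_score(y[idx, i], probs[idx, i])
        for k, v in bm.items():
            boot[k].append(v)

    rows = []
    for k, v in point.items():
        samples = np.asarray(boot[k], dtype=float)
        with np.errstate(all="ignore"):
            lo, hi = (np.nanpercentile(samples, [2.5, 97.5])
                      if np.isfinite(samples).any() else (np.nan, np.nan))
        label = k
        for i, name in enumerate(classes):
            label = label.replace(f"_{i}", f"_{name}")
        rows.append({"metric": label, "value": v, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def multilabel_summary(table: pd.DataFrame) -> dict:
    """Flatten an evaluate_multilabel table into {metric: value}."""
    return dict(zip(table["metric"], table["value"]))
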