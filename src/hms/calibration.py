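"""Decision-threshold optimization and probability-calibration assessment.

Per-class F1-optimal thresholds are tuned on validation data only and
frozen before test evaluation.  Expected calibration error uses B=15
equal-width bins per class and reports the unweighted mean of the
per-class binary ECEs.  Temperature scaling and isotonic regression are
provided as post-hoc calibration baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.isotonic import IsotonicRegression

from .types import CLASS_NAMES

__all__ = ["ThresholdSet", "CalibrationReport", "optimize_thresholds", "ece",
           "temperature_scale", "isotonic_fit", "PerClassIsotonic",
           "f1_score_binary"]


@dataclass
class ThresholdSet:
    """Per-class decision cutoffs T_c; decision rule is p >= T -> positive."""

    thresholds: dict = field(default_factory=dict)

    def __getitem__(self, cls: str) -> float:
        return self.thresholds[cls]

    def as_array(self, classes=CLASS_NAMES) -> np.ndarray:
        return np.array([self.thresholds[c] for c in classes])

    @classmethod
    def fixed(cls, value: float = 0.5, classes=CLASS_NAMES) -> "ThresholdSet":
        return cls({c: value for c in classes})

    def apply(self, probs: np.ndarray, classes=CLASS_NAMES) -> np.ndarray:
        return (np.asarray(probs) >= self.as_array(classes)).astype(int)


def f1_score_binary(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """F1; a class with no positives and no predicted positives counts as
    vacuously perfect (1.0)."""
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0


def optimize_thresholds(val_probs: np.ndarray, val_labels: np.ndarray,
                        classes=CLASS_NAMES) -> ThresholdSet:
    """Per-class exhaustive F1 search over the unique predicted probabilities.

    F1 ties break to the SMALLEST threshold (recall-favouring: a screening
    system prefers the more aggressive cutoff).  A class with no positive
    validation labels falls back to 0.5 with a warning.
    """
    probs = np.asarray(val_probs, dtype=float)
    labels = np.asarray(val_labels)
    if probs.ndim == 1:
        probs = probs[:, None]
        labels = labels[:, None]
    out = {}
    for c, name in enumerate(classes[:probs.shape[1]]):
        p = probs[:, c]
        y = labels[:, c]
        if y.sum() == 0:
            warnings.warn(f"class {name} has no positive validation labels; "
                          "threshold defaults to 0.5")
            out[name] = 0.5
            continue
        candidates = np.unique(p)
        # vectorized sweep: sort descending, cumulative tp/fp at each cut
        order = np.argsort(-p, kind="stable")
        ps, ys = p[order], y[order]
        n_pos = ys.sum()
        best_f1, best_t = -1.0, 0.5
        for t in candidates:
            k = int(np.searchsorted(-ps, -t, side="right"))  # p >= t count
            tp = ys[:k].sum()
            fp = k - tp
            fn = n_pos - tp
            denom = 2 * tp + fp + fn
            f1 = 2 * tp / denom if denom else 0.0
            if f1 > best_f1 or (f1 == best_f1 and t < best_t):
                best_f1, best_t = f1, float(t)
        out[name] = best_t
    return ThresholdSet(out)


@dataclass
class CalibrationReport:
    ece: float
    per_class_ece: dict
    bins: pd.DataFrame        # class, bin, conf_mean, accuracy, count


def ece(probs: np.ndarray, labels: np.ndarray, bins: int = 15,
        classes=CLASS_NAMES) -> CalibrationReport:
    """Expected calibration error with equal-width bins over [0, 1].

    Per class: ECE_c = sum_b (n_b / N) |acc_b - conf_b| where the
    "accuracy" of a bin is the empirical positive rate of the binary
    label.  The headline number is the unweighted mean over classes.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.ndim == 1:
        probs = probs[:, None]
        labels = labels[:, None]
    n, n_cls = probs.shape
    rows = []
    per_class = {}
    for c in range(n_cls):
        name = classes[c] if c < len(classes) else f"class{c}"
        idx = np.minimum((probs[:, c] * bins).astype(int), bins - 1)
        e = 0.0
        for b in range(bins):
            mask = idx == b
            count = int(mask.sum())
            conf = float(probs[mask, c].mean()) if count else np.nan
            acc = float(labels[mask, c].mean()) if count else np.nan
            if count:
                e += (count / n) * abs(acc - conf)
            rows.append({"class": name, "bin": b, "conf_mean": conf,
                         "accuracy": acc, "count": count})
        per_class[name] = e
    table = pd.DataFrame(rows)
    return CalibrationReport(ece=float(np.mean(list(per_class.values()))),
                             per_class_ece=per_class, bins=table)


def temperature_scale(val_logits: np.ndarray, val_labels: np.ndarray) -> float:
    """T > 0 minimizing validation BCE of sigmoid(logits / T) (1-D search)."""
    logits = np.asarray(val_logits, dtype=float)
    labels = np.asarray(val_labels, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    flat_y = labels.ravel()
    if flat_y.min() == flat_y.max():
        warnings.warn("degenerate one-class validation set; T = 1")
        return 1.0

    def nll(log_t: float) -> float:
        t = np.exp(log_t)
        p = 1.0 / (1.0 + np.exp(-logits / t))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-(labels * np.log(p) + (1 - labels) * np.log(1 - p)).mean())

    res = minimize_scalar(nll, bounds=(np.log(0.05), np.log(20.0)),
                          method="bounded",
                          options={"xatol": 1e-6})
    return float(np.exp(res.x))


class PerClassIsotonic:
    """Monotone per-class probability remapping (pool-adjacent-violators)."""

    def __init__(self, models: dict):
        self._models = models

    def transform(self, probs: np.ndarray) -> np.ndarray:
        probs = np.asarray(probs, dtype=float)
        if probs.ndim == 1:
            probs = probs[:, None]
        out = probs.copy()
        for c, model in self._models.items():
            if model is not None:
                out[:, c] = model.predict(probs[:, c])
        return out


def isotonic_fit(val_probs: np.ndarray, val_labels: np.ndarray) -> PerClassIsotonic:
    """Fit a non-decreasing mapping per class on validation data.

    Classes with fewer than two distinct probabilities keep the identity
    mapping (with a warning).
    """
    probs = np.asarray(val_probs, dtype=float)
    labels = np.asarray(val_labels, dtype=float)
    if probs.ndim == 1:
        probs = probs[:, None]
        labels = labels[:, None]
    models = {}
    for c in range(probs.shape[1]):
        if len(np.unique(probs[:, c])) < 2:
            warnings.warn(f"class {c}: fewer than 2 distinct probabilities; "
                          "identity mapping")
            models[c] = None
            continue
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(probs[:, c], labels[:, c])
        models[c] = iso
    return PerClassIsotonic(models)
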