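"""Image-quality (MAE, PSNR) and classification metrics.

Classification metrics follow the usual confusion-count definitions,
reported as percentages:

    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100
    accuracy    = (TP + TN) / (TP + FP + TN + FN) * 100

Zero denominators yield ``None`` (an explicit "undefined" sentinel) rather
than NaN. For label maps whose cluster indices are arbitrary, MAE and
accuracy are computed after an optimal one-to-one label matching (Hungarian
assignment on the contingency table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["ConfusionCounts", "MetricsReport", "mae", "psnr",
           "classification_metrics", "match_labels", "mae_labels"]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return None if d == 0 else 100.0 * self.tp / d

    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return None if d == 0 else 100.0 * self.tn / d

    def accuracy(self) -> float | None:
        d = self.total
        return None if d == 0 else 100.0 * (self.tp + self.tn) / d


@dataclass
class MetricsReport:
    pooled: ConfusionCounts
    per_class: dict
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    macro_sensitivity: float | None = None
    macro_specificity: float | None = None
    positive_class: object = None

    def to_dict(self) -> dict:
        return {
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
            "macro_sensitivity_pct": self.macro_sensitivity,
            "macro_specificity_pct": self.macro_specificity,
            "positive_class": None if self.positive_class is None
            else int(self.positive_class),
            "per_class": {
                int(c): {"tp": cc.tp, "fp": cc.fp, "fn": cc.fn, "tn": cc.tn}
                for c, cc in self.per_class.items()
            },
        }


# ---------------------------------------------------------------------------
# Image quality


def mae(img_a: np.ndarray, img_b: np.ndarray) -> float:
    """Mean absolute error between two same-shape arrays."""
    a, b = np.asarray(img_a, dtype=float), np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


def psnr(img_a: np.ndarray, img_b: np.ndarray, max_value: float) -> float:
    """Peak signal-to-noise ratio ``10 log10(MAX^2 / MSE)`` in dB.

    ``max_value`` is the explicit peak of the intensity scale (1.0 for
    reflectance, 255 for 8-bit); identical images return ``math.inf``.
    """
    a, b = np.asarray(img_a, dtype=float), np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not max_value > 0:
        raise ValueError(f"max_value must be > 0; got {max_value}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_value**2 / mse)


# ---------------------------------------------------------------------------
# Label matching


def match_labels(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Optimal one-to-one map pred-label -> truth-label (Hungarian).

    Maximizes total agreement on the contingency table; surplus predicted
    labels keep their own value (identity) if unmatched.
    """
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    pv, tv = np.unique(pred), np.unique(truth)
    table = np.zeros((pv.size, tv.size), dtype=np.int64)
    for i, p in enumerate(pv):
        for j, t in enumerate(tv):
            table[i, j] = np.sum((pred == p) & (truth == t))
    rows, cols = linear_sum_assignment(-table)
    mapping = {int(p): int(p) for p in pv}
    for r, c in zip(rows, cols):
        mapping[int(pv[r])] = int(tv[c])
    return mapping


def mae_labels(pred_map: np.ndarray, truth_map: np.ndarray) -> float:
    """MAE between label maps after optimal label matching."""
    mapping = match_labels(pred_map, truth_map)
    remapped = np.vectorize(mapping.get)(np.asarray(pred_map))
    return mae(remapped, truth_map)


# ---------------------------------------------------------------------------
# Classification metrics


def _one_vs_rest(pred: np.ndarray, truth: np.ndarray, cls) -> ConfusionCounts:
    p = pred == cls
    t = truth == cls
    return ConfusionCounts(
        tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)), tn=int(np.sum(~p & ~t)),
    )


def _mean_or_none(values: list) -> float | None:
    vals = [v for v in values if v is not None]
    return None if not vals else float(np.mean(vals))


def classification_metrics(pred_map: np.ndarray, truth_map: np.ndarray,
                           positive_class=None) -> MetricsReport:
    """Confusion counts and percentage metrics from prediction vs truth.

    ``positive_class`` selects the one-vs-rest class driving the headline
    sensitivity/specificity (default: the highest truth label, the usual
    "abnormal tissue" convention here); macro averages over all classes are
    reported alongside. Pooled accuracy is exact multi-class agreement.
    """
    pred = np.asarray(pred_map).ravel()
    truth = np.asarray(truth_map).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred_map.shape} vs {truth_map.shape}")
    classes = np.unique(np.concatenate([np.unique(truth), np.unique(pred)]))
    if positive_class is None:
        positive_class = classes[-1]
    elif positive_class not in classes:
        raise ValueError(
            f"positive_class {positive_class!r} not among labels {classes.tolist()}"
        )

    per_class = {int(c): _one_vs_rest(pred, truth, c) for c in classes}
    pos = per_class[int(positive_class)]
    n = truth.size
    agree = int(np.sum(pred == truth))
    pooled = ConfusionCounts(tp=agree, fp=n - agree, fn=0, tn=0)

    return MetricsReport(
        pooled=pooled,
        per_class=per_class,
        sensitivity=pos.sensitivity(),
        specificity=pos.specificity(),
        accuracy=pos.accuracy(),
        macro_sensitivity=_mean_or_none(
            [cc.sensitivity() for cc in per_class.values()]),
        macro_specificity=_mean_or_none(
            [cc.specificity() for cc in per_class.values()]),
        positive_class=positive_class,
    )
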