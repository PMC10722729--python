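"""Micro-averaged precision, recall and F1 over the 7 interaction-type tasks.

True/false positives and false negatives are pooled across all labels and
all pairs before precision = TP/(TP+FP), recall = TP/(TP+FN) and
F1 = 2PR/(P+R) are computed once. Zero denominators yield 0, never NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import INTERACTION_TYPES

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    micro_f1: float
    per_label_counts: dict = field(default_factory=dict)
    n_samples: int = 0
    na: bool = False  # True for a degenerate (empty) evaluation stratum

    def to_json(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "micro_f1": self.micro_f1,
            "per_label_counts": self.per_label_counts,
            "n_samples": self.n_samples,
            "na": self.na,
        }


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        logger.debug("zero denominator in metric; returning 0 by convention")
        return 0.0
    return num / den


def micro_f1(pred, truth) -> MetricsReport:
    """Pooled-count micro metrics on binary (n, 7) prediction/truth matrices."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.ndim != 2 or pred.shape[1] != len(INTERACTION_TYPES):
        raise ValueError(f"expected (n, {len(INTERACTION_TYPES)}) matrices, got {pred.shape}")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2.0 * precision * recall, precision + recall)
    per_label = {
        t: {
            "tp": int((pred[:, j] & truth[:, j]).sum()),
            "fp": int((pred[:, j] & ~truth[:, j]).sum()),
            "fn": int((~pred[:, j] & truth[:, j]).sum()),
            "support": int(truth[:, j].sum()),
        }
        for j, t in enumerate(INTERACTION_TYPES)
    }
    return MetricsReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        micro_f1=f1,
        per_label_counts=per_label,
        n_samples=pred.shape[0],
    )


def macro_f1(pred, truth) -> float:
    """Supplementary unweighted mean of per-label F1 scores."""
    report = micro_f1(pred, truth)
    f1s = []
    for counts in report.per_label_counts.values():
        tp, fp, fn = counts["tp"], counts["fp"], counts["fn"]
        p = _safe_div(tp, tp + fp)
        r = _safe_div(tp, tp + fn)
        f1s.append(_safe_div(2.0 * p * r, p + r))
    return float(np.mean(f1s))
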