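"""Classification metrics: precision / recall / F-score, MCC and AUC."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .types import POSITIVE


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self):
        return self.tp + self.fp + self.fn + self.tn


def confusion(gold_labels, pred_labels) -> ConfusionCounts:
    c = ConfusionCounts()
    for g, p in zip(gold_labels, pred_labels, strict=True):
        g_pos, p_pos = g == POSITIVE, p == POSITIVE
        if g_pos and p_pos:
            c.tp += 1
        elif not g_pos and p_pos:
            c.fp += 1
        elif g_pos and not p_pos:
            c.fn += 1
        else:
            c.tn += 1
    return c


def prf(counts: ConfusionCounts):
    """(precision, recall, F) in [0,1]; zero denominators yield 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def f_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); accepts either fractions or percentages."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve with tie averaging."""
    y = np.asarray([1 if l == POSITIVE else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class EvalReport:
    precision: float
    recall: float
    f_score: float
    mcc: float
    auc: float
    counts: ConfusionCounts

    def as_dict(self, percent=True):
        scale = 100.0 if percent else 1.0
        return {
            "precision": round(self.precision * scale, 2),
            "recall": round(self.recall * scale, 2),
            "f_score": round(self.f_score * scale, 2),
            "mcc": round(self.mcc, 4),
            "auc": round(self.auc, 4),
            "counts": {"TP": self.counts.tp, "FP": self.counts.fp,
                       "FN": self.counts.fn, "TN": self.counts.tn},
        }

    def to_json(self, path, percent=True):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.as_dict(percent), fh, indent=2)


def evaluate(gold_labels, pred_labels, scores=None) -> EvalReport:
    """Full report from gold labels, predicted labels and (optionally) scores."""
    counts = confusion(gold_labels, pred_labels)
    p, r, f = prf(counts)
    try:
        a = auc(scores, gold_labels) if scores is not None else float("nan")
    except ValueError:
        a = float("nan")
    return EvalReport(p, r, f, mcc(counts), a, counts)
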