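"""Confusion-matrix metrics, AUC and the PhysioNet/CinC 2015 challenge score.

The positive class is TRUE_ALARM throughout: sensitivity is the fraction of
real alarms kept, specificity the fraction of false alarms suppressed.  The
challenge score

    score = (TP + TN) / (TP + TN + FP + 5 * FN)

penalizes a suppressed true alarm five-fold, which is also why prediction
ties resolve to the positive class.  Ratios with a zero denominator are
reported as NaN together with a flag naming the metric, never silently
coerced to 0 (per-alarm-type tables can have single-digit minority classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .exceptions import SchemaError
from .io import Label

__all__ = [
    "MetricsReport",
    "predicted_labels",
    "confusion",
    "basic_metrics",
    "auc",
    "challenge_score",
    "compute_report",
]

POSITIVE = Label.TRUE_ALARM


def _as_bool(labels: Sequence) -> np.ndarray:
    out = []
    for l in labels:
        if isinstance(l, Label):
            if l is Label.UNKNOWN:
                raise SchemaError("cannot score a record with UNKNOWN label")
            out.append(l is POSITIVE)
        else:
            out.append(bool(l))
    return np.asarray(out, dtype=bool)


def predicted_labels(probs: np.ndarray) -> np.ndarray:
    """argmax over {false, true} with ties resolved to the positive class."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    return probs[:, 1] >= probs[:, 0]


def confusion(labels: Sequence, predicted: Sequence) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) counts with TRUE_ALARM as the positive class."""
    y = _as_bool(labels)
    p = _as_bool(predicted)
    if y.shape != p.shape:
        raise SchemaError("labels and predictions differ in length")
    tp = int(np.sum(y & p))
    tn = int(np.sum(~y & ~p))
    fp = int(np.sum(~y & p))
    fn = int(np.sum(y & ~p))
    return tp, tn, fp, fn


def basic_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[dict[str, float], set[str]]:
    """SEN/SPE/PRE/F1/ACC as fractions in [0, 1]; 0/0 ratios -> NaN + flag."""
    flags: set[str] = set()

    def ratio(num, den, name):
        if den == 0:
            flags.add(name)
            return float("nan")
        return num / den

    sen = ratio(tp, tp + fn, "sen")
    spe = ratio(tn, tn + fp, "spe")
    pre = ratio(tp, tp + fp, "pre")
    acc = ratio(tp + tn, tp + tn + fp + fn, "acc")
    if np.isnan(sen) or np.isnan(pre) or (pre + sen) == 0:
        flags.add("f1")
        f1 = float("nan")
    else:
        f1 = 2 * pre * sen / (pre + sen)
    return {"sen": sen, "spe": spe, "pre": pre, "f1": f1, "acc": acc}, flags


def auc(labels: Sequence, positive_probs: Sequence[float]) -> float:
    """ROC area (Mann-Whitney statistic; ties count one half).

    NaN when only one class is present.
    """
    y = _as_bool(labels)
    scores = np.asarray(positive_probs, dtype=np.float64)
    if y.all() or not y.any():
        return float("nan")
    return float(roc_auc_score(y.astype(int), scores))


def challenge_score(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + 5 FN); NaN on an empty table."""
    den = tp + tn + fp + 5 * fn
    if den == 0:
        return float("nan")
    return (tp + tn) / den


@dataclass
class MetricsReport:
    """Confusion counts plus the derived metric panel (fractions in [0, 1])."""

    tp: int
    tn: int
    fp: int
    fn: int
    sen: float
    spe: float
    pre: float
    f1: float
    acc: float
    auc: float
    challenge_score: float
    undefined: set[str] = field(default_factory=set)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_percent(self) -> dict[str, float]:
        """Metrics on the 0-100 scale used in reported tables."""
        return {
            k: 100.0 * getattr(self, k)
            for k in ("sen", "spe", "pre", "f1", "auc", "acc", "challenge_score")
        }

    def summary(self) -> str:
        pct = self.as_percent()
        lines = [
            "Alarm classification metrics (positive = true alarm)",
            f"  n = {self.n}   TP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn}",
            "  "
            + "  ".join(
                f"{name.upper()}={pct[name]:.2f}%"
                for name in ("sen", "spe", "pre", "f1", "auc", "acc")
                if not np.isnan(pct[name])
            ),
            f"  Challenge-2015 score = {pct['challenge_score']:.2f}%",
        ]
        if self.undefined:
            lines.append(f"  undefined (0/0): {sorted(self.undefined)}")
        return "\n".join(lines)


def compute_report(labels: Sequence, probs: np.ndarray) -> MetricsReport:
    """Full metric panel from true labels and predicted class distributions."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    pred = predicted_labels(probs)
    tp, tn, fp, fn = confusion(labels, pred)
    metrics, flags = basic_metrics(tp, tn, fp, fn)
    a = auc(labels, probs[:, 1])
    if np.isnan(a):
        flags.add("auc")
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn, auc=a,
        challenge_score=challenge_score(tp, tn, fp, fn),
        undefined=flags, **metrics,
    )
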