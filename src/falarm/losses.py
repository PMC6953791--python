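"""Class-imbalance-aware losses: mean false error (MFE) and mean squared
false error (MSFE), with plain MSE as the baseline.

With true alarms a small minority of ICU alarm episodes, the usual MSE is
dominated by the majority class.  MFE instead averages the squared error
*within* each class first and sums the per-class means,

    l(g) = (1/|g|) sum_{samples in g} mean_j (y_j - yhat_j)^2
    L_MFE  = sum_g l(g)
    L_MSFE = sum_g l(g)^2

so each class contributes equally regardless of its size.  MSFE additionally
squares the per-class means, pushing the optimizer toward balancing them.
The training objective adds an L2 penalty beta * sum(theta^2) over the
trainable parameters (beta = 0.001 by default).

The per-sample error is the *mean* over the two softmax units of the squared
difference.  With a two-unit softmax the two unit errors are identical, so
mean versus sum changes every loss by a constant factor 2 only; the mean is
fixed here for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ExcludedClassError, SchemaError

__all__ = [
    "LossKind",
    "LossConfig",
    "per_sample_error",
    "class_error",
    "mfe",
    "msfe",
    "objective",
    "batch_loss",
    "loss_gradient",
]


class LossKind(str, Enum):
    MFE = "mfe"
    MSFE = "msfe"
    MSE = "mse"


@dataclass(frozen=True)
class LossConfig:
    kind: LossKind = LossKind.MFE
    l2_beta: float = 0.001

    def __post_init__(self) -> None:
        if self.l2_beta < 0:
            raise SchemaError("l2_beta must be non-negative")


def per_sample_error(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean over output units of the squared difference for one sample."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise SchemaError("label and prediction shapes differ")
    if not (np.all(y_hat >= -1e-9) and abs(y_hat.sum() - 1.0) < 1e-6):
        raise SchemaError("prediction is not a probability distribution")
    if not (np.all((y == 0) | (y == 1)) and y.sum() == 1):
        raise SchemaError("label is not one-hot")
    return float(np.mean((y - y_hat) ** 2))


def class_error(errors_by_class: Mapping[object, Sequence[float]]) -> dict:
    """Per-class mean of per-sample errors; an empty class is an error."""
    out = {}
    for cls, errs in errors_by_class.items():
        errs = np.asarray(list(errs), dtype=np.float64)
        if errs.size == 0:
            raise ExcludedClassError(f"class {cls!r} has no samples")
        out[cls] = float(errs.mean())
    return out


def mfe(errors_by_class: Mapping[object, Sequence[float]]) -> float:
    return float(sum(class_error(errors_by_class).values()))


def msfe(errors_by_class: Mapping[object, Sequence[float]]) -> float:
    return float(sum(v**2 for v in class_error(errors_by_class).values()))


def _group_errors(probs: np.ndarray, labels: np.ndarray) -> dict[int, np.ndarray]:
    """Per-class arrays of per-sample errors; absent classes are omitted
    (a mini-batch missing one class contributes only the present class)."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.ndim != 2 or probs.shape[0] != labels.shape[0]:
        raise SchemaError("probs must be (B, n_classes) aligned with labels")
    onehot = np.eye(probs.shape[1])[labels]
    errs = np.mean((onehot - probs) ** 2, axis=1)
    return {int(c): errs[labels == c] for c in np.unique(labels)}


def batch_loss(probs: np.ndarray, labels: np.ndarray, kind: LossKind) -> float:
    """Selected loss over a batch of predicted distributions and int labels."""
    groups = _group_errors(probs, labels)
    if kind is LossKind.MSE:
        return float(np.mean((np.eye(probs.shape[1])[labels] - probs) ** 2))
    if kind is LossKind.MFE:
        return mfe(groups)
    if kind is LossKind.MSFE:
        return msfe(groups)
    raise SchemaError(f"unknown loss kind {kind!r}")


def objective(
    batch_outputs: np.ndarray,
    batch_labels: np.ndarray,
    params: Iterable[np.ndarray] = (),
    config: LossConfig = LossConfig(),
) -> float:
    """Training objective: selected loss + beta * sum of squared parameters."""
    penalty = config.l2_beta * sum(float(np.sum(p.astype(np.float64) ** 2)) for p in params)
    return batch_loss(batch_outputs, batch_labels, config.kind) + penalty


def loss_gradient(probs: np.ndarray, labels: np.ndarray, kind: LossKind) -> np.ndarray:
    """d(loss)/d(probs) for the selected loss, shape (B, n_classes)."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    n_units = probs.shape[1]
    onehot = np.eye(n_units)[labels]
    diff = probs - onehot  # d(l_s)/dp = (2/K) * diff for the mean-over-units error
    if kind is LossKind.MSE:
        return 2.0 * diff / probs.size
    if kind not in (LossKind.MFE, LossKind.MSFE):
        raise SchemaError(f"unknown loss kind {kind!r}")
    grad = np.empty_like(diff)
    for c in np.unique(labels):
        mask = labels == c
        g_c = int(mask.sum())
        per_class = 2.0 * diff[mask] / (n_units * g_c)
        if kind is LossKind.MSFE:  # d(l(g)^2) = 2 l(g) dl(g)
            l_g = float(np.mean((onehot[mask] - probs[mask]) ** 2))
            per_class = 2.0 * l_g * per_class
        grad[mask] = per_class
    return grad
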