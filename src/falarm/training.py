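"""Two-step training and the cross-validated experiment protocol.

Step 1 pre-trains one feature network per modality against the true/false
alarm labels.  Each network's softmax head is then stripped and the backbone
frozen.  Step 2 trains only the small fusion head (FC-256 + dropout +
softmax) on the elementwise mean of the frozen modality embeddings.  In
single-modal experiments step 2 is skipped and the modality network's own
softmax classifies.

Experiments follow stratified k-fold cross-validation: both training steps
are repeated inside every fold, predictions on the held-out folds are pooled
("concatenated") and scored once, with per-fold panels kept alongside.
Every source of randomness (parameter init, batch order, dropout, fold
shuffling) is derived from the experiment seed, so a rerun with the same
config reproduces pooled metrics exactly.

The experiment layer is exposed in the model/results idiom:
``AlarmClassification(records, config).fit()`` returns an
:class:`ExperimentResult` with the pooled metric panel, per-fold detail,
loss traces and a ``summary()`` table; :func:`run_experiment` is the
equivalent functional entry point.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .evaluation import MetricsReport, compute_report
from .exceptions import ConfigError, ContractError, InsufficientDataError, MissingModalityError
from .io import AlarmType, ChannelRole, Label, WaveformRecord
from .losses import LossConfig, loss_gradient, objective
from .network import FusionHead, ModalConfig, ModalNet
from .preprocessing import PreprocessConfig, prepare_modality

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "RMSProp",
    "train_modal_net",
    "strip_softmax",
    "train_fusion",
    "kfold_split",
    "run_experiment",
    "AlarmClassification",
    "ExperimentResult",
]

_ROLE_INDEX = {r: i for i, r in enumerate(ChannelRole)}


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for both training steps and the experiment protocol.

    Defaults mirror the reference protocol: RMSProp at learning rate 0.001,
    mini-batches of 10, up to 100 epochs, MFE loss with L2 beta = 0.001,
    10-fold stratified cross-validation (5-fold is conventional for the
    per-alarm-type experiments).
    """

    seed: int
    n_epochs: int = 100
    batch_size: int = 10
    learning_rate: float = 0.001
    rms_decay: float = 0.9
    rms_epsilon: float = 1e-8
    loss: LossConfig = field(default_factory=LossConfig)
    k_folds: int = 10
    stratified: bool = True
    modalities: tuple[ChannelRole, ...] = (ChannelRole.ECG_II,)
    alarm_filter: Optional[AlarmType] = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    modal: ModalConfig = field(default_factory=ModalConfig)
    early_stopping: bool = False
    patience: int = 10
    min_delta: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_epochs < 0:
            raise ConfigError("n_epochs must be >= 0")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        if not self.modalities:
            raise ConfigError("at least one modality is required")

    def snapshot(self) -> dict:
        return {
            "seed": self.seed,
            "n_epochs": self.n_epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "rms_decay": self.rms_decay,
            "rms_epsilon": self.rms_epsilon,
            "loss": {"kind": self.loss.kind.value, "l2_beta": self.loss.l2_beta},
            "k_folds": self.k_folds,
            "stratified": self.stratified,
            "modalities": [m.value for m in self.modalities],
            "alarm_filter": self.alarm_filter.value if self.alarm_filter else None,
            "window_seconds": self.preprocess.window_seconds,
            "segment_samples": self.preprocess.segment_samples,
            "overlap_fraction": self.preprocess.overlap_fraction,
            "n_slices": self.modal.n_slices,
            "attention_enabled": self.modal.attention_enabled,
            "lstm_size": self.modal.lstm_size,
            "early_stopping": self.early_stopping,
        }


class RMSProp:
    """RMSProp with the standard squared-gradient running average."""

    def __init__(self, learning_rate: float = 0.001, decay: float = 0.9,
                 epsilon: float = 1e-8):
        self.lr = learning_rate
        self.decay = decay
        self.eps = epsilon
        self.cache: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for name, g in grads.items():
            c = self.cache.get(name)
            if c is None:
                c = self.cache[name] = np.zeros_like(params[name])
            c *= self.decay
            c += (1.0 - self.decay) * g * g
            params[name] -= (self.lr * g / (np.sqrt(c) + self.eps)).astype(params[name].dtype)


def _label_int(label: Label) -> int:
    if label is Label.UNKNOWN:
        raise ConfigError("cannot train on a record with UNKNOWN label")
    return 1 if label is Label.TRUE_ALARM else 0


def _prepare(records: Sequence[WaveformRecord], role: ChannelRole,
             config: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    batches = [prepare_modality(r, role, config.preprocess) for r in records]
    X = np.stack([b.segments for b in batches]).astype(config.modal.dtype)
    y = np.array([_label_int(r.label) for r in records], dtype=np.int64)
    return X, y


def _derived_seed(config_seed: int, *context: int) -> int:
    return int(np.random.SeedSequence([config_seed, *context]).generate_state(1)[0] % (2**31))


def _train_ids_digest(records: Sequence[WaveformRecord]) -> str:
    h = hashlib.sha256()
    for rid in sorted(r.record_id for r in records):
        h.update(rid.encode())
    return h.hexdigest()[:16]


def _batched(fn, X: np.ndarray, batch: int = 32) -> np.ndarray:
    return np.concatenate([fn(X[i : i + batch]) for i in range(0, len(X), batch)])


def train_modal_net(
    records: Sequence[WaveformRecord],
    channel_role: ChannelRole,
    config: TrainConfig,
    seed_context: tuple[int, ...] = (),
) -> tuple[ModalNet, list[float]]:
    """Step-1 pre-training of one modality network.

    Deterministic given the config seed (and an optional context such as the
    fold index): initialization and the per-epoch batch order are both
    derived from it.  Returns the net and the per-epoch objective trace.
    """
    if not records:
        raise InsufficientDataError("no records to train on")
    X, y = _prepare(records, channel_role, config)
    ctx = (*seed_context, _ROLE_INDEX[channel_role])
    net = ModalNet(config.modal, seed=_derived_seed(config.seed, 0, *ctx))
    trace = _fit(net, X, y, config, order_seed=_derived_seed(config.seed, 1, *ctx))
    net.provenance = {
        "role": channel_role.value,
        "train_ids_digest": _train_ids_digest(records),
        "seed_context": list(ctx),
    }
    return net, trace


def _fit(model, X, y, config: TrainConfig, order_seed: int,
         dropout_seed: Optional[int] = None) -> list[float]:
    """Shared mini-batch RMSProp loop for ModalNet and FusionHead."""
    beta = config.loss.l2_beta
    kind = config.loss.kind
    opt = RMSProp(config.learning_rate, config.rms_decay, config.rms_epsilon)
    order_rng = np.random.default_rng(order_seed)
    drop_rng = np.random.default_rng(dropout_seed) if dropout_seed is not None else None
    is_head = isinstance(model, FusionHead)
    trace: list[float] = []
    best, stale = np.inf, 0
    for _ in range(config.n_epochs):
        perm = order_rng.permutation(len(X))
        batch_losses = []
        for start in range(0, len(X), config.batch_size):
            idx = perm[start : start + config.batch_size]
            if is_head:
                probs, cache = model.forward(X[idx], training=True, rng=drop_rng,
                                             need_cache=True)
            else:
                probs, _, cache = model.forward(X[idx], need_cache=True)
            grads = model.backward(cache, loss_gradient(probs, y[idx], kind))
            params = model.trainable_params()
            if params:
                for name in params:
                    grads[name] = grads[name] + 2.0 * beta * params[name]
                opt.step(params, {name: grads[name] for name in params})
            batch_losses.append(objective(probs, y[idx], params.values(), config.loss))
        epoch_loss = float(np.mean(batch_losses))
        trace.append(epoch_loss)
        if config.early_stopping:
            if epoch_loss < best - config.min_delta:
                best, stale = epoch_loss, 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    return trace


def strip_softmax(net: ModalNet) -> ModalNet:
    """Remove the softmax head and freeze the backbone (idempotent).

    The returned net only produces 256-dim embeddings; class-probability
    queries raise :class:`ContractError`.
    """
    stripped = net.copy()
    stripped.stripped = True
    stripped.frozen = True
    return stripped


def _check_modalities(records, modalities):
    for rec in records:
        missing = [m.value for m in modalities if m not in rec.channels]
        if missing:
            raise MissingModalityError(
                f"record {rec.record_id!r} lacks {missing}"
            )


def train_fusion(
    records: Sequence[WaveformRecord],
    nets: dict[ChannelRole, ModalNet],
    config: TrainConfig,
    seed_context: tuple[int, ...] = (),
) -> tuple[FusionHead, list[float]]:
    """Step-2 training of the fusion head on frozen modality embeddings."""
    for role, net in nets.items():
        if not net.frozen:
            raise ContractError(f"{role.value} backbone must be frozen before fusion")
    _check_modalities(records, nets.keys())
    emb = _mean_embeddings(records, nets, config)
    y = np.array([_label_int(r.label) for r in records], dtype=np.int64)
    head = FusionHead(
        embed_size=emb.shape[1],
        seed=_derived_seed(config.seed, 2, *seed_context),
        fc_size=config.modal.fc_size,
        n_classes=config.modal.n_classes,
        dtype=config.modal.dtype,
    )
    trace = _fit(head, emb, y, config,
                 order_seed=_derived_seed(config.seed, 3, *seed_context),
                 dropout_seed=_derived_seed(config.seed, 4, *seed_context))
    return head, trace


def _mean_embeddings(records, nets: dict[ChannelRole, ModalNet],
                     config: TrainConfig) -> np.ndarray:
    per_role = []
    for role in sorted(nets, key=lambda r: r.value):
        X, _ = _prepare(records, role, config)
        per_role.append(_batched(nets[role].embed, X))
    return np.mean(per_role, axis=0)


def kfold_split(
    records: Sequence[WaveformRecord], k: int, stratified: bool, seed: int
) -> list[tuple[list[str], list[str]]]:
    """Partition record ids into k folds (stratified by label and, where the
    strata allow, jointly by alarm type)."""
    n = len(records)
    if k > n:
        raise ConfigError(f"k={k} folds but only {n} records")
    if k < 2:
        raise ConfigError("k must be >= 2")
    ids = np.array([r.record_id for r in records])
    folds = []
    if stratified:
        for key in (
            [f"{r.label.value}/{r.alarm_type.value if r.alarm_type else '?'}" for r in records],
            [r.label.value for r in records],
        ):
            counts = np.unique(key, return_counts=True)[1]
            if counts.min() >= k:
                splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
                for tr, te in splitter.split(ids, key):
                    folds.append((list(ids[tr]), list(ids[te])))
                return folds
        logger.debug("strata smaller than k; falling back to unstratified folds")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, te in splitter.split(ids):
        folds.append((list(ids[tr]), list(ids[te])))
    return folds


@dataclass
class ExperimentResult:
    """Pooled cross-validation outcome plus per-fold detail.

    Predictions from every held-out fold are concatenated and scored once
    (``metrics``); per-fold panels are in ``fold_metrics``.  ``checkpoints``
    maps (fold, role) to the trained network and ``(fold, "fusion")`` to the
    fusion head, each tagged with the training-split digest it was fitted on.
    """

    record_ids: list[str]
    labels: list[Label]
    probs: np.ndarray  # (N, 2) pooled predicted distributions
    fold_assignment: list[int]
    metrics: MetricsReport
    fold_metrics: list[MetricsReport]
    config: dict
    excluded_ids: list[str]
    loss_traces: dict
    checkpoints: dict

    @property
    def n_folds(self) -> int:
        return len(self.fold_metrics)

    def fold_mean(self, name: str) -> float:
        """Mean of a metric over folds (ignoring folds where it is undefined)."""
        vals = [getattr(m, name) for m in self.fold_metrics]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Cross-validated alarm classification",
            "=" * 52,
            f"modalities : {', '.join(cfg['modalities'])}"
            + (f"   alarm type: {cfg['alarm_filter']}" if cfg.get("alarm_filter") else ""),
            f"records    : {len(self.record_ids)} scored"
            + (f" ({len(self.excluded_ids)} excluded: missing modality)" if self.excluded_ids else ""),
            f"protocol   : {self.n_folds}-fold CV, {cfg['n_epochs']} epochs, "
            f"batch {cfg['batch_size']}, {cfg['loss']['kind']} loss, seed {cfg['seed']}",
            "-" * 52,
            self.metrics.summary(),
            "-" * 52,
            "per-fold means: "
            + "  ".join(
                f"{name.upper()}={100 * self.fold_mean(name):.2f}%"
                for name in ("sen", "spe", "acc", "auc")
            ),
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve of the pooled predictions (matplotlib Axes)."""
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        y = [1 if l is Label.TRUE_ALARM else 0 for l in self.labels]
        fpr, tpr, _ = roc_curve(y, self.probs[:, 1])
        ax.plot(fpr, tpr, label=f"AUC = {self.metrics.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "metrics": {
                **{k: getattr(self.metrics, k) for k in ("tp", "tn", "fp", "fn")},
                **self.metrics.as_percent(),
                "undefined": sorted(self.metrics.undefined),
            },
            "fold_metrics": [m.as_percent() for m in self.fold_metrics],
            "excluded_ids": self.excluded_ids,
            "record_ids": self.record_ids,
            "fold_assignment": self.fold_assignment,
            "probs_true": self.probs[:, 1].tolist(),
            "labels": [l.value for l in self.labels],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def run_experiment(records: Sequence[WaveformRecord], config: TrainConfig) -> ExperimentResult:
    """Full protocol: filter -> k-fold -> two-step training per fold -> pooled metrics."""
    return AlarmClassification(records, config).fit()


class AlarmClassification:
    """Model object for the cross-validated true/false-alarm experiment.

    Parameters
    ----------
    records : the alarm episodes (with labels) to evaluate on.
    config : :class:`TrainConfig`; ``modalities`` selects single- or
        multi-modal mode and ``alarm_filter`` restricts to one alarm type.
    """

    def __init__(self, records: Sequence[WaveformRecord], config: TrainConfig):
        self.config = config
        if config.alarm_filter is not None:
            records = [r for r in records if r.alarm_type == config.alarm_filter]
        self.excluded = [
            r.record_id
            for r in records
            if any(m not in r.channels for m in config.modalities)
        ]
        if self.excluded:
            logger.info(
                "excluding %d/%d records missing a configured modality",
                len(self.excluded), len(records),
            )
        self.records = [r for r in records if r.record_id not in set(self.excluded)]

    @classmethod
    def from_directory(cls, data_dir, labels_csv, config: TrainConfig) -> "AlarmClassification":
        from pathlib import Path

        from .io import load_label_table, read_record

        table = load_label_table(labels_csv)
        records = [
            read_record(p, table) for p in sorted(Path(data_dir).glob("*.hea"))
        ]
        return cls(records, config)

    def fit(self) -> ExperimentResult:
        config = self.config
        records = self.records
        if len(records) < config.k_folds:
            raise ConfigError(
                f"{len(records)} records cannot fill {config.k_folds} folds"
            )
        by_id = {r.record_id: r for r in records}
        folds = kfold_split(records, config.k_folds, config.stratified, config.seed)
        multimodal = len(config.modalities) > 1

        ids, labels, probs, fold_of = [], [], [], []
        fold_metrics, checkpoints, traces = [], {}, {}
        for i, (train_ids, test_ids) in enumerate(folds):
            train = [by_id[r] for r in train_ids]
            test = [by_id[r] for r in test_ids]
            nets = {}
            for role in config.modalities:
                net, trace = train_modal_net(train, role, config, seed_context=(i,))
                net.provenance["fold"] = i
                nets[role] = net
                checkpoints[(i, role.value)] = net
                traces[(i, role.value)] = trace
            if multimodal:
                frozen = {r: strip_softmax(n) for r, n in nets.items()}
                head, htrace = train_fusion(train, frozen, config, seed_context=(i,))
                checkpoints[(i, "fusion")] = head
                traces[(i, "fusion")] = htrace
                fold_probs, _ = head.forward(_mean_embeddings(test, frozen, config))
            else:
                role = config.modalities[0]
                X_test, _ = _prepare(test, role, config)
                fold_probs = _batched(nets[role].predict_proba, X_test)
            fold_labels = [r.label for r in test]
            fold_metrics.append(compute_report(fold_labels, fold_probs))
            ids.extend(test_ids)
            labels.extend(fold_labels)
            probs.append(fold_probs)
            fold_of.extend([i] * len(test_ids))

        pooled = np.concatenate(probs)
        return ExperimentResult(
            record_ids=ids,
            labels=labels,
            probs=pooled,
            fold_assignment=fold_of,
            metrics=compute_report(labels, pooled),
            fold_metrics=fold_metrics,
            config=config.snapshot(),
            excluded_ids=self.excluded,
            loss_traces=traces,
            checkpoints=checkpoints,
        )
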