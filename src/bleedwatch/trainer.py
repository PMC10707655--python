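"""Training loop and metrics for the multi-task network.

The two task losses are combined without weighting::

    loss = seg_loss + cls_loss

where ``seg_loss`` is mean per-pixel binary cross-entropy against the
instrument mask and ``cls_loss`` is cross-entropy against the binary
blood-accumulation label. Event-detection accuracy is the plain fraction
``correct_predictions / samples``, reported overall and per class.

Both cross-entropies clamp probabilities at ``EPS = 1e-7`` so reported loss
values are exactly reproducible. Gradients are taken on the logits, so the
clamp only affects the reported numbers, not optimisation.
"""

from __future__ import annotations

import copy
import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _nn
from .mtlnet import MTLUNet
from .scenegen import FrameSample

__all__ = [
    "EPS",
    "LossBreakdown",
    "MetricCounts",
    "TrainConfig",
    "TrainResult",
    "seg_loss",
    "cls_loss",
    "multi_task_loss",
    "classification_accuracy",
    "percent",
    "evaluate",
    "train",
]

EPS = 1e-7


@dataclass(frozen=True)
class LossBreakdown:
    """Per-task loss components in nats; ``total`` is their exact sum."""

    seg_loss: float
    cls_loss: float
    total: float


@dataclass
class MetricCounts:
    """Raw counts behind the accuracy formula."""

    correct_predictions: int
    samples: int
    per_class_correct: np.ndarray
    per_class_total: np.ndarray

    def __post_init__(self) -> None:
        if self.correct_predictions > self.samples:
            raise ValueError("correct_predictions cannot exceed samples")
        if int(self.per_class_total.sum()) != self.samples:
            raise ValueError("per-class totals must sum to samples")

    def per_class_accuracy(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.per_class_total > 0,
                self.per_class_correct / np.maximum(self.per_class_total, 1),
                np.nan,
            )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    selection_epoch: int = 30
    val_fraction: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.selection_epoch <= self.epochs:
            raise ValueError("selection_epoch must be <= epochs")


@dataclass
class TrainResult:
    history: pd.DataFrame
    model: MTLUNet
    selected_counts: MetricCounts
    checkpoint_path: Path | None = None


# ---------------------------------------------------------------------------
# losses and metrics
# ---------------------------------------------------------------------------


def seg_loss(seg_prob: np.ndarray, tool_mask: np.ndarray) -> float:
    """Mean per-pixel binary cross-entropy, in nats."""
    seg_prob = np.asarray(seg_prob, dtype=np.float64)
    tool_mask = np.asarray(tool_mask, dtype=np.float64)
    if seg_prob.shape != tool_mask.shape:
        raise ValueError(f"shape mismatch {seg_prob.shape} vs {tool_mask.shape}")
    p = np.clip(seg_prob, EPS, 1.0 - EPS)
    return float(-np.mean(tool_mask * np.log(p) + (1 - tool_mask) * np.log(1 - p)))


def cls_loss(cls_prob: np.ndarray, blood_label: int | np.ndarray) -> float:
    """Cross-entropy of the true class, in nats; mean over a batch."""
    cls_prob = np.atleast_2d(np.asarray(cls_prob, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(blood_label, dtype=int))
    if cls_prob.shape[0] != labels.shape[0]:
        raise ValueError("batch size mismatch between cls_prob and labels")
    sums = cls_prob.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-5) or np.any(cls_prob < -1e-12):
        raise ValueError("cls_prob rows must be normalised probability vectors")
    p_true = np.clip(cls_prob[np.arange(len(labels)), labels], EPS, 1.0)
    return float(-np.mean(np.log(p_true)))


def multi_task_loss(
    seg_prob: np.ndarray,
    tool_mask: np.ndarray,
    cls_prob: np.ndarray,
    blood_label: int | np.ndarray,
) -> LossBreakdown:
    """Unweighted sum of the two task losses, components reported separately."""
    s = seg_loss(seg_prob, tool_mask)
    c = cls_loss(cls_prob, blood_label)
    return LossBreakdown(seg_loss=s, cls_loss=c, total=s + c)


def classification_accuracy(counts: MetricCounts) -> float:
    """``correct_predictions / samples``; per-class values via the counts."""
    if counts.samples == 0:
        raise ValueError("accuracy undefined for zero samples")
    return counts.correct_predictions / counts.samples


def percent(fraction: float, decimals: int = 2) -> float:
    """Fraction as a percentage, rounded half-up to the reporting precision."""
    q = decimal.Decimal(10) ** -decimals
    return float(
        decimal.Decimal(str(fraction * 100)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def evaluate(
    model: MTLUNet,
    images: np.ndarray,
    labels: np.ndarray,
    batch_size: int = 32,
) -> MetricCounts:
    """Event-detection counts of a model on labelled frames."""
    n_classes = model.config.cls_classes
    correct = np.zeros(n_classes, dtype=int)
    total = np.zeros(n_classes, dtype=int)
    for start in range(0, len(images), batch_size):
        xb = images[start : start + batch_size]
        yb = labels[start : start + batch_size]
        _, cls_prob = model.forward(xb)
        pred = cls_prob.argmax(axis=1)
        for c in range(n_classes):
            sel = yb == c
            total[c] += int(sel.sum())
            correct[c] += int((pred[sel] == c).sum())
    return MetricCounts(
        correct_predictions=int(correct.sum()),
        samples=int(total.sum()),
        per_class_correct=correct,
        per_class_total=total,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _to_arrays(dataset: Sequence[FrameSample]):
    images = np.stack([s.image for s in dataset]).astype(np.float32)
    masks = np.stack([s.tool_mask for s in dataset]).astype(np.float32)
    labels = np.array([s.blood_label for s in dataset], dtype=int)
    return images, masks, labels


def _stratified_split(labels: np.ndarray, val_fraction: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * len(idx)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(train_idx), np.sort(val_idx)


def train(
    network: MTLUNet,
    dataset: Sequence[FrameSample],
    config: TrainConfig,
    checkpoint_path: str | Path | None = None,
    history_path: str | Path | None = None,
) -> TrainResult:
    """Train the multi-task network; returns history and the selected model.

    The dataset is split into train/validation (stratified by class,
    ``val_fraction`` held out). Each epoch records the mean training loss
    components and validation event-detection accuracy (overall and per
    class); the model state at ``selection_epoch`` is the one returned and
    optionally checkpointed. Fully reproducible given ``config.rng_seed``.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    images, masks, labels = _to_arrays(dataset)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0x7EA1]))
    train_idx, val_idx = _stratified_split(labels, config.val_fraction, rng)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("dataset too small for the requested validation split")

    opt = _nn.Adam(network.layers(), lr=config.learning_rate)
    rows = []
    selected_state: dict[str, np.ndarray] | None = None
    selected_counts: MetricCounts | None = None

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(train_idx)
        ep_seg, ep_cls, n_batches = 0.0, 0.0, 0
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            xb, mb, yb = images[sel], masks[sel], labels[sel]
            nb = len(sel)
            seg_p, cls_p = network.forward(xb, train=True)
            cache = network._cache
            # loss gradients on logits: mean-per-pixel BCE and mean CE
            dseg = ((seg_p - mb) / (mb.size))[..., None].astype(np.float32)
            onehot = np.eye(network.config.cls_classes, dtype=np.float32)[yb]
            dcls = ((cls_p - onehot) / nb).astype(np.float32)
            assert cache is not None
            network.backward(dseg, dcls)
            opt.step()
            opt.zero_grad()
            ep_seg += seg_loss(seg_p, mb)
            ep_cls += cls_loss(cls_p, yb)
            n_batches += 1
        counts = evaluate(network, images[val_idx], labels[val_idx])
        per_class = counts.per_class_accuracy()
        rows.append(
            {
                "epoch": epoch,
                "train_seg": ep_seg / n_batches,
                "train_cls": ep_cls / n_batches,
                "train_total": (ep_seg + ep_cls) / n_batches,
                "val_accuracy": classification_accuracy(counts),
                "val_acc_class0": per_class[0],
                "val_acc_class1": per_class[1],
            }
        )
        if epoch == config.selection_epoch:
            selected_state = copy.deepcopy(network.state_arrays())
            selected_counts = counts

    assert selected_state is not None and selected_counts is not None
    for name, arr in network.state_arrays().items():
        arr[...] = selected_state[name]

    history = pd.DataFrame(rows)
    ckpt = None
    if checkpoint_path is not None:
        ckpt = Path(checkpoint_path)
        network.save(ckpt)
    if history_path is not None:
        history.to_csv(history_path, index=False)
    return TrainResult(
        history=history,
        model=network,
        selected_counts=selected_counts,
        checkpoint_path=ckpt,
    )
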