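"""Training loop: per-pixel cross-entropy, Adam, best-model checkpointing.

The loss is sparse categorical cross-entropy on integer {0, 1} labels, the
optimiser Adam with initial learning rate 0.001, and the batch size 6.
Training runs a fixed number of epochs (no early stopping); each epoch
consumes one augmented variant of every training pair and is followed by
an un-augmented full-resolution evaluation of the validation set.  Weights
are persisted only when the checkpoint metric (validation loss by default,
switchable to validation accuracy) improves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rfilm.augment import AugmentConfig, epoch_stream
from rfilm.dataio import BinaryMask, FieldImage
from rfilm.metrics import confusion, metrics_table, miou_over_set, panel
from rfilm.model import ModifiedUNet, predict_mask, save_checkpoint
from rfilm.nn import cross_entropy_with_logits

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainingHistory", "train_model", "evaluate_model"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 6
    epochs: int = 55
    checkpoint_metric: str = "val_loss"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.checkpoint_metric not in ("val_loss", "val_accuracy"):
            raise ValueError("checkpoint_metric must be 'val_loss' or 'val_accuracy'")


@dataclass
class TrainingHistory:
    records: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _to_batch(pairs: list[tuple[FieldImage, BinaryMask]]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p[0].pixels for p in pairs]).astype(np.float32) / 255.0
    y = np.stack([p[1].labels for p in pairs]).astype(np.int64)
    return x, y


def _eval_loss(model: ModifiedUNet, pairs: list[tuple[FieldImage, BinaryMask]]) -> tuple[float, float]:
    losses, accs = [], []
    for img, msk in pairs:
        x, y = _to_batch([(img, msk)])
        logits = model.forward(x)
        loss, acc, _ = cross_entropy_with_logits(logits, y)
        losses.append(loss)
        accs.append(acc)
    return float(np.mean(losses)), float(np.mean(accs))


def train_model(
    model: ModifiedUNet,
    train_pairs: list[tuple[FieldImage, BinaryMask]],
    val_pairs: list[tuple[FieldImage, BinaryMask]],
    aug_cfg: AugmentConfig,
    cfg: TrainConfig,
    out_dir: str | Path = ".",
) -> tuple[TrainingHistory, Path]:
    """Train ``model`` in place; return the history and checkpoint path."""
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ckpt_path = out_dir / "best_model.npz"

    optimizer = model.make_optimizer(lr=cfg.learning_rate)
    stream = epoch_stream(train_pairs, aug_cfg, cfg.epochs)
    history = TrainingHistory()
    best_metric = np.inf if cfg.checkpoint_metric == "val_loss" else -np.inf

    for epoch in range(cfg.epochs):
        epoch_losses, epoch_accs = [], []
        batch: list[tuple[FieldImage, BinaryMask]] = []
        for pair in stream.epoch_iter(epoch):
            batch.append(pair)
            if len(batch) == cfg.batch_size:
                epoch_losses_acc = _train_batch(model, optimizer, batch, epoch)
                epoch_losses.append(epoch_losses_acc[0])
                epoch_accs.append(epoch_losses_acc[1])
                batch = []
        if batch:
            loss, acc = _train_batch(model, optimizer, batch, epoch)
            epoch_losses.append(loss)
            epoch_accs.append(acc)

        val_loss, val_acc = _eval_loss(model, val_pairs)
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "train_accuracy": float(np.mean(epoch_accs)),
            "val_loss": val_loss,
            "val_accuracy": val_acc,
        }
        history.records.append(record)
        metric = val_loss if cfg.checkpoint_metric == "val_loss" else val_acc
        improved = metric < best_metric if cfg.checkpoint_metric == "val_loss" else metric > best_metric
        if improved:
            best_metric = metric
            history.best_epoch = epoch
            save_checkpoint(model, ckpt_path)
            logger.info("epoch %d: %s improved to %.6f, checkpoint saved", epoch, cfg.checkpoint_metric, metric)
        logger.info(
            "epoch %d: train_loss=%.4f train_acc=%.4f val_loss=%.4f val_acc=%.4f",
            epoch, record["train_loss"], record["train_accuracy"], val_loss, val_acc,
        )

    logger.info("augmented samples streamed: %d (expected %d)", stream.count, stream.expected_total)
    return history, ckpt_path


def _train_batch(model, optimizer, batch, epoch) -> tuple[float, float]:
    x, y = _to_batch(batch)
    logits = model.forward(x)
    loss, acc, dlogits = cross_entropy_with_logits(logits, y)
    if not np.isfinite(loss):
        raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch}")
    model.backward(dlogits)
    optimizer.step(model.gradients())
    return loss, acc


_GROUP_KEYS = {"weather": lambda img: img.weather, "height_m": lambda img: img.height_m}


def evaluate_model(
    model: ModifiedUNet,
    pairs: list[tuple[FieldImage, BinaryMask]],
    group_by: str | None = None,
) -> pd.DataFrame:
    """Metric panel overall and per metadata group, in percent.

    ``group_by`` may be ``"weather"`` or ``"height_m"`` (read from each
    image's metadata).  The returned table has one row per group plus an
    ``overall`` row, with the full panel averaged per image and both MIOU
    aggregation modes.
    """
    if not pairs:
        raise ValueError("empty evaluation set")
    if group_by is not None and group_by not in _GROUP_KEYS:
        raise ValueError(f"unknown group_by key {group_by!r}; expected one of {sorted(_GROUP_KEYS)}")

    preds = [(predict_mask(model, img), msk) for img, msk in pairs]

    def summarise(indices: list[int], label) -> dict:
        panels = [panel(confusion(*preds[i])) for i in indices]
        sub = [preds[i] for i in indices]
        return {
            "group": "overall" if label is None else group_by,
            "value": "all" if label is None else label,
            "n_images": len(indices),
            "accuracy": float(np.mean([p.accuracy for p in panels])),
            "precision": float(np.mean([p.precision for p in panels])),
            "recall": float(np.mean([p.recall for p in panels])),
            "f1": float(np.mean([p.f1 for p in panels])),
            "miou_per_image": miou_over_set(sub, "per_image_mean"),
            "miou_pooled": miou_over_set(sub, "pooled"),
        }

    rows = []
    if group_by is not None:
        key = _GROUP_KEYS[group_by]
        values = sorted({key(img) for img, _ in pairs}, key=str)
        for v in values:
            idx = [i for i, (img, _) in enumerate(pairs) if key(img) == v]
            rows.append(summarise(idx, v))
    rows.append(summarise(list(range(len(pairs))), None))
    return metrics_table(rows)
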