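"""Training loop, checkpoint selection and mask prediction.

Training minimizes unweighted per-pixel cross-entropy over the three classes
with Adam.  Per-epoch train and validation losses are recorded; the
deployed model is the checkpoint with the lowest validation loss (earliest
epoch on ties).  Images are normalized per channel to [0, 1] and resized to
the configured square input size before entering the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .models import ModelConfig, build_model
from .nn import functional as F

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "preprocess_images",
    "preprocess_masks",
    "train_model",
    "select_best_checkpoint",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the training protocol:
    learning rate 0.00005, 100 epochs)."""

    learning_rate: float = 5e-5
    epochs: int = 100
    batch_size: int = 4
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class EpochRecord:
    """One epoch of history: losses plus the model state at epoch end."""

    epoch: int  # 1-based
    train_loss: float
    val_loss: float
    state: dict = field(repr=False, default_factory=dict)
    path: str | None = None


def _resize_array(arr: np.ndarray, size: int, resample) -> np.ndarray:
    if arr.shape[0] == size and arr.shape[1] == size:
        return arr
    return np.asarray(Image.fromarray(arr).resize((size, size), resample))


def preprocess_images(images, input_size: int) -> np.ndarray:
    """(n, H, W, 3) uint8 images -> (n, 3, S, S) float32 in [0, 1]."""
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValueError(f"expected (n, H, W, 3) images, got {images.shape}")
    out = np.stack(
        [
            _resize_array(img.astype(np.uint8), input_size, Image.BILINEAR)
            for img in images
        ]
    )
    return out.transpose(0, 3, 1, 2).astype(np.float32) / 255.0


def preprocess_masks(masks, input_size: int) -> np.ndarray:
    """(n, H, W) label masks -> (n, S, S) int64, nearest-neighbor resized."""
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    out = np.stack(
        [_resize_array(m.astype(np.uint8), input_size, Image.NEAREST) for m in masks]
    )
    return out.astype(np.int64)


def _epoch_loss(model, x, y, batch_size, optimizer=None, rng=None):
    n = len(x)
    order = np.arange(n)
    if rng is not None:
        rng.shuffle(order)
    losses, weights = [], []
    for start in range(0, n, batch_size):
        idx = order[start : start + batch_size]
        loss = F.cross_entropy(model(nn.Tensor(x[idx])), y[idx])
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        losses.append(float(loss.data))
        weights.append(len(idx))
    return float(np.average(losses, weights=weights))


def train_model(model, train_set, val_set, config: TrainConfig) -> list:
    """Train ``model`` on (images, masks) pairs; return per-epoch history.

    ``train_set``/``val_set`` are ``(images, masks)`` tuples with images
    (n, H, W, 3) uint8 and masks (n, H, W) in {0, 1, 2}.  Deterministic for
    a fixed ``config.seed``.  Raises on empty datasets; a non-finite loss
    aborts with a FloatingPointError naming the epoch.
    """
    input_size = model.config.input_size
    xs, ys = train_set
    xv, yv = val_set
    if len(xs) == 0 or len(xv) == 0:
        raise ValueError("train and validation sets must be non-empty")
    xs = preprocess_images(xs, input_size)
    ys = preprocess_masks(ys, input_size)
    xv = preprocess_images(xv, input_size)
    yv = preprocess_masks(yv, input_size)

    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    history = []
    for epoch in range(1, config.epochs + 1):
        model.train()
        try:
            train_loss = _epoch_loss(
                model, xs, ys, config.batch_size, optimizer=optimizer, rng=rng
            )
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch} "
                f"(lr={config.learning_rate}): {exc}"
            ) from exc
        model.eval()
        val_loss = _epoch_loss(model, xv, yv, config.batch_size)
        record = EpochRecord(
            epoch=epoch,
            train_loss=train_loss,
            val_loss=val_loss,
            state=model.state_dict(),
        )
        if ckpt_dir:
            record.path = str(ckpt_dir / f"epoch_{epoch:03d}.npz")
            save_checkpoint(record.path, model, record)
            pd.DataFrame(
                [
                    dict(epoch=r.epoch, train_loss=r.train_loss, val_loss=r.val_loss)
                    for r in history + [record]
                ]
            ).to_csv(ckpt_dir / "training_log.csv", index=False)
        history.append(record)
    return history


def select_best_checkpoint(history) -> EpochRecord:
    """Checkpoint with the lowest validation loss; ties go to the earliest."""
    history = list(history)
    if not history:
        raise ValueError("empty training history")
    return min(history, key=lambda r: (r.val_loss, r.epoch))


def predict_mask(model, image) -> np.ndarray:
    """Segment one image: per-pixel argmax over the 3 class scores.

    Ties break toward the lowest class index.  Returns a (S, S) uint8 mask
    with values in {0, 1, 2} at the model's input size.
    """
    x = preprocess_images(image, model.config.input_size)
    model.eval()
    logits = model(nn.Tensor(x))
    return logits.data.argmax(axis=1)[0].astype(np.uint8)


def save_checkpoint(path, model, record: EpochRecord):
    """Write model state plus config/epoch/losses to an .npz checkpoint."""
    meta = dict(
        architecture=model.config.architecture,
        input_size=model.config.input_size,
        num_classes=model.config.num_classes,
        width_multiplier=model.config.width_multiplier,
        atrous_rates=list(model.config.atrous_rates),
        output_stride=model.config.output_stride,
        epoch=record.epoch,
        train_loss=record.train_loss,
        val_loss=record.val_loss,
    )
    np.savez_compressed(
        path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **record.state,
    )


def load_checkpoint(path):
    """Rebuild a model from an .npz checkpoint; returns (model, meta)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = ModelConfig(
        architecture=meta["architecture"],
        input_size=meta["input_size"],
        num_classes=meta["num_classes"],
        width_multiplier=meta["width_multiplier"],
        atrous_rates=tuple(meta["atrous_rates"]),
        output_stride=meta["output_stride"],
    )
    model = build_model(config)
    model.load_state_dict(state)
    model.eval()
    return model, meta
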