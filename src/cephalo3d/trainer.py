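"""Dataset splitting, loss, optimization schedule and stopping rule.

The training recipe is fixed: stochastic gradient descent with momentum 0.9,
initial learning rate 1e-3, weight decay 5e-4, learning-rate reduction by 0.1
every 50 epochs, and early stopping armed from epoch 60 — training ends once
20 consecutive epochs pass without a new best validation loss, or at epoch
150.  Cases are split train:validation:test = 7:1:2 with a seeded shuffle.
The same hyperparameters apply to every modality; the scaled-down phantom
exercises override only the learning rate and epoch budget (see
docs/methods.md).

The loss is mean squared error on peak-normalized heatmaps (L1 available via
``loss="l1"``).  An optional per-sample mask restricts supervision to chosen
channels, which the 2D branch training uses to supervise only the landmark a
slice belongs to.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nn import SGD, Tensor

__all__ = [
    "TrainConfig",
    "TrainingDiverged",
    "split_dataset",
    "lr_schedule",
    "heatmap_loss",
    "should_stop",
    "stop_epoch",
    "train",
]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass
class TrainConfig:
    lr0: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 5e-4
    lr_factor: float = 0.1
    lr_step_epochs: int = 50
    max_epochs: int = 150
    patience: int = 20
    min_epochs: int = 60  # epoch from which the patience rule is armed
    split_ratios: tuple[float, float, float] = (7, 1, 2)
    batch_size: int = 1
    loss: str = "mse"  # or "l1"
    clip_norm: float | None = 10.0  # global gradient-norm clip, None disables
    seed: int = 0

    def lr(self, epoch: int) -> float:
        return lr_schedule(epoch, self.lr0, self.lr_factor, self.lr_step_epochs)


def split_dataset(case_ids: Sequence, ratios: tuple[float, float, float] = (7, 1, 2),
                  seed: int = 0) -> tuple[list, list, list]:
    """Disjoint covering train/val/test partition with rounded proportions.

    Validation and test sizes are the rounded proportions; the remainder goes
    to training (480 cases at 7:1:2 -> 336/48/96).  The shuffle is seeded so
    the split is reproducible.
    """
    ids = list(case_ids)
    if len(ids) < 10:
        raise ValueError(f"need at least 10 cases, got {len(ids)}")
    total = float(sum(ratios))
    n_val = round(len(ids) * ratios[1] / total)
    n_test = round(len(ids) * ratios[2] / total)
    n_train = len(ids) - n_val - n_test
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    return (shuffled[:n_train],
            shuffled[n_train:n_train + n_val],
            shuffled[n_train + n_val:])


def lr_schedule(epoch: int, lr0: float = 1e-3, factor: float = 0.1,
                step: int = 50) -> float:
    """Stepped decay: ``lr0 * factor ** floor(epoch / step)`` (epoch 0-based)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return lr0 * factor ** (epoch // step)


def heatmap_loss(pred: np.ndarray, target: np.ndarray, kind: str = "mse") -> float:
    """Scalar heatmap regression loss over all voxels/pixels and landmarks."""
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    d = pred.astype(np.float64) - target.astype(np.float64)
    return float(np.mean(d ** 2) if kind == "mse" else np.mean(np.abs(d)))


def should_stop(epoch: int, best_epoch: int, cfg: TrainConfig) -> bool:
    """Early-stop test after finishing 1-based ``epoch``.

    Armed from ``min_epochs``; triggers when ``patience`` epochs have passed
    without a new best validation loss.
    """
    return epoch >= cfg.min_epochs and (epoch - best_epoch) >= cfg.patience


def stop_epoch(val_losses: Sequence[float], cfg: TrainConfig | None = None) -> int:
    """The 1-based epoch at which training ends for a given validation trace.

    A strictly better (lower) loss resets the patience counter.  With a
    monotone improving trace this is ``max_epochs``; with the best value at
    epoch 45 and nothing better after, it is 65 (armed at 60, 45+20 >= 60).
    """
    cfg = cfg or TrainConfig()
    best, best_epoch = np.inf, 0
    for e, v in enumerate(val_losses, start=1):
        if v < best:
            best, best_epoch = v, e
        if should_stop(e, best_epoch, cfg):
            return e
        if e >= cfg.max_epochs:
            return cfg.max_epochs
    return min(len(val_losses), cfg.max_epochs)


def _epoch_pass(model, data, cfg, opt=None, rng=None) -> float:
    order = np.arange(len(data))
    if rng is not None:
        rng.shuffle(order)
    total = 0.0
    for i in order:
        x, target, mask = data[i]
        pred = model(Tensor(x))
        target = np.asarray(target, dtype=np.float32)
        loss = pred.mae(target, mask) if cfg.loss == "l1" else pred.mse(target, mask)
        lv = float(loss.data)
        if not np.isfinite(lv):
            raise TrainingDiverged(f"non-finite loss {lv} on sample {i}")
        if opt is not None:
            opt.zero_grad()
            loss.backward()
            opt.step()
        total += lv
    return total / max(len(data), 1)


def train(model, train_data, val_data, cfg: TrainConfig,
          progress: bool = False) -> dict:
    """Run the full schedule; return a history dict and restore best weights.

    ``train_data``/``val_data`` are sequences of ``(input, target, mask)``
    where ``input`` is ``(1, *spatial)``, ``target`` ``(L, *spatial)`` and
    ``mask`` broadcastable or None.  The model ends loaded with the weights of
    the best validation epoch.  History records per-epoch train/val loss and
    the learning rate actually applied.
    """
    rng = np.random.default_rng((cfg.seed, 0x7A))
    params = model.params()
    opt = SGD(params, lr=cfg.lr(0), momentum=cfg.momentum,
              weight_decay=cfg.weight_decay, clip_norm=cfg.clip_norm)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val, best_epoch = np.inf, 0
    best_weights = [p.data.copy() for p in params]
    for epoch in range(1, cfg.max_epochs + 1):
        opt.lr = cfg.lr(epoch - 1)
        tr = _epoch_pass(model, train_data, cfg, opt=opt, rng=rng)
        vl = _epoch_pass(model, val_data, cfg) if len(val_data) else tr
        history["train_loss"].append(tr)
        history["val_loss"].append(vl)
        history["lr"].append(opt.lr)
        if progress:
            print(f"epoch {epoch:3d}  lr {opt.lr:.2e}  train {tr:.3e}  val {vl:.3e}")
        if vl < best_val:
            best_val, best_epoch = vl, epoch
            best_weights = [p.data.copy() for p in params]
        if should_stop(epoch, best_epoch, cfg):
            break
    for p, w in zip(params, best_weights):
        p.data = w
    history["best_epoch"] = best_epoch
    history["best_val"] = float(best_val)
    history["stopped_epoch"] = epoch
    return history
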