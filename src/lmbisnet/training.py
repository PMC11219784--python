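"""Dice-loss training loop: Adam, plateau learning-rate halving, early stop.

The schedule follows the published recipe: initial learning rate 0.001,
a ceiling of 50 epochs, the learning rate halved after 7 consecutive
epochs without validation-dice improvement, and early stopping to avoid
overfitting. The best-validation weights are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .network import NetworkGraph
from .types import FundusSample, ValidationError

__all__ = [
    "TrainingConfig",
    "SchedulerState",
    "dice_loss",
    "dice_loss_grad",
    "lr_schedule_step",
    "train",
    "samples_to_arrays",
]

DICE_SMOOTH = 1.0


@dataclass
class TrainingConfig:
    initial_lr: float = 0.001
    max_epochs: int = 50
    plateau_patience: int = 7
    lr_factor: float = 0.5
    early_stop_patience: int = 15
    batch_size: int = 2
    seed: int = 0
    lr_floor: float = 1e-6

    def __post_init__(self):
        if not 0 < self.lr_factor < 1:
            raise ValidationError("lr_factor must lie in (0,1)")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValidationError("patiences must be >= 1")
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


def dice_loss(pred: np.ndarray, target: np.ndarray,
              smooth: float = DICE_SMOOTH) -> float:
    """Soft dice loss 1 - (2*sum(p*g)+eps) / (sum(p)+sum(g)+eps).

    ``pred`` holds vessel-class probabilities in [0,1]; ``target`` is the
    binary vessel mask of the same shape.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {target.shape}")
    if not np.isin(target, (0.0, 1.0)).all():
        raise ValidationError("target must be binary")
    inter = float((pred * target).sum())
    denom = float(pred.sum() + target.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def dice_loss_grad(pred: np.ndarray, target: np.ndarray,
                   smooth: float = DICE_SMOOTH) -> np.ndarray:
    """Analytic gradient of ``dice_loss`` w.r.t. the predictions."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    inter = (pred * target).sum()
    denom = pred.sum() + target.sum()
    num = 2.0 * inter + smooth
    den = denom + smooth
    return (num / den ** 2) - (2.0 * target / den)


@dataclass
class SchedulerState:
    """Plateau-halving learning-rate state (monitors validation dice)."""

    lr: float
    best_metric: float = -np.inf
    stale_epochs: int = 0
    patience: int = 7
    factor: float = 0.5
    floor: float = 1e-6
    history: list[float] = field(default_factory=list)


def lr_schedule_step(state: SchedulerState, epoch_metric: float) -> SchedulerState:
    """Advance one epoch: an improvement resets the stale counter; after
    ``patience`` consecutive stale epochs the learning rate is halved."""
    if state.lr <= 0:
        raise ValidationError("learning rate must be positive")
    if epoch_metric > state.best_metric:
        state.best_metric = epoch_metric
        state.stale_epochs = 0
    else:
        state.stale_epochs += 1
        if state.stale_epochs >= state.patience:
            state.lr = max(state.lr * state.factor, state.floor)
            state.stale_epochs = 0
    state.history.append(state.lr)
    return state


def samples_to_arrays(samples: list[FundusSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (N,3,H,W) images and (N,H,W) vessel masks."""
    x = np.stack([s.image.transpose(2, 0, 1) for s in samples]).astype(np.float32)
    y = np.stack([s.vessel_mask for s in samples]).astype(np.float32)
    return x, y


def _val_dice(model, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    losses = []
    for i in range(0, len(x), batch):
        probs = model.forward(x[i:i + batch], training=False)
        losses.append(dice_loss(probs[:, 1], y[i:i + batch]))
    return 1.0 - float(np.mean(losses))


def train(graph: NetworkGraph, train_samples: list[FundusSample],
          val_samples: list[FundusSample], config: TrainingConfig,
          max_steps: int | None = None,
          stop_at_val_dice: float | None = None) -> tuple[dict, list[dict]]:
    """Train a built network; returns (best weights, per-epoch history).

    History rows carry epoch, mean train loss, validation dice and the
    learning rate in force. Data order, initial weights and everything
    stochastic derive from ``config.seed``. ``max_steps`` optionally caps
    total optimiser steps and ``stop_at_val_dice`` ends training once the
    validation dice reaches a target (both for smoke tests).
    """
    if not train_samples or not val_samples:
        raise ValidationError("train and validation sets must be nonempty")
    model = graph.model
    xtr, ytr = samples_to_arrays(train_samples)
    xva, yva = samples_to_arrays(val_samples)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.initial_lr)
    sched = SchedulerState(lr=config.initial_lr, patience=config.plateau_patience,
                           factor=config.lr_factor, floor=config.lr_floor)
    best_state = model.get_state()
    best_dice = -np.inf
    stale = 0
    history: list[dict] = []
    steps = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(xtr))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            model.zero_grad()
            probs = model.forward(xtr[idx], training=True)
            loss = dice_loss(probs[:, 1], ytr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            gp = dice_loss_grad(probs[:, 1], ytr[idx]).astype(model.dtype)
            dprobs = np.zeros_like(probs)
            dprobs[:, 1] = gp
            model.backward(dprobs)
            opt.lr = sched.lr
            opt.step()
            epoch_losses.append(loss)
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break
        vdice = _val_dice(model, xva, yva, config.batch_size)
        lr_schedule_step(sched, vdice)
        history.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                        "val_dice": vdice, "lr": sched.lr})
        if vdice > best_dice:
            best_dice = vdice
            best_state = model.get_state()
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break
        if max_steps is not None and steps >= max_steps:
            break
        if stop_at_val_dice is not None and vdice >= stop_at_val_dice:
            break
    model.set_state(best_state)
    return best_state, history
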