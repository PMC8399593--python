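"""Training regime: SGD with momentum, per-pixel cross-entropy, patience.

The optimizer is stochastic gradient descent with momentum; the loss is
the mean per-pixel (optionally class-weighted) cross-entropy.  Validation
loss is evaluated after every ``validation_frequency`` mini-batch
iterations, and a *cumulative* patience counter tracks how many times it
failed to improve on the running minimum: each evaluation that is greater
than or equal to the smallest loss seen so far increments the counter
(cumulatively — a later improvement does not reset it), and training
stops when the counter reaches ``validation_patience``.  The returned
parameters are those from the iteration with the minimum validation loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .nn.layers import weighted_ce_logit_grad
from .nn.model import SegmentationNetwork

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "EarlyStopping",
    "pixel_cross_entropy",
    "sgdm_step",
    "train",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters; defaults are the tuned values of the study design.

    ``class_weights`` rescales the per-pixel loss by true class
    (NotNeo, Neo); the default (1, 1) applies no imbalance correction.
    """

    mini_batch_size: int = 7
    max_epochs: int = 10
    momentum: float = 0.9
    initial_learning_rate: float = 5e-4
    validation_patience: int = 4
    validation_frequency: int = 1
    seed: int = 0
    class_weights: tuple[float, float] = (1.0, 1.0)

    def validate(self) -> None:
        if self.mini_batch_size < 1 or self.max_epochs < 1 or self.validation_patience < 1:
            raise ValueError("counts must be positive")
        if self.validation_frequency < 1:
            raise ValueError("validation_frequency must be >= 1")
        if self.initial_learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")


@dataclass
class TrainingHistory:
    """Loss traces and the stopping outcome of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stop_reason: str = "max_epochs"  # "patience_exhausted" | "max_epochs"
    best_iteration: int = -1  # index into val_loss

    def to_csv(self) -> str:
        lines = ["iteration,train_loss,val_loss"]
        for i, (t, v) in enumerate(zip(self.train_loss, self.val_loss)):
            lines.append(f"{i},{t:.6f},{v:.6f}")
        lines.append(f"# stop_reason={self.stop_reason} best_iteration={self.best_iteration}")
        return "\n".join(lines) + "\n"


def pixel_cross_entropy(
    probs: np.ndarray,
    truth: np.ndarray,
    class_weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Mean over pixels of ``-w_c log p(true class)``.

    probs: (..., 2, H, W) class probabilities; truth: (..., H, W) with
    values in {0, 1} (or {0, 255}, which is collapsed to {0, 1}).
    Probabilities are clamped below at 1e-12 before the logarithm.
    """
    probs = np.asarray(probs, dtype=float)
    truth = np.asarray(truth)
    if truth.max(initial=0) > 1:
        truth = (truth > 0).astype(np.int64)
    if probs.ndim == 3:
        probs = probs[None]
    if truth.ndim == 2:
        truth = truth[None]
    if probs.shape[0] != truth.shape[0] or probs.shape[2:] != truth.shape[1:]:
        raise ValueError(
            f"probabilities {probs.shape} and truth {truth.shape} are misaligned"
        )
    idx = np.indices(truth.shape)
    p_true = probs[idx[0], truth, idx[1], idx[2]]
    w = np.where(truth == 1, class_weights[1], class_weights[0])
    return float(np.mean(-w * np.log(np.maximum(p_true, 1e-12))))


def sgdm_step(params, grads, velocity, learning_rate: float, momentum: float):
    """One momentum update, in place, over nested parameter dictionaries.

    velocity <- momentum * velocity - learning_rate * gradient;
    parameter <- parameter + velocity.  Entries without a gradient (e.g.
    batch-norm running statistics) are left untouched.
    """
    for layer, lgrads in grads.items():
        for key, g in lgrads.items():
            p = params[layer][key]
            if p.shape != g.shape:
                raise ValueError(f"shape mismatch for {layer}/{key}: {p.shape} vs {g.shape}")
            v = velocity.setdefault(layer, {}).setdefault(key, np.zeros_like(p))
            v *= momentum
            v -= learning_rate * g
            p += v
    return params, velocity


class EarlyStopping:
    """Cumulative-patience stopping rule on a validation-loss stream.

    ``update`` returns True when training should stop: the counter
    increments whenever the new loss is >= the running minimum and is
    never reset by later improvements; it exhausts at ``patience``.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.counter = 0
        self.best_loss = np.inf
        self.best_index = -1
        self.n_seen = 0

    def update(self, loss: float) -> bool:
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_index = self.n_seen
        else:
            self.counter += 1
        self.n_seen += 1
        return self.counter >= self.patience


def _batch(arrays: list[np.ndarray]) -> np.ndarray:
    return np.stack([SegmentationNetwork.prepare_input(a)[0] for a in arrays])


def _mask_batch(masks: list[np.ndarray]) -> np.ndarray:
    return np.stack([(np.asarray(m) > 0).astype(np.int64) for m in masks])


def evaluate_loss(
    model: SegmentationNetwork,
    patches: list[np.ndarray],
    masks: list[np.ndarray],
    class_weights=(1.0, 1.0),
    batch_size: int = 8,
) -> float:
    """Mean cross-entropy over a set, pixel-weighted across all patches."""
    total, n_pix = 0.0, 0
    for i in range(0, len(patches), batch_size):
        xb = _batch(patches[i : i + batch_size])
        yb = _mask_batch(masks[i : i + batch_size])
        probs, _ = model.forward(xb, training=False)
        m = yb.size
        total += pixel_cross_entropy(probs, yb, class_weights) * m
        n_pix += m
    return total / n_pix


def train(
    model: SegmentationNetwork,
    train_patches: list[np.ndarray],
    train_masks: list[np.ndarray],
    val_patches: list[np.ndarray],
    val_masks: list[np.ndarray],
    config: TrainingConfig,
    log=None,
) -> tuple[SegmentationNetwork, TrainingHistory]:
    """Mini-batch SGDM training with validation-patience early stopping.

    Data order is reshuffled once per epoch under the run seed; the final
    short mini-batch of an epoch is kept.  On return the model carries the
    parameters of the best validation iteration.
    """
    config.validate()
    if not train_patches or not val_patches:
        raise ValueError("training and validation sets must be non-empty")
    if len(train_patches) != len(train_masks):
        raise ValueError("training patches and masks are misaligned")

    rng = np.random.default_rng(config.seed)
    velocity: dict = {}
    history = TrainingHistory()
    stopper = EarlyStopping(config.validation_patience)
    best_params = model.copy_params()
    iteration = 0
    stop = False

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_patches))
        for start in range(0, len(order), config.mini_batch_size):
            sel = order[start : start + config.mini_batch_size]
            xb = _batch([train_patches[i] for i in sel])
            yb = _mask_batch([train_masks[i] for i in sel])
            probs, caches = model.forward(xb, training=True)
            loss = pixel_cross_entropy(probs, yb, config.class_weights)
            dlogits = weighted_ce_logit_grad(probs, yb, config.class_weights)
            grads = model.backward(dlogits, caches)
            sgdm_step(
                model.params, grads, velocity,
                config.initial_learning_rate, config.momentum,
            )
            history.train_loss.append(loss)

            if iteration % config.validation_frequency == 0:
                vloss = evaluate_loss(model, val_patches, val_masks, config.class_weights)
            else:
                vloss = history.val_loss[-1] if history.val_loss else np.inf
            history.val_loss.append(vloss)
            improved = vloss < stopper.best_loss
            should_stop = stopper.update(vloss)
            if improved:
                best_params = model.copy_params()
            if log is not None:
                log(
                    f"iteration={iteration} epoch={epoch} train_loss={loss:.6f} "
                    f"val_loss={vloss:.6f} patience={stopper.counter}"
                )
            iteration += 1
            if should_stop:
                history.stop_reason = "patience_exhausted"
                stop = True
                break
        if stop:
            break

    history.best_iteration = stopper.best_index
    model.set_params(best_params)
    return model, history
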