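"""Shared mini-batch training loop with validation-loss early stopping.

The loop is used by both the autoencoder (squared-error reconstruction) and
the classifier (cross-entropy).  Early stopping keeps the weights of the best
validation epoch: training halts once the validation loss has failed to
improve for ``patience`` consecutive epochs, and the best-epoch weights are
restored before returning.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .layers import Sequential
from .optim import Adam

# loss_fn(net_output, target) -> (scalar loss, gradient wrt net_output)
LossFn = Callable[[np.ndarray, np.ndarray], tuple[float, np.ndarray]]


def evaluate_loss(net: Sequential, x: np.ndarray, t: np.ndarray,
                  loss_fn: LossFn, batch_size: int) -> float:
    """Sample-weighted mean loss of ``net`` over ``(x, t)``."""
    total, m = 0.0, x.shape[0]
    for start in range(0, m, batch_size):
        xb = x[start:start + batch_size]
        tb = t[start:start + batch_size]
        loss, _ = loss_fn(net.forward(xb), tb)
        total += loss * xb.shape[0]
    return total / m


def fit_network(
    net: Sequential,
    x_train: np.ndarray,
    t_train: np.ndarray,
    x_val: np.ndarray,
    t_val: np.ndarray,
    loss_fn: LossFn,
    *,
    learning_rate: float = 1e-3,
    batch_size: int = 32,
    max_epochs: int = 100,
    patience: int = 10,
    rng: np.random.Generator,
) -> dict[str, list[float]]:
    """Train ``net`` in place; return per-epoch train/validation loss history.

    The returned history has keys ``train_loss`` and ``val_loss`` (one entry
    per completed epoch) and ``best_epoch`` (1-based index of the epoch whose
    weights were kept).
    """
    optimizer = Adam(net.params(), learning_rate=learning_rate)
    m = x_train.shape[0]
    batch_size = min(batch_size, m)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = net.get_state()
    best_epoch = 0
    bad_epochs = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(m)
        epoch_loss = 0.0
        for start in range(0, m, batch_size):
            idx = order[start:start + batch_size]
            out = net.forward(x_train[idx])
            loss, dout = loss_fn(out, t_train[idx])
            net.backward(dout)
            optimizer.step(net.grads())
            epoch_loss += loss * idx.size
        history["train_loss"].append(epoch_loss / m)
        val_loss = evaluate_loss(net, x_val, t_val, loss_fn, batch_size)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.get_state()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break
    net.set_state(best_state)
    history["best_epoch"] = best_epoch
    return history


def squared_error_loss(x_hat: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean over samples of half the squared Euclidean reconstruction error."""
    diff = x_hat - x
    m = x.shape[0]
    loss = 0.5 * float(np.sum(diff.astype(np.float64) ** 2)) / m
    return loss, diff / m


def softmax_cross_entropy_loss(logits: np.ndarray,
                               onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Softmax + mean cross-entropy with gradient wrt the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    m = logits.shape[0]
    loss = -float(np.sum(onehot * np.log(np.maximum(p, 1e-12)))) / m
    return loss, (p - onehot) / m
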