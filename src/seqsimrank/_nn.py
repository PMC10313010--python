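"""Shared pieces for the neural matchers: init, MLP stacks, training loop."""

from __future__ import annotations

import numpy as np

from ._autograd import Adam, Tensor, bce_loss

__all__ = ["glorot", "make_mlp", "apply_mlp", "train_loop", "DivergenceError"]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def glorot(rng, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def make_mlp(rng, sizes) -> list:
    """Parameter tensors [(W, b), ...] for a dense stack."""
    layers = []
    for d_in, d_out in zip(sizes[:-1], sizes[1:]):
        W = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        b = Tensor(np.zeros(d_out), requires_grad=True)
        layers.append((W, b))
    return layers


def apply_mlp(x: Tensor, layers, activation="tanh", last_linear=False) -> Tensor:
    act = {"tanh": Tensor.tanh, "relu": Tensor.relu, "sigmoid": Tensor.sigmoid}[activation]
    for k, (W, b) in enumerate(layers):
        x = x @ W + b
        if not (last_linear and k == len(layers) - 1):
            x = act(x)
    return x


def train_loop(
    forward,
    params,
    n_train: int,
    targets: np.ndarray,
    *,
    validate=None,
    epochs: int = 50,
    batch_size: int = 32,
    lr: float = 1e-2,
    patience: int = 10,
    seed: int = 0,
):
    """Seeded minibatch Adam training with early stopping.

    forward(indices) must return the predicted-probability Tensor for
    the given training indices. validate() (optional) returns a scalar
    to maximize; the best parameter snapshot is restored at the end.
    Returns the per-epoch mean training loss.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(params, lr=lr)
    best_value, best_state, since_best = -np.inf, None, 0
    history = []
    for _epoch in range(epochs):
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, batch_size):
            idx = order[start : start + batch_size]
            opt.zero_grad()
            prob = forward(idx)
            loss = bce_loss(prob, targets[idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    "training loss diverged (non-finite); try a smaller learning rate"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if validate is not None:
            value = validate()
            if value > best_value:
                best_value, since_best = value, 0
                best_state = [p.data.copy() for p in params]
            else:
                since_best += 1
                if since_best >= patience:
                    break
    if best_state is not None:
        for p, saved in zip(params, best_state):
            p.data = saved
    return history
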