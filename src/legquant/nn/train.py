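"""Adam optimizer and a generic mini-batch training loop."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "fit"]


class Adam:
    def __init__(self, model, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(v) for name, v, _ in model.params()}
        self.v = {name: np.zeros_like(v) for name, v, _ in model.params()}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for name, val, grad in self.model.params():
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad**2
            val -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def fit(
    model,
    X: np.ndarray,
    Y: np.ndarray,
    loss_fn,
    epochs: int = 5,
    batch_size: int = 16,
    lr: float = 1e-3,
    seed: int = 0,
    callback=None,
) -> list[float]:
    """Train ``model`` on arrays ``X``/``Y``; returns per-epoch mean loss.

    Deterministic: shuffling comes from a generator seeded with
    ``seed`` and all arithmetic is plain numpy.
    """
    rng = np.random.default_rng(seed)
    n = len(X)
    opt = Adam(model, lr=lr)
    history = []
    model.set_train(True)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = np.ascontiguousarray(X[idx], dtype=np.float32)
            yb = Y[idx]
            out = model.forward(xb)
            loss, dout = loss_fn(out, yb)
            model.backward(dout)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if callback is not None:
            callback(epoch, history[-1])
    model.set_train(False)
    return history
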