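"""Minimal fully connected network with externally supplied dropout masks.

The benchmark experiments need a feed-forward net whose hidden activations
can be zeroed by an arbitrary per-iteration mask computed outside the
network (fiber-driven or Bernoulli).  This module implements exactly that:
dense layers with ReLU hidden activations, mean-squared-error or
softmax-cross-entropy loss, and an Adam optimizer.  Dropout is applied by
multiplying each hidden layer's post-activation output by a binary keep
mask, so masked units output exactly zero and receive zero gradient.

Weight initialization follows the common uniform fan-in rule
``U(-1/sqrt(fan_in), 1/sqrt(fan_in))`` for both weights and biases.
"""

from __future__ import annotations

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLP:
    """Dense ReLU network trained with Adam.

    Parameters
    ----------
    layer_sizes
        Widths ``(n_in, h_1, ..., h_k, n_out)``; hidden layers use ReLU,
        the output layer is linear (regression) or logits (classification).
    task
        ``"regression"`` (mean squared error) or ``"classification"``
        (softmax cross-entropy).
    lr, betas, eps
        Adam hyperparameters.
    seed
        Seeds weight initialization.
    """

    def __init__(
        self,
        layer_sizes,
        task: str = "regression",
        lr: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        seed=None,
    ) -> None:
        if task not in ("regression", "classification"):
            raise ValueError(f"unknown task {task!r}")
        if len(layer_sizes) < 2:
            raise ValueError("need at least an input and an output layer")
        self.layer_sizes = tuple(int(w) for w in layer_sizes)
        self.task = task
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(rng.uniform(-bound, bound, size=fan_out))
        self._m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._t = 0

    @property
    def n_hidden(self) -> int:
        return len(self.layer_sizes) - 2

    def forward(self, x: np.ndarray, keep_masks=None):
        """Forward pass; returns (output, cache of post-mask activations).

        ``keep_masks`` is a sequence with one entry per hidden layer: a
        float vector of 0/1 keep indicators (optionally rescaled), or None
        for no dropout on that layer.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if keep_masks is not None and len(keep_masks) != self.n_hidden:
            raise ValueError(
                f"expected {self.n_hidden} masks (one per hidden layer), "
                f"got {len(keep_masks)}"
            )
        acts = [x]
        h = x
        for li in range(self.n_hidden):
            h = relu(h @ self.weights[li] + self.biases[li])
            if keep_masks is not None and keep_masks[li] is not None:
                h = h * keep_masks[li]
            acts.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        return out, acts

    def predict(self, x: np.ndarray) -> np.ndarray:
        out, _ = self.forward(x)
        return out

    def _loss_and_delta(self, out: np.ndarray, y: np.ndarray):
        n = out.shape[0]
        if self.task == "regression":
            y = np.atleast_2d(np.asarray(y, dtype=float))
            diff = out - y
            loss = float(np.mean(diff**2))
            delta = 2.0 * diff / diff.size
        else:
            y = np.asarray(y, dtype=int)
            p = softmax(out)
            loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-300)))
            delta = p.copy()
            delta[np.arange(n), y] -= 1.0
            delta /= n
        return loss, delta

    def evaluate(self, x: np.ndarray, y: np.ndarray):
        """Loss (and accuracy, for classification) with no dropout applied."""
        out, _ = self.forward(x)
        loss, _ = self._loss_and_delta(out, y)
        if self.task == "classification":
            acc = float(np.mean(out.argmax(axis=1) == np.asarray(y, dtype=int)))
            return loss, acc
        return loss

    def gradients(self, x: np.ndarray, y: np.ndarray, keep_masks=None):
        """Loss and parameter gradients for one (masked) training batch."""
        out, acts = self.forward(x, keep_masks)
        loss, delta = self._loss_and_delta(out, y)
        grads_w = [np.empty(0)] * len(self.weights)
        grads_b = [np.empty(0)] * len(self.biases)
        grads_w[-1] = acts[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        for li in range(self.n_hidden - 1, -1, -1):
            delta = delta @ self.weights[li + 1].T
            # ReLU derivative; the post-mask activation is zero wherever the
            # unit was masked or inactive, so masked units get zero gradient.
            delta = delta * (acts[li + 1] > 0.0)
            if keep_masks is not None and keep_masks[li] is not None:
                delta = delta * np.asarray(keep_masks[li], dtype=float)
            grads_w[li] = acts[li].T @ delta
            grads_b[li] = delta.sum(axis=0)
        return loss, grads_w, grads_b

    def train_step(self, x: np.ndarray, y: np.ndarray, keep_masks=None) -> float:
        """One Adam update on a mini-batch; returns the batch loss."""
        loss, grads_w, grads_b = self.gradients(x, y, keep_masks)
        self._t += 1
        params = self.weights + self.biases
        grads = grads_w + grads_b
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
        return loss
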