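"""A compact feed-forward network on NumPy.

Architecture: input -> [linear(hidden) + ReLU + dropout] x L -> linear(out)
-> softmax or sigmoid. Losses: categorical cross-entropy with optional
per-example weights, or (element-mean) binary cross-entropy. Optimizer: Adam.
Everything is seeded and single-threaded, so training is bit-reproducible on
one device.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def categorical_cross_entropy(p, y, weights=None) -> float:
    """Mean over examples of -w * log p[true]; y is one-hot."""
    logp = np.log(np.clip(p, _EPS, 1.0))
    per_example = -(y * logp).sum(axis=1)
    if weights is not None:
        per_example = per_example * weights
    return float(per_example.mean())

def binary_cross_entropy(p, y) -> float:
    """Mean over examples and labels of the elementwise BCE."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


class MLP:
    """Weights + forward/backward passes; no training loop (see models)."""

    def __init__(self, layer_sizes: list[int], final_activation: str,
                 dropout_rate: float, seed: int):
        if final_activation not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown final activation {final_activation!r}")
        self.layer_sizes = list(layer_sizes)
        self.final_activation = final_activation
        self.dropout_rate = float(dropout_rate)
        rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            # He initialization, appropriate for ReLU hidden units;
            # float32 throughout (deterministic and ~2-4x faster than float64)
            self.W.append(
                rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
                .astype(np.float32)
            )
            self.b.append(np.zeros(n_out, dtype=np.float32))
        self._adam_state = None

    # -- forward -----------------------------------------------------------

    def forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        """Return (probabilities, cache). Dropout is active iff *rng* given."""
        a = X.astype(np.float32, copy=False)
        cache = {"a": [a], "mask": []}
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if i < n_layers - 1:
                a = np.maximum(z, 0.0)
                if rng is not None and self.dropout_rate > 0:
                    keep = np.float32(1.0 - self.dropout_rate)
                    mask = (
                        rng.random(a.shape, dtype=np.float32) < keep
                    ).astype(np.float32) / keep
                    a = a * mask
                    cache["mask"].append(mask)
                else:
                    cache["mask"].append(None)
                cache["a"].append(a)
            else:
                p = softmax(z) if self.final_activation == "softmax" \
                    else sigmoid(z)
        cache["p"] = p
        return p, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    # -- backward ----------------------------------------------------------

    def _output_delta(self, p, y, loss: str, weights):
        """dL/dz at the output layer, L averaged as in the loss functions."""
        n = p.shape[0]
        if loss == "cce" and self.final_activation == "softmax":
            delta = (p - y) / n
            if weights is not None:
                delta = delta * weights[:, None]
            return delta
        if loss == "bce" and self.final_activation == "sigmoid":
            return (p - y) / y.size
        if loss == "bce" and self.final_activation == "softmax":
            # chain rule through the softmax for an elementwise BCE
            pc = np.clip(p, _EPS, 1.0 - _EPS)
            g = (pc - y) / (pc * (1.0 - pc)) / y.size  # dL/dp
            return p * (g - (g * p).sum(axis=1, keepdims=True))
        raise ValueError(
            f"unsupported loss/activation pair: {loss}/{self.final_activation}"
        )

    def gradients(self, cache, y, loss: str, weights=None):
        delta = self._output_delta(cache["p"], y, loss, weights)
        grads_W, grads_b = [], []
        for i in range(len(self.W) - 1, -1, -1):
            a_prev = cache["a"][i]
            grads_W.append(a_prev.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = delta @ self.W[i].T
                mask = cache["mask"][i - 1]
                if mask is not None:
                    delta = delta * mask
                delta = delta * (cache["a"][i] > 0)
        return grads_W[::-1], grads_b[::-1]

    # -- Adam ---------------------------------------------------------------

    def adam_step(self, grads_W, grads_b, lr: float,
                  beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "mW": [np.zeros_like(W) for W in self.W],
                "vW": [np.zeros_like(W) for W in self.W],
                "mb": [np.zeros_like(b) for b in self.b],
                "vb": [np.zeros_like(b) for b in self.b],
            }
        s = self._adam_state
        s["t"] += 1
        t = s["t"]
        for i in range(len(self.W)):
            for params, grads, m, v in (
                (self.W, grads_W, s["mW"], s["vW"]),
                (self.b, grads_b, s["mb"], s["vb"]),
            ):
                m[i] = beta1 * m[i] + (1 - beta1) * grads[i]
                v[i] = beta2 * v[i] + (1 - beta2) * grads[i] ** 2
                m_hat = m[i] / (1 - beta1**t)
                v_hat = v[i] / (1 - beta2**t)
                params[i] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # -- (de)serialization ---------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    def set_weights(self, arrays: dict[str, np.ndarray]) -> None:
        for i in range(len(self.W)):
            W, b = arrays[f"W{i}"], arrays[f"b{i}"]
            if W.shape != self.W[i].shape or b.shape != self.b[i].shape:
                raise ValueError(
                    f"weight shape mismatch at layer {i}: "
                    f"{W.shape} vs {self.W[i].shape}"
                )
            self.W[i] = W.astype(np.float32)
            self.b[i] = b.astype(np.float32)
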