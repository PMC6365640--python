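"""Minimal fully-connected network engine (numpy) with Adam.

All networks in this package — the expert-action screening nets, the
Q-network/target-network pair and the reward-prediction net — are small
feed-forward MLPs (two hidden layers, tens of units).  The engine keeps
weights as plain numpy arrays so the Q-learning soft target update
theta' <- tau*theta + (1-tau)*theta' is a direct array operation, and every
source of randomness (initialization, shuffling, mini-batch sampling) flows
from an explicit seeded generator, making training runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MLPSpec", "MLP", "Adam", "softmax", "soft_update_arrays"]


@dataclass(frozen=True)
class MLPSpec:
    """Architecture of a fully-connected network."""

    input_dim: int
    hidden_dims: tuple[int, ...]
    output_dim: int
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.input_dim <= 0 or self.output_dim <= 0:
            raise ValueError("input_dim and output_dim must be positive")
        if any(h <= 0 for h in self.hidden_dims):
            raise ValueError("hidden dimensions must be positive")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unsupported activation {self.activation!r}")

    @property
    def layer_dims(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden_dims, self.output_dim)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MLP:
    """Feed-forward network with ReLU/tanh hidden layers and a linear head."""

    def __init__(self, spec: MLPSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(seed)
        dims = spec.layer_dims
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims, dims[1:]):
            # He initialization, suited to ReLU-family activations
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- parameter plumbing -------------------------------------------------

    @property
    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def copy_weights_from(self, other: "MLP") -> None:
        if other.spec != self.spec:
            raise ValueError("network specs differ")
        self.weights = [w.copy() for w in other.weights]
        self.biases = [b.copy() for b in other.biases]

    def clone(self) -> "MLP":
        twin = MLP(self.spec, seed=0)
        twin.copy_weights_from(self)
        return twin

    # -- forward / backward -------------------------------------------------

    def _act(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) if self.spec.activation == "relu" else np.tanh(z)

    def _act_grad(self, z: np.ndarray, a: np.ndarray) -> np.ndarray:
        return (z > 0).astype(float) if self.spec.activation == "relu" else 1.0 - a * a

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list, list]:
        """Return (output, pre-activations, activations) for backprop."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pre, acts = [], [X]
        h = X
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            pre.append(z)
            h = z if i == n_layers - 1 else self._act(z)
            acts.append(h)
        return h, pre, acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _, _ = self.forward(X)
        return out

    def backward(self, d_out: np.ndarray, pre: list, acts: list) -> list[np.ndarray]:
        """Gradients of the loss w.r.t. all parameters, given dL/d(output)."""
        grads_w: list[np.ndarray] = [np.empty(0)] * len(self.weights)
        grads_b: list[np.ndarray] = [np.empty(0)] * len(self.biases)
        delta = d_out
        for i in range(len(self.weights) - 1, -1, -1):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * self._act_grad(pre[i - 1], acts[i])
        return grads_w + grads_b


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: Sequence[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def soft_update_arrays(theta: Sequence[np.ndarray], theta_prime: Sequence[np.ndarray],
                       tau: float) -> list[np.ndarray]:
    """Elementwise theta' <- tau*theta + (1-tau)*theta', updated in place."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    if len(theta) != len(theta_prime):
        raise ValueError("parameter lists differ in length")
    for src, dst in zip(theta, theta_prime):
        if src.shape != dst.shape:
            raise ValueError(f"shape mismatch {src.shape} vs {dst.shape}")
        dst *= 1.0 - tau
        dst += tau * src
    return list(theta_prime)
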