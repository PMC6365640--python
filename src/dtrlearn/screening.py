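"""Supervised prediction of expert treatment choices and top-N action screening.

A screening net is a multiclass MLP trained by behavior cloning: given the
encoded patient state it predicts the probability that the treating physician
would choose each drug combination.  Downstream, only the N most likely
expert actions are admissible for the Q-network's recommendation — actions
that experts essentially never take in a given state have unreliable value
estimates and are screened out.

Default architectures follow the registry deployment: screening nets
state_dim -> 16 -> 32 -> K; the initial-treatment net takes a 9-dimensional
input with hidden layers 16 and 32 (output 145 for conditioning, 127 for
GVHD prophylaxis).  Training uses Adam at learning rate 1e-4 with softmax
cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .nn import MLP, Adam, MLPSpec, softmax
from .registry import ActionCodec, Hyperparameters, StateVector

__all__ = [
    "MLPSpec",
    "ExpertModel",
    "screening_spec",
    "train_expert_predictor",
    "predict_action_probabilities",
    "top_n_accuracy",
    "screen_actions",
]

Example = tuple[StateVector, int]


def screening_spec(input_dim: int, n_actions: int,
                   hidden: tuple[int, int] = (16, 32)) -> MLPSpec:
    """Default screening-net architecture: input -> 16 -> 32 -> K."""
    return MLPSpec(input_dim=input_dim, hidden_dims=hidden, output_dim=n_actions)


@dataclass
class ExpertModel:
    """A trained expert-action predictor."""

    net: MLP
    codec: Optional[ActionCodec]
    training_log: list[float] = field(default_factory=list)

    @property
    def spec(self) -> MLPSpec:
        return self.net.spec

    @property
    def n_actions(self) -> int:
        return self.net.spec.output_dim

    def probabilities(self, states: np.ndarray) -> np.ndarray:
        return softmax(self.net.predict(np.atleast_2d(states)))


def _to_arrays(examples: Sequence[Example], input_dim: int, n_actions: int):
    X = np.empty((len(examples), input_dim))
    y = np.empty(len(examples), dtype=int)
    for i, (state, label) in enumerate(examples):
        v = state.values if isinstance(state, StateVector) else np.asarray(state, float)
        if v.shape != (input_dim,):
            raise ValueError(f"state has length {v.shape}, expected ({input_dim},)")
        if not 0 <= int(label) < n_actions:
            raise ValueError(f"action index {label} outside [0, {n_actions})")
        X[i] = v
        y[i] = int(label)
    return X, y


def train_expert_predictor(
    examples: Sequence[Example],
    spec: MLPSpec,
    hyper: Optional[Hyperparameters] = None,
    validation_fraction: float = 0.1,
    patience: int = 20,
) -> ExpertModel:
    """Behavior cloning: fit a softmax MLP to (state, expert action) pairs.

    Minimizes cross-entropy with Adam (learning rate ``hyper.eta``, default
    1e-4 here), mini-batches of ``hyper.batch_size``, up to ``hyper.epochs``
    passes with early stopping on a held-out validation split (restoring the
    best weights).  Fully deterministic for a fixed ``hyper.seed``.
    """
    hyper = hyper or Hyperparameters(eta=1e-4, epochs=200)
    X, y = _to_arrays(examples, spec.input_dim, spec.output_dim)
    if len(examples) < hyper.batch_size:
        raise ValueError(
            f"need at least batch_size={hyper.batch_size} examples, got {len(examples)}"
        )
    rng = np.random.default_rng(hyper.seed)
    order = rng.permutation(len(X))
    n_val = max(1, int(round(validation_fraction * len(X)))) if patience else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    net = MLP(spec, seed=int(rng.integers(2**31)))
    opt = Adam(net.parameters, lr=hyper.eta)
    log: list[float] = []
    best_val = np.inf
    best = None
    stall = 0
    n = len(Xtr)
    batch = min(hyper.batch_size, n)
    for _epoch in range(hyper.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n - batch + 1, batch):
            idx = perm[start:start + batch]
            out, pre, acts = net.forward(Xtr[idx])
            p = softmax(out)
            # dL/dlogits for mean cross-entropy
            d_out = p.copy()
            d_out[np.arange(len(idx)), ytr[idx]] -= 1.0
            d_out /= len(idx)
            opt.step(net.parameters, net.backward(d_out, pre, acts))
            epoch_loss += -float(
                np.mean(np.log(p[np.arange(len(idx)), ytr[idx]] + 1e-12))
            )
        log.append(epoch_loss / max(1, n // batch))
        if patience and n_val:
            pv = softmax(net.predict(Xval))
            val_loss = -float(np.mean(np.log(pv[np.arange(len(yval)), yval] + 1e-12)))
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best = ([w.copy() for w in net.weights], [b.copy() for b in net.biases])
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
    if best is not None:
        net.weights, net.biases = best
    return ExpertModel(net=net, codec=None, training_log=log)


def predict_action_probabilities(model: ExpertModel, state: StateVector) -> np.ndarray:
    """Length-K simplex vector of predicted expert-action probabilities."""
    v = state.values if isinstance(state, StateVector) else np.asarray(state, float)
    if v.shape != (model.spec.input_dim,):
        raise ValueError(
            f"state length {v.shape} does not match input_dim {model.spec.input_dim}"
        )
    return model.probabilities(v)[0]


def top_n_accuracy(model: ExpertModel, test_examples: Sequence[Example], N: int) -> float:
    """Fraction of examples whose observed action is among the N most probable.

    Ties in predicted probability are broken toward the lower action index.
    """
    if not test_examples:
        raise ValueError("empty test set")
    if not 1 <= N <= model.n_actions:
        raise ValueError(f"N must lie in [1, {model.n_actions}]")
    X, y = _to_arrays(test_examples, model.spec.input_dim, model.n_actions)
    probs = model.probabilities(X)
    # stable sort on -p keeps lower indices first among ties
    ranks = np.argsort(-probs, axis=1, kind="stable")[:, :N]
    hits = (ranks == y[:, None]).any(axis=1)
    return float(hits.mean())


def screen_actions(model: ExpertModel, state: StateVector, N: int) -> list[int]:
    """The N actions of highest predicted expert probability, descending."""
    if not 1 <= N <= model.n_actions:
        raise ValueError(f"N must lie in [1, {model.n_actions}]")
    p = predict_action_probabilities(model, state)
    return np.argsort(-p, kind="stable")[:N].tolist()
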