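"""Offline deep Q-learning with experience replay and a soft-tracked target network.

Training is purely offline: logged transitions are loaded into a bounded
FIFO replay buffer (capacity 20000 by default; the oldest tuples are evicted
when full) and the Q-network is fit by mini-batch TD regression.  Targets are
computed by a target network theta' that slowly tracks the Q-network,
theta' <- tau*theta + (1-tau)*theta' with tau = 0.01 after every gradient
step, which damps the oscillations that plain bootstrapped Q-regression is
prone to.  No environment interaction ever occurs during training — new data
cannot be gathered on actual patients — so there is no exploration schedule;
greedy action selection is exercised only at recommendation time, optionally
restricted to an admissible (expert-screened) action set.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .nn import MLP, Adam, MLPSpec, soft_update_arrays
from .registry import Hyperparameters, StateVector, Transition

__all__ = [
    "ReplayBuffer",
    "QNetwork",
    "dqn_spec",
    "init_networks",
    "soft_update",
    "td_targets",
    "train_dqn",
    "TrainedDQN",
    "recommend",
]


def dqn_spec(input_dim: int, n_actions: int,
             hidden: tuple[int, int] = (32, 64)) -> MLPSpec:
    """Default Q-network architecture: input -> 32 -> 64 -> K."""
    return MLPSpec(input_dim=input_dim, hidden_dims=hidden, output_dim=n_actions)


class ReplayBuffer:
    """Bounded FIFO store of transitions; insertion beyond capacity evicts the oldest."""

    def __init__(self, capacity: int = 20000):
        if capacity <= 0:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._storage: deque[Transition] = deque(maxlen=capacity)

    def add(self, transition: Transition) -> None:
        self._storage.append(transition)

    def extend(self, transitions: Iterable[Transition]) -> None:
        for t in transitions:
            self.add(t)

    def __len__(self) -> int:
        return len(self._storage)

    def __iter__(self):
        return iter(self._storage)

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Transition]:
        """Uniform sample with replacement."""
        if not self._storage:
            raise ValueError("cannot sample from an empty buffer")
        idx = rng.integers(len(self._storage), size=batch_size)
        return [self._storage[i] for i in idx]


class QNetwork:
    """Action-value network Q(s, .; theta): one output per action."""

    def __init__(self, spec: MLPSpec, seed: int):
        self.net = MLP(spec, seed)

    @property
    def spec(self) -> MLPSpec:
        return self.net.spec

    @property
    def parameters(self) -> list[np.ndarray]:
        return self.net.parameters

    def q_values(self, states: np.ndarray) -> np.ndarray:
        return self.net.predict(np.atleast_2d(states))


def init_networks(spec: MLPSpec, seed: int) -> tuple[QNetwork, QNetwork]:
    """Create a Q-network and its target, initialized with identical weights."""
    qnet = QNetwork(spec, seed)
    target = QNetwork(spec, seed)
    target.net.copy_weights_from(qnet.net)
    return qnet, target


def soft_update(theta: Sequence[np.ndarray] | QNetwork,
                theta_prime: Sequence[np.ndarray] | QNetwork,
                tau: float):
    """theta' <- tau*theta + (1-tau)*theta', elementwise; returns theta'."""
    src = theta.parameters if isinstance(theta, QNetwork) else list(theta)
    dst = theta_prime.parameters if isinstance(theta_prime, QNetwork) else list(theta_prime)
    soft_update_arrays(src, dst, tau)
    return theta_prime


def _stack(transitions: Sequence[Transition]):
    S = np.stack([t.s.values for t in transitions])
    A = np.array([t.a.combo_index for t in transitions], dtype=int)
    R = np.array([t.r for t in transitions], dtype=float)
    S_next = np.stack([t.s_next.values for t in transitions])
    boot = np.array(
        [not (t.terminal or t.truncated) for t in transitions], dtype=float
    )
    return S, A, R, S_next, boot


def td_targets(
    batch: Sequence[Transition],
    target_net: QNetwork,
    gamma: float,
    horizon: Optional[int] = None,
    r_max: float = 1.0,
) -> np.ndarray:
    """y_i = r_i + gamma * max_a' Q'(s'_i, a') for bootstrappable transitions, else r_i.

    When ``horizon`` is given, the bootstrap continuation value is clipped to
    the feasible range [0, sum_{k<T-t'} gamma^k * r_max] of returns still
    attainable from the destination stage t'.  With per-visit rewards bounded
    by ``r_max``, this keeps the targets inside the finite-horizon envelope
    that a stationary network (which cannot see the stage) would otherwise
    overshoot.
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    _, _, R, S_next, boot = _stack(batch)
    q_next = target_net.q_values(S_next).max(axis=1)
    if horizon is not None:
        steps_left = np.array(
            [max(horizon - t.s_next.stage_index, 0) for t in batch], dtype=float
        )
        if gamma < 1.0:
            v_max = r_max * (1.0 - gamma**steps_left) / (1.0 - gamma)
        else:
            v_max = r_max * steps_left
        q_next = np.clip(q_next, 0.0, v_max)
    return R + gamma * boot * q_next


@dataclass
class TrainedDQN:
    """A trained Q-network with its target and per-pass loss log."""

    qnet: QNetwork
    target: QNetwork
    loss_log: list[float] = field(default_factory=list)

    def greedy_action(self, state: StateVector,
                      admissible: Optional[Sequence[int]] = None) -> int:
        return recommend(self.qnet, admissible, state)

    def as_policy(self, admissible: Optional[Sequence[int]] = None, label: str = "dqn"):
        """Wrap the greedy Q-network as an evaluation :class:`~dtrlearn.evaluate.Policy`.

        ``admissible`` restricts recommendations to a screened action set.
        """
        from .evaluate import Policy

        return Policy(lambda state: recommend(self.qnet, admissible, state), label=label)


def train_dqn(
    transitions: Sequence[Transition],
    spec: MLPSpec,
    hyper: Optional[Hyperparameters] = None,
    horizon: Optional[int] = 4,
    plateau_patience: int = 10,
    plateau_tol: float = 5e-3,
) -> TrainedDQN:
    """Fit a Q-network to logged transitions by experience replay.

    One pass samples ``len(buffer) // batch_size`` uniform mini-batches; each
    step minimizes the squared TD error against the target network (Adam,
    starting at learning rate ``hyper.eta`` and annealed linearly to zero
    over the pass budget) and then soft-updates the target with
    tau = ``hyper.tau``.  Training runs ``hyper.epochs`` passes, with early
    plateau stopping once the Q-values on a fixed probe set stop moving
    (mean absolute drift per pass below ``plateau_tol`` for
    ``plateau_patience`` consecutive passes; the raw TD loss is dominated by
    the irreducible outcome variance, so convergence is judged on the value
    estimates themselves).  ``horizon`` enables the finite-horizon clip of
    the bootstrap targets (see :func:`td_targets`).  Deterministic for a
    fixed ``hyper.seed``.
    """
    hyper = hyper or Hyperparameters()
    transitions = list(transitions)
    if not transitions:
        raise ValueError("no transitions provided")
    if len(transitions) < hyper.batch_size:
        raise ValueError(
            f"need at least batch_size={hyper.batch_size} transitions, got {len(transitions)}"
        )
    buffer = ReplayBuffer(hyper.buffer_capacity)
    buffer.extend(transitions)

    rng = np.random.default_rng(hyper.seed)
    qnet, target = init_networks(spec, seed=int(rng.integers(2**31)))
    opt = Adam(qnet.parameters, lr=hyper.eta)

    probe_idx = rng.choice(len(buffer), size=min(256, len(buffer)), replace=False)
    all_states = [t.s.values for t in buffer]
    probe = np.stack([all_states[i] for i in probe_idx])
    probe_q = qnet.q_values(probe)

    steps_per_pass = max(1, len(buffer) // hyper.batch_size)
    loss_log: list[float] = []
    stall = 0
    for _pass in range(hyper.epochs):
        # anneal the step size linearly to zero so the iterates settle
        # instead of oscillating around the TD fixed point
        opt.lr = hyper.eta * (1.0 - _pass / hyper.epochs)
        pass_loss = 0.0
        for _ in range(steps_per_pass):
            batch = buffer.sample(hyper.batch_size, rng)
            S, A, _, _, _ = _stack(batch)
            y = td_targets(batch, target, hyper.gamma, horizon=horizon)
            out, pre, acts = qnet.net.forward(S)
            rows = np.arange(len(batch))
            diff = out[rows, A] - y
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite TD loss at pass {_pass}; try a smaller learning rate"
                )
            pass_loss += loss
            d_out = np.zeros_like(out)
            d_out[rows, A] = 2.0 * diff / len(batch)
            opt.step(qnet.parameters, qnet.net.backward(d_out, pre, acts))
            soft_update(qnet, target, hyper.tau)
        loss_log.append(pass_loss / steps_per_pass)
        new_probe_q = qnet.q_values(probe)
        drift = float(np.mean(np.abs(new_probe_q - probe_q)))
        probe_q = new_probe_q
        if drift < plateau_tol:
            stall += 1
            if stall >= plateau_patience:
                break
        else:
            stall = 0
    return TrainedDQN(qnet=qnet, target=target, loss_log=loss_log)


def recommend(qnet: QNetwork, admissible: Optional[Sequence[int]],
              state: StateVector) -> int:
    """Greedy action: argmax of Q(state, .) over the admissible set.

    ``admissible`` of None means all actions.  Ties break toward the lower
    action index.
    """
    K = qnet.spec.output_dim
    if admissible is None:
        admissible = range(K)
    admissible = sorted(set(int(a) for a in admissible))
    if not admissible:
        raise ValueError("admissible action set is empty")
    if admissible[-1] >= K or admissible[0] < 0:
        raise ValueError(f"admissible indices must lie in [0, {K})")
    v = state.values if isinstance(state, StateVector) else np.asarray(state, float)
    q = qnet.q_values(v)[0]
    best = admissible[0]
    for a in admissible[1:]:
        if q[a] > q[best]:
            best = a
    return best
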