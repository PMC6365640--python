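"""Off-policy evaluation of treatment policies and comparison baselines.

Two evaluation protocols are provided:

* **Matched reward** — among test-set patient-stages where the logged expert
  action coincides with the policy's recommendation, average the observed
  next-state immediate reward; uncertainty via a percentile bootstrap of the
  matched rewards (5000 resamples by default).
* **Counterfactual value** — train a reward-prediction network on logged
  (state, action, reward) tuples and average its prediction at the policy's
  recommended action over the test states; the policy's top choice is rarely
  the logged action, so the network supplies the counterfactual estimate.

Baselines: the observed expert behavior, a one-size-fits-all policy (the
most frequent treatment for everyone), a random-forest reward regression
with greedy argmax, and uniform random choice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .nn import MLP, Adam, MLPSpec
from .registry import (
    ActionCodec,
    FeatureSchema,
    Hyperparameters,
    StateVector,
    Trajectory,
    Transition,
    to_transitions,
)

__all__ = [
    "Policy",
    "uniform_random_policy",
    "matched_reward",
    "bootstrap_ci",
    "one_size_fits_all_policy",
    "random_forest_policy",
    "RewardModel",
    "reward_net_spec",
    "train_reward_predictor",
    "counterfactual_value",
    "baseline_excluding_top",
]


@dataclass
class Policy:
    """A treatment policy: encoded state (with stage index) -> action index."""

    decide: Callable[[StateVector], int]
    label: str = "policy"

    def __call__(self, state: StateVector) -> int:
        return int(self.decide(state))


def uniform_random_policy(n_actions: int, seed: int) -> Policy:
    """Uniform random choice; per-state draws are seeded and replayable."""
    root = np.random.default_rng(seed)
    cache: dict[bytes, int] = {}

    def decide(state: StateVector) -> int:
        key = state.values.tobytes() + bytes([state.stage_index])
        if key not in cache:
            cache[key] = int(root.integers(n_actions))
        return cache[key]

    return Policy(decide, label="random")


def matched_reward(
    policy: Policy,
    test_trajectories: Sequence[Trajectory],
    codec: ActionCodec,
    schema: Optional[FeatureSchema] = None,
    stage_filter: Optional[set[int]] = None,
) -> tuple[float, int, list[float]]:
    """Mean observed reward among patient-stages that follow the recommendation.

    For each evaluated stage record whose logged action equals the policy's
    recommendation, the next-state immediate reward is collected.  Returns
    (mean reward, matched count, matched reward values); raises if no record
    matches rather than reporting a silent zero.
    """
    schema = schema or FeatureSchema.default()
    if not test_trajectories:
        raise ValueError("empty test set")
    rewards: list[float] = []
    for traj in test_trajectories:
        for tr in to_transitions(traj, codec, schema, stage_filter):
            if policy(tr.s) == tr.a.combo_index:
                rewards.append(tr.r)
    if not rewards:
        raise ValueError(
            f"no matched patients: policy {policy.label!r} never agrees with "
            "the logged actions on this test set"
        )
    return float(np.mean(rewards)), len(rewards), rewards


def bootstrap_ci(
    values: Sequence[float],
    B: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("empty value sequence")
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(values.size, size=(B, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def one_size_fits_all_policy(
    train_trajectories: Sequence[Trajectory],
    codec: ActionCodec,
    stage: Optional[int] = None,
    schema: Optional[FeatureSchema] = None,
) -> Policy:
    """The constant policy giving everyone the most frequent observed treatment.

    Frequencies are counted over the training records (restricted to
    ``stage`` if given); ties break toward the lower action index.
    """
    schema = schema or FeatureSchema.default()
    counts: Counter[int] = Counter()
    for traj in train_trajectories:
        for rec in traj.records:
            if rec.action is None:
                continue
            if stage is not None and rec.stage_index != stage:
                continue
            counts[codec.index_of(rec.action.drug_set)] += 1
    if not counts:
        where = "the cohort" if stage is None else f"stage {stage}"
        raise ValueError(f"no treatment actions observed at {where}")
    modal = min(counts, key=lambda a: (-counts[a], a))
    return Policy(lambda state: modal, label="one-size-fits-all")


def random_forest_policy(
    train_transitions: Sequence[Transition],
    codec: ActionCodec,
    seed: int = 0,
    n_estimators: int = 200,
) -> Policy:
    """Greedy policy over a random-forest regression of reward on (state, action)."""
    from sklearn.ensemble import RandomForestRegressor

    if not train_transitions:
        raise ValueError("no training transitions")
    X = np.stack(
        [np.append(tr.s.values, tr.a.combo_index) for tr in train_transitions]
    )
    y = np.array([tr.r for tr in train_transitions])
    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    forest.fit(X, y)
    K = codec.n_actions
    actions = np.arange(K)

    def decide(state: StateVector) -> int:
        grid = np.column_stack([np.tile(state.values, (K, 1)), actions])
        return int(np.argmax(forest.predict(grid)))

    return Policy(decide, label="random-forest")


def reward_net_spec(state_dim: int, n_actions: int,
                    hidden: tuple[int, int] = (16, 32)) -> MLPSpec:
    """Reward net: (state, one-hot action) -> scalar reward."""
    return MLPSpec(input_dim=state_dim + n_actions, hidden_dims=hidden, output_dim=1)


@dataclass
class RewardModel:
    """A trained immediate-reward predictor r_hat(s, a), clipped to [0, 1]."""

    net: MLP
    n_actions: int
    training_log: list[float] = field(default_factory=list)

    @property
    def state_dim(self) -> int:
        return self.net.spec.input_dim - self.n_actions

    def _features(self, states: np.ndarray, actions: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(states)
        onehot = np.zeros((len(states), self.n_actions))
        onehot[np.arange(len(states)), actions] = 1.0
        return np.hstack([states, onehot])

    def predict(self, state: StateVector | np.ndarray, action: int) -> float:
        v = state.values if isinstance(state, StateVector) else np.asarray(state, float)
        out = self.net.predict(self._features(v, np.array([action])))[0, 0]
        return float(np.clip(out, 0.0, 1.0))

    def predict_all_actions(self, state: StateVector | np.ndarray) -> np.ndarray:
        v = state.values if isinstance(state, StateVector) else np.asarray(state, float)
        S = np.tile(v, (self.n_actions, 1))
        out = self.net.predict(self._features(S, np.arange(self.n_actions)))[:, 0]
        return np.clip(out, 0.0, 1.0)


def train_reward_predictor(
    transitions: Sequence[Transition],
    n_actions: int,
    spec: Optional[MLPSpec] = None,
    hyper: Optional[Hyperparameters] = None,
) -> RewardModel:
    """Fit an MLP regression of the observed immediate reward on (state, action).

    Squared-error loss, Adam at learning rate ``hyper.eta`` (default 1e-4);
    deterministic for a fixed seed.
    """
    hyper = hyper or Hyperparameters(eta=1e-4, epochs=200)
    transitions = list(transitions)
    if not transitions:
        raise ValueError("no transitions provided")
    if len(transitions) < hyper.batch_size:
        raise ValueError(
            f"need at least batch_size={hyper.batch_size} transitions"
        )
    state_dim = transitions[0].s.values.size
    spec = spec or reward_net_spec(state_dim, n_actions)
    model = RewardModel(net=MLP(spec, seed=hyper.seed), n_actions=n_actions)
    S = np.stack([tr.s.values for tr in transitions])
    A = np.array([tr.a.combo_index for tr in transitions], dtype=int)
    X = model._features(S, A)
    y = np.array([tr.r for tr in transitions])

    rng = np.random.default_rng(hyper.seed + 1)
    opt = Adam(model.net.parameters, lr=hyper.eta)
    n = len(X)
    batch = min(hyper.batch_size, n)
    for _epoch in range(hyper.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n - batch + 1, batch):
            idx = perm[start:start + batch]
            out, pre, acts = model.net.forward(X[idx])
            diff = out[:, 0] - y[idx]
            epoch_loss += float(np.mean(diff**2))
            d_out = (2.0 * diff / len(idx))[:, None]
            opt.step(model.net.parameters, model.net.backward(d_out, pre, acts))
        model.training_log.append(epoch_loss / max(1, n // batch))
    return model


RewardFn = Callable[[StateVector, int], float]


def counterfactual_value(
    reward_model: RewardModel | RewardFn,
    policy: Policy,
    test_states: Sequence[StateVector],
) -> float:
    """Mean predicted reward at the policy's recommended action over test states."""
    if not test_states:
        raise ValueError("empty state set")
    predict = (
        reward_model.predict if isinstance(reward_model, RewardModel) else reward_model
    )
    return float(np.mean([predict(s, policy(s)) for s in test_states]))


def baseline_excluding_top(
    reward_model: RewardModel | RewardFn,
    test_states: Sequence[StateVector],
    policy: Policy,
    codec: ActionCodec,
) -> float:
    """Mean predicted reward averaged over all actions except the policy's top pick."""
    K = codec.n_actions
    if K < 2:
        raise ValueError("need at least 2 actions to exclude the top recommendation")
    if not test_states:
        raise ValueError("empty state set")
    predict = (
        reward_model.predict if isinstance(reward_model, RewardModel) else reward_model
    )
    totals = []
    for s in test_states:
        top = policy(s)
        others = [predict(s, a) for a in range(K) if a != top]
        totals.append(np.mean(others))
    return float(np.mean(totals))
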