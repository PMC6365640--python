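"""Tests for matched-reward and counterfactual policy evaluation."""

import numpy as np
import pytest

from dtrlearn import evaluate as ev
from dtrlearn import simulate as sim
from dtrlearn.registry import (
    ActionCodec,
    Hyperparameters,
    StateVector,
    Transition,
    TreatmentAction,
    to_transitions,
)
from dtrlearn.simulate import HEALTHY
from conftest import make_trajectory
from test_registry import ACUTE, DEAD, HEALTHY as HEALTHY_FLAGS


def behavior_mimic_policy(codec, schema):
    """A policy that replays whatever action the expert logged (by state match
    it cannot be built in general, so tests instead pass observed actions)."""


class TestMatchedReward:
    def test_expert_policy_matches_everything(self, small_cohort, codec, schema):
        # a policy that always recommends the logged action, built by lookup
        lookup = {}
        for traj in small_cohort:
            for tr in to_transitions(traj, codec, schema):
                lookup[(tr.s.values.tobytes(), tr.s.stage_index)] = tr.a.combo_index
        policy = ev.Policy(
            lambda s: lookup[(s.values.tobytes(), s.stage_index)], "mimic"
        )
        mean, count, values = ev.matched_reward(policy, small_cohort, codec, schema)
        all_rewards = [
            tr.r
            for traj in small_cohort
            for tr in to_transitions(traj, codec, schema)
        ]
        # rare encoded-state aliasing (e.g. ages clipped to the same bound)
        # can overwrite a lookup entry; allow a handful of misses
        assert count >= len(all_rewards) - 5
        assert mean == pytest.approx(np.mean(all_rewards), abs=0.005)

    def test_hand_average(self, baseline, codec, schema):
        traj = make_trajectory(
            baseline,
            [HEALTHY_FLAGS, HEALTHY_FLAGS, ACUTE, DEAD],
            [{"drug_a"}, {"drug_b"}, {"drug_a", "drug_c"}],
        )
        # recommend drug_a at stage 0 (matches, r=1), drug_a at stage 1
        # (logged was drug_b: no match), the escalation at stage 2 (matches,
        # r=0 on death)
        def decide(state):
            return codec.index_of({"drug_a", "drug_c"}) if state.stage_index == 2 \
                else codec.index_of({"drug_a"})

        mean, count, values = ev.matched_reward(
            ev.Policy(decide, "test"), [traj], codec, schema
        )
        assert count == 2
        assert mean == pytest.approx((1.0 + 0.0) / 2)

    def test_zero_matches_is_an_error(self, small_cohort, codec, schema):
        never = ev.Policy(lambda s: -1, "never")
        with pytest.raises(ValueError, match="no matched patients"):
            ev.matched_reward(never, small_cohort, codec, schema)

    def test_empty_test_set_rejected(self, codec, schema):
        with pytest.raises(ValueError):
            ev.matched_reward(ev.Policy(lambda s: 0), [], codec, schema)


class TestBootstrapCI:
    def test_constant_sequence_zero_width(self):
        lo, hi = ev.bootstrap_ci([0.7] * 20, B=200, seed=0)
        assert lo == hi == pytest.approx(0.7)

    def test_interval_brackets_sample_mean(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.5, 0.1, size=200)
        lo, hi = ev.bootstrap_ci(x, B=5000, seed=1)
        assert lo <= x.mean() <= hi

    def test_seed_determinism(self):
        x = np.random.default_rng(5).normal(size=50)
        assert ev.bootstrap_ci(x, B=500, seed=7) == ev.bootstrap_ci(x, B=500, seed=7)

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(6)
        small = rng.normal(size=100)
        large = rng.normal(size=1600)
        lo_s, hi_s = ev.bootstrap_ci(small, B=2000, seed=0)
        lo_l, hi_l = ev.bootstrap_ci(large, B=2000, seed=0)
        ratio = (hi_s - lo_s) / (hi_l - lo_l)
        # 16x the sample should shrink the width ~4x
        assert 2.5 <= ratio <= 6.0

    def test_coverage_of_the_mean(self):
        """95% percentile interval covers a known mean 93-97% of the time."""
        rng = np.random.default_rng(123)
        cover = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(0.7, 0.1, size=80)
            lo, hi = ev.bootstrap_ci(x, B=600, seed=int(rng.integers(2**31)))
            cover += lo <= 0.7 <= hi
        assert 0.93 <= cover / reps <= 0.97


class TestOneSizeFitsAll:
    def test_modal_action(self, baseline, codec, schema):
        trajs = [
            make_trajectory(baseline, [HEALTHY_FLAGS, DEAD], [{"drug_a"}], pid="a"),
            make_trajectory(baseline, [HEALTHY_FLAGS, DEAD], [{"drug_a"}], pid="b"),
            make_trajectory(baseline, [HEALTHY_FLAGS, DEAD], [{"drug_a"}], pid="c"),
            make_trajectory(baseline, [HEALTHY_FLAGS, DEAD], [{"drug_b"}], pid="d"),
        ]
        policy = ev.one_size_fits_all_policy(trajs, codec)
        assert policy(StateVector(np.zeros(8), 0)) == codec.index_of({"drug_a"})

    def test_constant_in_state(self, small_cohort, codec, schema):
        policy = ev.one_size_fits_all_policy(small_cohort, codec)
        rng = np.random.default_rng(0)
        actions = {
            policy(StateVector(rng.normal(size=8), int(rng.integers(4))))
            for _ in range(20)
        }
        assert len(actions) == 1

    def test_single_observed_action(self, baseline, codec):
        trajs = [make_trajectory(baseline, [HEALTHY_FLAGS, DEAD], [{"drug_b"}])]
        policy = ev.one_size_fits_all_policy(trajs, codec)
        assert policy(StateVector(np.zeros(8), 0)) == codec.index_of({"drug_b"})

    def test_no_actions_at_stage_rejected(self, baseline, codec):
        trajs = [make_trajectory(baseline, [HEALTHY_FLAGS, DEAD], [{"drug_a"}])]
        with pytest.raises(ValueError, match="stage 3"):
            ev.one_size_fits_all_policy(trajs, codec, stage=3)


def deterministic_reward_transitions(n, seed, n_actions=2):
    """Action 0 always pays 1, action 1 pays 0, everywhere."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        s = StateVector(rng.normal(size=8), 0)
        a = int(rng.integers(n_actions))
        out.append(
            Transition(s, TreatmentAction(frozenset({"d"}), a),
                       1.0 if a == 0 else 0.0, s, False)
        )
    return out


class TestRandomForestPolicy:
    def test_learns_dominant_action(self, codec):
        transitions = deterministic_reward_transitions(500, seed=0)
        policy = ev.random_forest_policy(transitions, codec, seed=0)
        rng = np.random.default_rng(1)
        states = [StateVector(rng.normal(size=8), 0) for _ in range(100)]
        hits = sum(policy(s) == 0 for s in states)
        assert hits >= 95

    def test_actions_within_codec_range(self, codec):
        transitions = deterministic_reward_transitions(200, seed=2)
        policy = ev.random_forest_policy(transitions, codec, seed=0)
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = policy(StateVector(rng.normal(size=8), 0))
            assert 0 <= a < codec.n_actions

    def test_seed_determinism(self, codec):
        transitions = deterministic_reward_transitions(200, seed=4)
        pa = ev.random_forest_policy(transitions, codec, seed=5)
        pb = ev.random_forest_policy(transitions, codec, seed=5)
        rng = np.random.default_rng(6)
        states = [StateVector(rng.normal(size=8), 0) for _ in range(30)]
        assert [pa(s) for s in states] == [pb(s) for s in states]


class TestRewardPredictor:
    def test_fits_noiseless_flag_based_mapping(self):
        """Reward depends only on status flags and action — an MLP should
        drive held-out squared error to near zero."""
        rng = np.random.default_rng(7)
        table = np.array([[1.0, 0.6], [0.5, 0.9], [0.3, 0.7]])
        transitions = []
        for _ in range(2500):
            status = int(rng.integers(3))
            flags = np.zeros(3)
            flags[status] = 1.0
            s = StateVector(np.concatenate([flags, rng.normal(size=5)]), 0)
            a = int(rng.integers(2))
            transitions.append(
                Transition(s, TreatmentAction(frozenset({"d"}), a),
                           float(table[status, a]), s, False)
            )
        model = ev.train_reward_predictor(
            transitions[:2000], 2,
            hyper=Hyperparameters(eta=1e-4, epochs=200, seed=0),
        )
        errs = [
            (model.predict(t.s, t.a.combo_index) - t.r) ** 2
            for t in transitions[2000:]
        ]
        assert float(np.mean(errs)) <= 0.01

    def test_predictions_clipped_to_unit_interval(self):
        transitions = deterministic_reward_transitions(100, seed=8)
        model = ev.train_reward_predictor(
            transitions, 2, hyper=Hyperparameters(eta=1e-4, epochs=5, seed=0)
        )
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = model.predict(StateVector(rng.normal(scale=10, size=8), 0), 0)
            assert 0.0 <= p <= 1.0

    def test_seed_determinism(self):
        transitions = deterministic_reward_transitions(100, seed=10)
        hyper = Hyperparameters(eta=1e-4, epochs=3, seed=2)
        a = ev.train_reward_predictor(transitions, 2, hyper=hyper)
        b = ev.train_reward_predictor(transitions, 2, hyper=hyper)
        for wa, wb in zip(a.net.parameters, b.net.parameters):
            np.testing.assert_array_equal(wa, wb)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ev.train_reward_predictor([], 2)


class TestCounterfactualValue:
    def test_constant_model(self):
        states = [StateVector(np.zeros(8), 0) for _ in range(5)]
        value = ev.counterfactual_value(
            lambda s, a: 0.42, ev.Policy(lambda s: 0), states
        )
        assert value == pytest.approx(0.42)

    def test_hand_average(self):
        states = [StateVector(np.zeros(8), 0), StateVector(np.ones(8), 0)]
        model = lambda s, a: 0.9 if s.values[0] == 0 else 0.7
        value = ev.counterfactual_value(model, ev.Policy(lambda s: 0), states)
        assert value == pytest.approx(0.8)

    def test_exact_reward_prefers_optimal_policy(self, default_config, oracle, schema):
        """Scoring with the true one-step reward ranks the optimal policy
        above uniform random."""
        P = default_config.transition_model
        r = default_config.status_reward()

        def true_reward(state, action):
            status = sim.status_of_state(state, schema)
            return float(P[status, action] @ r)

        cohort = sim.simulate_cohort(sim.default_scenario(300, seed=5))
        codec = default_config.codec()
        states = [
            tr.s
            for traj in cohort
            for tr in to_transitions(traj, codec, schema)
        ]
        v_opt = ev.counterfactual_value(true_reward, oracle.as_policy(schema), states)
        v_rand = ev.counterfactual_value(
            true_reward, ev.uniform_random_policy(codec.n_actions, 0), states
        )
        assert v_opt >= v_rand

    def test_empty_states_rejected(self):
        with pytest.raises(ValueError):
            ev.counterfactual_value(lambda s, a: 1.0, ev.Policy(lambda s: 0), [])


class TestBaselineExcludingTop:
    def test_two_actions_reduces_to_other_action(self, codec):
        two = ActionCodec([frozenset({"a"}), frozenset({"b"})])
        states = [StateVector(np.zeros(8), 0)]
        model = lambda s, a: 0.9 if a == 0 else 0.3
        value = ev.baseline_excluding_top(model, states, ev.Policy(lambda s: 0), two)
        assert value == pytest.approx(0.3)

    def test_hand_average_three_actions(self):
        three = ActionCodec([frozenset({c}) for c in "abc"])
        states = [StateVector(np.zeros(8), 0)]
        preds = {0: 0.9, 1: 0.5, 2: 0.1}
        value = ev.baseline_excluding_top(
            lambda s, a: preds[a], states, ev.Policy(lambda s: 0), three
        )
        assert value == pytest.approx(0.3)

    def test_never_exceeds_per_state_max(self, codec):
        rng = np.random.default_rng(11)
        states = [StateVector(rng.normal(size=8), 0) for _ in range(10)]
        preds = {
            (i, a): rng.uniform()
            for i in range(10)
            for a in range(codec.n_actions)
        }
        lookup = {s.values.tobytes(): i for i, s in enumerate(states)}
        model = lambda s, a: preds[(lookup[s.values.tobytes()], a)]
        value = ev.baseline_excluding_top(
            model, states, ev.Policy(lambda s: 1), codec
        )
        per_state_max = np.mean(
            [max(preds[(i, a)] for a in range(codec.n_actions)) for i in range(10)]
        )
        assert value <= per_state_max

    def test_single_action_rejected(self):
        one = ActionCodec([frozenset({"a"})])
        with pytest.raises(ValueError):
            ev.baseline_excluding_top(
                lambda s, a: 1.0, [StateVector(np.zeros(8), 0)],
                ev.Policy(lambda s: 0), one
            )
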