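import numpy as np
import pytest

from dtrlearn import dqn
from dtrlearn.registry import (
    FeatureSchema,
    Hyperparameters,
    PatientBaseline,
    StageRecord,
    StatusFlags,
    Trajectory,
    TreatmentAction,
    immediate_reward,
    split_trajectories,
    to_transitions,
)
from dtrlearn import simulate as sim


@pytest.fixture(scope="session")
def schema():
    return FeatureSchema.default()


@pytest.fixture(scope="session")
def default_config():
    return sim.default_scenario(n_patients=2000, seed=1)


@pytest.fixture(scope="session")
def cohort(default_config):
    return sim.simulate_cohort(default_config)


@pytest.fixture(scope="session")
def codec(default_config):
    return default_config.codec()


@pytest.fixture(scope="session")
def oracle(default_config):
    return sim.optimal_policy_oracle(default_config, gamma=0.99)


@pytest.fixture(scope="session")
def all_transitions(cohort, codec, schema):
    return [t for traj in cohort for t in to_transitions(traj, codec, schema)]


@pytest.fixture(scope="session")
def trained_dqn(all_transitions, schema, codec):
    """DQN trained on the full default cohort's transitions."""
    spec = dqn.dqn_spec(len(schema), codec.n_actions)
    return dqn.train_dqn(all_transitions, spec, Hyperparameters(seed=0))


@pytest.fixture(scope="session")
def split_cohort(cohort):
    return split_trajectories(cohort, 0.2, seed=5)


@pytest.fixture(scope="session")
def split_dqn(split_cohort, codec, schema):
    """DQN trained on the 80% training split only."""
    train, _ = split_cohort
    transitions = [t for traj in train for t in to_transitions(traj, codec, schema)]
    spec = dqn.dqn_spec(len(schema), codec.n_actions)
    return dqn.train_dqn(transitions, spec, Hyperparameters(seed=0)), transitions


@pytest.fixture(scope="session")
def small_cohort():
    config = sim.default_scenario(n_patients=200, seed=3)
    return sim.simulate_cohort(config)


@pytest.fixture
def baseline():
    return PatientBaseline(
        age=45.0,
        sex="F",
        comorbidity_flags=(1, 0, 1),
        donor_relation="identical_sibling",
        donor_sex="M",
    )


def make_trajectory(baseline, statuses, drug_sets, pid="P1"):
    """Build a trajectory from latent status labels and per-stage drug sets."""
    from dtrlearn.registry import STAGE_DAYS

    records = []
    for i, status in enumerate(statuses):
        action = None
        if drug_sets is not None and i < len(drug_sets) and drug_sets[i] is not None:
            action = TreatmentAction(frozenset(drug_sets[i]), -1)
        records.append(
            StageRecord(
                stage_time=STAGE_DAYS[i],
                status=status,
                action=action,
                reward_in=0.0 if i == 0 else immediate_reward(status),
            )
        )
    return Trajectory(pid, baseline, records)
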