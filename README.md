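# dtrlearn

Offline deep Q-learning for **dynamic treatment regimes** (DTRs) estimated
from registry-style observational data.

Many diseases are managed through a *sequence* of treatment decisions that
adapt to the patient's evolving clinical state. The motivating setting is
graft-versus-host disease (GVHD) after allogeneic hematopoietic cell
transplantation: patients are followed at fixed registry visits (day 0, 100,
180, 365, 730), their status at each visit is one of
{event-free, acute GVHD, chronic GVHD, relapse, dead}, and at each visit the
physician prescribes a combination of drugs drawn from a large discrete
space (hundreds of observed combinations). Death and relapse are absorbing.
Randomized sequential trials over such action spaces are infeasible, so the
policy must be learned *offline* from logged trajectories.

`dtrlearn` implements the full estimation and evaluation pipeline:

- **Registry data model** — typed longitudinal trajectories, an 8-feature
  state encoding (4 status flags + age, sex, donor HLA-matching category,
  comorbidity count), a drug-combination action codec, long-format CSV I/O,
  and preprocessing (low-variance feature filter, patient-level train/test
  splits).
- **Reward** — a quality-of-life proxy attached to each arrival state:
  r = 1 (alive, event-free), 0.8 (acute GVHD), 0.7 (chronic GVHD),
  0 (dead; relapse is scored 0 by default). The estimand is the expected
  discounted cumulative reward R_t = Σ_k γ^{k−t} r_k with γ = 0.99.
- **Expert-action screening** — behavior-cloning MLPs predicting the
  physician's drug combination from the state, used to restrict Q-greedy
  recommendations to the top-N clinically plausible actions and scored by
  top-N accuracy.
- **Offline DQN** — Q(s, a; θ) as an MLP (8 → 32 → 64 → K), experience
  replay from a 20 000-tuple FIFO buffer, squared TD error minimized by
  Adam (η = 10⁻³, annealed), and a target network θ′ tracking
  θ′ ← τθ + (1−τ)θ′ with τ = 0.01 after every step. No environment
  interaction occurs during training.
- **Policy evaluation** — the matched-reward protocol (mean observed
  next-state reward among patient-stages whose logged action equals the
  policy's recommendation, with 5 000-resample percentile bootstrap CIs)
  and counterfactual evaluation via a learned reward network; baselines:
  logged expert behavior, one-size-fits-all (modal treatment), a
  random-forest reward regression, and uniform random.
- **Synthetic registry** — a ground-truth Markov decision process over the
  five clinical statuses with a configurable stochastic expert, plus exact
  finite-horizon dynamic programming (`optimal_policy_oracle`,
  `policy_value_exact`), so every learning stage is testable against an
  exact oracle without access to any restricted cohort.

## Worked example

```python
import numpy as np
from dtrlearn import (Hyperparameters, FeatureSchema, split_trajectories,
                      to_transitions)
from dtrlearn import dqn, evaluate as ev, simulate as sim

config = sim.default_scenario(n_patients=2000, seed=1)
cohort = sim.simulate_cohort(config)                 # 2000 trajectories
codec, schema = config.codec(), FeatureSchema.default()

train, test = split_trajectories(cohort, 0.2, seed=5)
transitions = [t for traj in train for t in to_transitions(traj, codec, schema)]

trained = dqn.train_dqn(transitions, dqn.dqn_spec(len(schema), codec.n_actions),
                        Hyperparameters(seed=0))

oracle = sim.optimal_policy_oracle(config, gamma=0.99)
for policy in (trained.as_policy(),
               ev.one_size_fits_all_policy(train, codec),
               ev.uniform_random_policy(codec.n_actions, seed=3)):
    mean, count, values = ev.matched_reward(policy, test, codec, schema)
    lo, hi = ev.bootstrap_ci(values, B=5000, seed=0)
    print(f"{policy.label:>18}: {mean:.3f} ({lo:.3f}, {hi:.3f})  n={count}")
```

Output (one run):

```
               dqn: 0.914 (0.894, 0.933)  n=586
 one-size-fits-all: 0.890 (0.870, 0.909)  n=694
            random: 0.833 (0.802, 0.863)  n=364
```

The DQN's matched reward exceeds the one-size-fits-all and random baselines,
and the ordering agrees with the simulator's exact policy values
(3.412 for the optimal policy vs 3.318 constant vs 2.722 random over the
4-stage horizon). On the same cohort the greedy DQN policy picks the exact
dynamic-programming optimum in ~86% of visited patient-stages.

A command-line interface wraps the same pipeline:

```bash
dtrlearn simulate --n-patients 2000 --seed 1 --out cohort.csv
dtrlearn train-dqn --cohort cohort.csv --out dqn.npz
dtrlearn evaluate --cohort cohort.csv --model dqn.npz --out report.json
```

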