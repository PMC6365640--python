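# Methods

## Problem and model

A patient's post-transplant course is modeled as a finite-horizon discrete
decision process observed at the registry follow-up times t ∈ {0, 1, 2, 3, 4}
(days 0, 100, 180, 365, 730). The state s_t combines four clinical status
indicators (alive, acute GVHD, chronic GVHD, relapse) with baseline
patient/donor features; the action a_t is the drug combination administered
at the visit, coded as an index into the set of combinations observed in the
cohort; the reward r_t is a quality-of-life proxy earned on *arriving* in
the next state: 1 if alive and event-free, 0.8 with acute GVHD, 0.7 with
chronic GVHD, 0 if dead. Death and relapse are absorbing; no decisions
follow them. The target of estimation is the optimal action-value function

    Q(s, a) = max_π E[ R_t | s_t = s, a_t = a, π ],   R_t = Σ_{k≥t} γ^{k−t} r_k

with discount γ = 0.99, and the induced greedy policy.

Two conventions needed decisions the reward's four cases do not cover:
a patient alive after relapse scores 0 (relapse is treated as absorbing
failure, like death), and a patient carrying both GVHD flags scores the
chronic (worse) value 0.7 — a quality-of-life proxy should be dominated by
the more severe condition. Both are configurable (`RewardConfig`).

## State encoding

The default schema produces an 8-vector: the four status flags, then
age/100, a binary sex code, the donor HLA-matching category (six levels,
integer-coded), and the comorbidity count. The schema is an explicit,
serializable object (`FeatureSchema`) stored alongside cohorts and models,
so alternative encodings slot in without touching the learners. The
`low_variance_filter` utility supports dropping near-constant features
before training.

## Offline deep Q-learning

Logged trajectories are converted to replay tuples (s, a, r, s′). Each tuple
carries two end-of-episode flags with different semantics: `terminal`
(absorption — death or relapse) and `truncated` (the patient reached the
final follow-up alive; the process continues but observation stops). TD
targets bootstrap only when neither flag is set:

    y = r + γ · max_a′ Q(s′, a′; θ′)        (else y = r).

The Q-network is a fully connected MLP, input 8, hidden layers 32 and 64,
one output per action. Training loads the tuples into a bounded FIFO replay
buffer (capacity 20 000; the oldest tuples are evicted when full), then runs
mini-batch TD regression: uniform batches of 32, squared TD error, Adam at
η = 10⁻³, and after every gradient step a soft target-network update
θ′ ← τθ + (1−τ)θ′ with τ = 0.01. One pass makes ⌊N/32⌋ steps; the default
budget is 100 passes with early stopping once the Q-values on a fixed probe
batch drift less than 5·10⁻³ per pass for 10 consecutive passes. (The raw
TD loss is not a usable convergence signal: it is dominated by the
irreducible variance of the stochastic outcomes, so convergence is judged
on the value estimates themselves.)

Two numerical choices matter in practice:

- **Finite-horizon clipping of bootstrap targets.** The network is
  stationary — the stage index is not an input — so with mixed-horizon data
  the naive bootstrap drives values toward the *infinite*-horizon fixed
  point (≈ r_max/(1−γ) ≈ 100), far above the largest return actually
  attainable (Σ_{k<4} γ^k ≈ 3.94). The continuation value max Q(s′,·) is
  therefore clipped to [0, Σ_{k<T−t′} γ^k · r_max], the feasible envelope
  given the destination stage t′ and known reward bound r_max = 1. This
  keeps learned values on the scale of real returns without changing the
  argmax structure.
- **Learning-rate annealing.** With a constant step size the iterates
  orbit the TD fixed point indefinitely (per-pass value drift plateaus
  around 0.1 and the greedy policy flaps). The Adam step size is annealed
  linearly to zero across the pass budget so the iterates settle.

Training is purely offline — the trainer touches nothing but the provided
tuples — and bit-reproducible for a fixed seed: initialization, batch
sampling and shuffling all flow from one seeded generator.

No exploration schedule exists (there is no environment to explore);
greedy action selection happens only at recommendation time, and can be
restricted to an admissible set produced by the screening net. Ties break
toward the lower action index everywhere, for determinism.

## Expert-action screening

The screening nets are multiclass MLPs (default input → 16 → 32 → K,
softmax output, cross-entropy loss, Adam at η = 10⁻⁴) trained to imitate
the logged physician's choice; the initial-treatment variant takes a
9-dimensional input. Training runs up to 200 epochs with batch 32 and early
stopping on an internal validation split (patience 20, best weights
restored). Quality is measured by top-N accuracy — the logged action lies
among the N highest-probability predictions — which is monotone
non-decreasing in N by construction, and the top-N sets are nested. A
Q-greedy recommendation restricted to the screen's top-N avoids actions
whose value estimates rest on a handful of observations.

## Policy evaluation

**Matched reward.** For every evaluated patient-stage whose logged action
equals the policy's recommendation, collect the observed next-state
immediate reward; report the mean, the matched count, and a percentile
bootstrap CI of the mean (B = 5000, level 0.95). Matching is per stage
record, not per whole trajectory: with hundreds of drug combinations the
probability that a full trajectory follows a nontrivial policy at every
stage is essentially zero. Zero matches raise an error rather than report
a silent 0. The protocol is simple and model-free but *not* unconfounded:
the matched subpopulations of two policies can differ in case mix. In
particular, if the behavior policy favors different actions in healthy
versus sick states, a policy that recommends the popular healthy-state
action everywhere inherits a healthier matched set than a policy that
treats sick states correctly. The default synthetic scenario (below) keeps
the expert's primary preference identical across statuses precisely so this
composition effect cancels and matched-reward rankings reflect true policy
value; on real registry data the protocol should be read with this caveat.

**Counterfactual value.** A reward network r̂(s, a) (MLP on the state
concatenated with a one-hot action, squared error, Adam at η = 10⁻⁴,
predictions clipped to [0, 1]) is trained on logged tuples; a policy's
value is the mean r̂(s, π(s)) over test states. The complementary baseline
averages r̂ over all actions *except* the policy's recommendation. With the
exact one-step reward function substituted for r̂, the counterfactual value
of a policy equals the exact one-step policy value — a consistency check
the tests exercise.

**Baselines.** One-size-fits-all (the modal observed treatment for
everyone), the logged expert behavior itself, uniform random, and a random
forest trained to regress immediate reward on (state, action code) with
greedy argmax (scikit-learn `RandomForestRegressor`, 200 trees).

## Synthetic registry and exact oracles

The simulator generates cohorts from a known Markov decision process on the
five clinical statuses: transitions depend only on (current status, action)
— so the encoded state is Markov-sufficient by construction, making the
Q-learning premise true in tests — while baseline features (age, sex, donor
matching drawn with the frequency profile of a large AML transplant cohort,
comorbidities) act as realistic nuisance covariates the learners must
ignore. Every patient starts event-free at day 0; the behavior policy is a
temperature-1 softmax over status-dependent preference logits; rewards are
attached by the reward mapping; absorption ends the trajectory.

The default scenario has 3 drugs, 4 combinations, and 4 decision stages.
A different combination is strictly best in each transient status
(maintenance when event-free; distinct escalations for acute and chronic
GVHD) with one-step expected-reward gaps of roughly 0.2–0.3 between the
best and worst choice — effect sizes chosen large so the optimal policy is
identifiable from ≈2000 patients. The simulated expert leans toward the
maintenance combination in *every* status (probability ≈ 0.38–0.48), with a
weaker secondary lean toward the correct escalation in the GVHD states;
all actions retain ≥ 0.17 probability everywhere, so offline learning has
full action support. As noted above, the status-independent primary
preference is what makes matched-reward comparisons rank policies
consistently with their exact values.

Exact references come from dynamic programming on the latent chain:
`optimal_policy_oracle` runs backward induction to the optimal values and
greedy actions per (status, stage); `policy_value_exact` propagates the
state distribution forward under any latent policy (deterministic or
stochastic) to its exact discounted value. The tests verify the oracle
against brute-force enumeration of all deterministic policies on a reduced
two-state chain, and verify the simulator against binomial standard errors
and Monte-Carlo value estimates.

What the simulator does not emulate: covariate-dependent transition
probabilities (prognostic baseline features), stage-heterogeneous dynamics,
informative censoring or missing follow-up, and action spaces at the real
registry's scale (hundreds of combinations). Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions — not clinical validity of recommendations on real data, where
the Markov assumption and the unconfoundedness of matched evaluation are
both approximations.

## Problem sizes and runtime

Default experiment sizes were chosen so the full pipeline runs in about a
minute on one CPU: cohorts of 2000 patients (~7000 transitions), DQN budget
100 passes (~21 000 gradient steps), screening/reward nets 100–200 epochs,
bootstrap B = 5000 for reported CIs (600 inside the 500-replicate coverage
study). The exact-oracle computations are trivial (tens of states).

## Known limitations

- The stationary Q-network cannot represent stage-dependent optima; the
  default scenario's optimal action is stage-invariant by design. Scenarios
  whose optimum changes near the horizon need the stage in the schema.
- Matched-reward evaluation is biased under status-dependent behavior
  policies (see above); the counterfactual protocol inherits any bias of
  the reward network instead.
- Maximization bias of the plain TD target (no double estimator) is
  mitigated but not removed by the finite-horizon clip.
- The replay buffer's FIFO semantics matter only when the logged dataset
  exceeds capacity; the default synthetic cohorts do not.
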