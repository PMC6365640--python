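"""Data model for registry-style longitudinal treatment trajectories.

A cohort is a collection of :class:`Trajectory` objects, one per patient.
Each trajectory is an ordered sequence of :class:`StageRecord` observations
taken at the registry follow-up times (day 0, 100, 180, 365, 730).  A record
holds the patient's clinical status flags, the drug combination administered
at that visit (if any), and the immediate reward earned on *arriving* in the
recorded state.  Death and relapse are absorbing: no records follow them.

The immediate reward is a heuristic quality-of-life score on [0, 1]:
1 for alive and event-free, 0.8 for acute GVHD, 0.7 for chronic GVHD and
0 for death.  Relapse, which the source registry treats as a terminal state
alongside death, is scored 0 by default; both values are configurable via
:class:`RewardConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "STAGE_DAYS",
    "DONOR_RELATIONS",
    "PatientBaseline",
    "StatusFlags",
    "StateVector",
    "TreatmentAction",
    "ActionCodec",
    "StageRecord",
    "Trajectory",
    "Transition",
    "Hyperparameters",
    "RewardConfig",
    "FeatureSchema",
    "immediate_reward",
    "encode_state",
    "discounted_return",
    "build_action_codec",
    "low_variance_filter",
    "to_transitions",
    "split_trajectories",
    "save_cohort",
    "load_cohort",
]

#: Registry follow-up times in days after transplant.
STAGE_DAYS: tuple[int, ...] = (0, 100, 180, 365, 730)

#: Donor-recipient HLA matching categories (six levels).
DONOR_RELATIONS: tuple[str, ...] = (
    "identical_sibling",
    "other_relative",
    "urd_well_matched",
    "urd_partially_matched",
    "urd_mismatched",
    "other",
)

SEX_CODES = {"F": 0, "M": 1}


@dataclass(frozen=True)
class PatientBaseline:
    """Time-invariant patient and donor features recorded at transplant."""

    age: float
    sex: str
    comorbidity_flags: tuple[int, ...]
    donor_relation: str
    donor_sex: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
        if self.donor_relation not in DONOR_RELATIONS:
            raise ValueError(
                f"donor_relation {self.donor_relation!r} not in {DONOR_RELATIONS}"
            )


@dataclass(frozen=True)
class StatusFlags:
    """Clinical status indicators observed at one follow-up visit."""

    alive: bool
    acute_gvhd: bool = False
    chronic_gvhd: bool = False
    relapse: bool = False

    def __post_init__(self) -> None:
        if not self.alive and (self.acute_gvhd or self.chronic_gvhd):
            raise ValueError("a dead patient cannot carry GVHD flags")

    @property
    def terminal(self) -> bool:
        """Death and relapse are absorbing states."""
        return (not self.alive) or self.relapse


@dataclass(frozen=True)
class StateVector:
    """Encoded state s_t: a fixed-length feature vector plus its stage index."""

    values: np.ndarray
    stage_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class TreatmentAction:
    """A drug combination together with its index under an :class:`ActionCodec`."""

    drug_set: frozenset[str]
    combo_index: int


class ActionCodec:
    """Bijection between observed drug combinations and action indices 0..K-1.

    Combinations are kept in first-observation order so that indices are
    reproducible for a fixed cohort ordering.
    """

    def __init__(self, combos: Sequence[frozenset[str]]):
        self.combos: list[frozenset[str]] = [frozenset(c) for c in combos]
        if len(set(self.combos)) != len(self.combos):
            raise ValueError("duplicate drug set in codec")
        self._index = {c: i for i, c in enumerate(self.combos)}
        vocab: list[str] = []
        for c in self.combos:
            for drug in sorted(c):
                if drug not in vocab:
                    vocab.append(drug)
        self.drug_vocabulary: list[str] = vocab

    @property
    def n_actions(self) -> int:
        return len(self.combos)

    def index_of(self, drug_set: Iterable[str]) -> int:
        key = frozenset(drug_set)
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"drug set {sorted(key)} not in action codec") from None

    def action(self, drug_set: Iterable[str]) -> TreatmentAction:
        key = frozenset(drug_set)
        return TreatmentAction(key, self.index_of(key))

    def to_json(self) -> dict:
        return {"combos": [sorted(c) for c in self.combos]}

    @classmethod
    def from_json(cls, obj: dict) -> "ActionCodec":
        return cls([frozenset(c) for c in obj["combos"]])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ActionCodec) and self.combos == other.combos

    def __len__(self) -> int:
        return self.n_actions


@dataclass(frozen=True)
class StageRecord:
    """One follow-up observation: status, administered drugs, incoming reward."""

    stage_time: int
    status: StatusFlags
    action: Optional[TreatmentAction] = None
    reward_in: float = 0.0

    def __post_init__(self) -> None:
        if self.stage_time not in STAGE_DAYS:
            raise ValueError(f"stage_time {self.stage_time} not in {STAGE_DAYS}")

    @property
    def stage_index(self) -> int:
        return STAGE_DAYS.index(self.stage_time)


@dataclass
class Trajectory:
    """One patient's ordered stage records."""

    patient_id: str
    baseline: PatientBaseline
    records: list[StageRecord]

    def validate(self) -> None:
        if not self.records:
            raise ValueError(f"{self.patient_id}: empty trajectory")
        if self.records[0].stage_time != 0:
            raise ValueError(f"{self.patient_id}: first record must be at day 0")
        times = [r.stage_time for r in self.records]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.patient_id}: stage times must strictly increase")
        for i, rec in enumerate(self.records):
            if rec.status.terminal and i != len(self.records) - 1:
                raise ValueError(
                    f"{self.patient_id}: records present after terminal state"
                )


@dataclass(frozen=True)
class Transition:
    """Replay tuple (s, a, r, s') with episode-end bookkeeping.

    ``terminal`` marks absorption (death or relapse); ``truncated`` marks the
    end of the observation horizon with the patient still alive and
    relapse-free.  TD targets bootstrap only when neither flag is set.
    """

    s: StateVector
    a: TreatmentAction
    r: float
    s_next: StateVector
    terminal: bool
    truncated: bool = False


@dataclass
class Hyperparameters:
    """Training hyperparameters shared across the learning modules.

    Defaults: discount gamma=0.99, target-network tracking rate tau=0.01,
    learning rate eta=1e-3 for Q-learning (use 1e-4 for the supervised nets),
    replay capacity 20000.
    """

    gamma: float = 0.99
    tau: float = 0.01
    eta: float = 1e-3
    buffer_capacity: int = 20000
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        if not 0 < self.tau <= 1:
            raise ValueError("tau must lie in (0, 1]")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.buffer_capacity <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("capacity, batch size and epochs must be positive")


@dataclass(frozen=True)
class RewardConfig:
    """Immediate-reward values per status case.

    ``both_gvhd`` selects the value used when the acute and chronic flags are
    set simultaneously; the default takes the chronic (worse) value, so the
    quality-of-life proxy is dominated by the more severe condition.
    """

    healthy: float = 1.0
    acute: float = 0.8
    chronic: float = 0.7
    dead: float = 0.0
    relapse: float = 0.0
    both_gvhd: str = "chronic"


DEFAULT_REWARDS = RewardConfig()


def immediate_reward(status: StatusFlags, rewards: RewardConfig = DEFAULT_REWARDS) -> float:
    """Quality-of-life reward earned on arriving in ``status``.

    Returns 1 (alive, event-free), 0.8 (acute GVHD), 0.7 (chronic GVHD) or
    0 (dead); relapse while alive scores ``rewards.relapse`` (default 0).
    """
    if not status.alive:
        return rewards.dead
    if status.relapse:
        return rewards.relapse
    if status.acute_gvhd and status.chronic_gvhd:
        return rewards.chronic if rewards.both_gvhd == "chronic" else rewards.acute
    if status.chronic_gvhd:
        return rewards.chronic
    if status.acute_gvhd:
        return rewards.acute
    return rewards.healthy


class FeatureSchema:
    """Ordered list of named feature encoders mapping (baseline, status) -> vector.

    The default 8-feature schema is the four status flags followed by four
    baseline-derived features: age/100, sex code, donor-relation category code
    and the comorbidity count.
    """

    STATUS_FEATURES = ("alive", "acute_gvhd", "chronic_gvhd", "relapse")
    CATEGORICAL_FEATURES = ("sex", "donor_relation")

    def __init__(self, features: Sequence[str]):
        self.features = list(features)
        known = set(self.STATUS_FEATURES) | set(self.CATEGORICAL_FEATURES)
        for name in self.features:
            if name not in self._ENCODERS and name not in known:
                raise ValueError(f"unknown feature {name!r}")

    @classmethod
    def default(cls) -> "FeatureSchema":
        return cls(
            list(cls.STATUS_FEATURES)
            + ["age_norm", "sex", "donor_relation", "comorbidity_count"]
        )

    _ENCODERS: dict[str, Callable[[PatientBaseline], float]] = {
        "age_norm": lambda b: b.age / 100.0,
        "comorbidity_count": lambda b: float(sum(b.comorbidity_flags)),
    }

    def __len__(self) -> int:
        return len(self.features)

    def status_slice(self) -> list[int]:
        """Positions of the four status flags inside the encoded vector."""
        return [self.features.index(f) for f in self.STATUS_FEATURES]

    def encode(self, baseline: PatientBaseline, status: StatusFlags) -> np.ndarray:
        out = np.empty(len(self.features))
        for i, name in enumerate(self.features):
            if name in self.STATUS_FEATURES:
                out[i] = float(getattr(status, name))
            elif name == "sex":
                try:
                    out[i] = SEX_CODES[baseline.sex]
                except KeyError:
                    raise ValueError(
                        f"cannot encode field 'sex': unknown category {baseline.sex!r}"
                    ) from None
            elif name == "donor_relation":
                out[i] = DONOR_RELATIONS.index(baseline.donor_relation)
            else:
                out[i] = self._ENCODERS[name](baseline)
        return out

    def to_json(self) -> dict:
        return {"features": self.features}

    @classmethod
    def from_json(cls, obj: dict) -> "FeatureSchema":
        return cls(obj["features"])


def encode_state(
    baseline: PatientBaseline,
    status: StatusFlags,
    stage_index: int,
    schema: Optional[FeatureSchema] = None,
) -> StateVector:
    """Deterministically encode a patient-stage into a fixed-length state vector."""
    schema = schema or FeatureSchema.default()
    return StateVector(schema.encode(baseline, status), stage_index)


def discounted_return(rewards: Sequence[float], gamma: float) -> float:
    """Discounted cumulative reward: sum_k gamma^k r_k over the sequence."""
    if not 0 < gamma <= 1:
        raise ValueError("gamma must lie in (0, 1]")
    rewards = np.asarray(list(rewards), dtype=float)
    if rewards.size == 0:
        return 0.0
    return float(np.sum(rewards * gamma ** np.arange(rewards.size)))


def build_action_codec(trajectories: Iterable[Trajectory]) -> ActionCodec:
    """Enumerate the distinct observed drug combinations, in first-observation order."""
    combos: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for traj in trajectories:
        for rec in traj.records:
            if rec.action is None:
                continue
            key = frozenset(rec.action.drug_set)
            if key not in seen:
                seen.add(key)
                combos.append(key)
    if not combos:
        raise ValueError("no treatment actions observed in the cohort")
    return ActionCodec(combos)


def low_variance_filter(feature_matrix: np.ndarray, threshold: float = 0.0) -> list[int]:
    """Indices of columns whose sample variance exceeds ``threshold``."""
    X = np.asarray(feature_matrix, dtype=float)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    ddof = 1 if X.shape[0] > 1 else 0
    variances = X.var(axis=0, ddof=ddof)
    return [i for i, v in enumerate(variances) if v > threshold]


def to_transitions(
    trajectory: Trajectory,
    codec: ActionCodec,
    schema: Optional[FeatureSchema] = None,
    stage_filter: Optional[set[int]] = None,
    rewards: RewardConfig = DEFAULT_REWARDS,
) -> list[Transition]:
    """Replay tuples (s_t, a_t, r_t, s_{t+1}) from one trajectory.

    One transition is emitted per consecutive record pair whose source stage
    index is in ``stage_filter`` (all stages if None) and whose source carries
    an action.  The reward is the immediate reward of the destination status;
    ``terminal`` is set on absorption (death/relapse) and ``truncated`` on
    reaching the final follow-up stage alive.
    """
    schema = schema or FeatureSchema.default()
    out: list[Transition] = []
    for src, dst in zip(trajectory.records, trajectory.records[1:]):
        if src.action is None:
            continue
        t = src.stage_index
        if stage_filter is not None and t not in stage_filter:
            continue
        idx = codec.index_of(src.action.drug_set)
        action = TreatmentAction(frozenset(src.action.drug_set), idx)
        s = encode_state(trajectory.baseline, src.status, t, schema)
        s_next = encode_state(trajectory.baseline, dst.status, dst.stage_index, schema)
        terminal = dst.status.terminal
        truncated = (not terminal) and dst.stage_index == len(STAGE_DAYS) - 1
        out.append(
            Transition(
                s=s,
                a=action,
                r=immediate_reward(dst.status, rewards),
                s_next=s_next,
                terminal=terminal,
                truncated=truncated,
            )
        )
    return out


def split_trajectories(
    trajectories: Sequence[Trajectory], test_fraction: float, seed: int
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Patient-level train/test partition, reproducible for a given seed."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    trajectories = list(trajectories)
    n = len(trajectories)
    if n < 2:
        raise ValueError("need at least 2 trajectories to split")
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [trajectories[i] for i in range(n) if i not in test_idx]
    test = [trajectories[i] for i in range(n) if i in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# Cohort I/O: long-format CSV plus a JSON sidecar for schema and action codec.


def _baseline_columns(b: PatientBaseline) -> dict:
    return {
        "age": b.age,
        "sex": b.sex,
        "donor_relation": b.donor_relation,
        "donor_sex": b.donor_sex,
        "comorbidities": ";".join(str(int(f)) for f in b.comorbidity_flags),
    }


def save_cohort(
    csv_path,
    trajectories: Sequence[Trajectory],
    schema: Optional[FeatureSchema] = None,
    codec: Optional[ActionCodec] = None,
) -> None:
    """Write a cohort as long-format CSV with a JSON sidecar (<path>.meta.json)."""
    import pandas as pd

    rows = []
    for traj in trajectories:
        base = _baseline_columns(traj.baseline)
        for rec in traj.records:
            rows.append(
                {
                    "patient_id": traj.patient_id,
                    "stage_time": rec.stage_time,
                    "alive": int(rec.status.alive),
                    "acute_gvhd": int(rec.status.acute_gvhd),
                    "chronic_gvhd": int(rec.status.chronic_gvhd),
                    "relapse": int(rec.status.relapse),
                    "drugs": ";".join(sorted(rec.action.drug_set)) if rec.action else "",
                    **base,
                }
            )
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "schema": (schema or FeatureSchema.default()).to_json(),
        "codec": codec.to_json() if codec is not None else None,
    }
    with open(f"{csv_path}.meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def load_cohort(
    csv_path, rewards: RewardConfig = DEFAULT_REWARDS
) -> tuple[list[Trajectory], FeatureSchema, Optional[ActionCodec]]:
    """Read a cohort written by :func:`save_cohort`; rewards are recomputed."""
    import pandas as pd

    df = pd.read_csv(csv_path, keep_default_na=False, float_precision="round_trip")
    with open(f"{csv_path}.meta.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    schema = FeatureSchema.from_json(meta["schema"])
    codec = ActionCodec.from_json(meta["codec"]) if meta.get("codec") else None

    trajectories = []
    for pid, group in df.groupby("patient_id", sort=False):
        group = group.sort_values("stage_time")
        first = group.iloc[0]
        comorb = tuple(
            int(x) for x in str(first["comorbidities"]).split(";") if x != ""
        )
        baseline = PatientBaseline(
            age=float(first["age"]),
            sex=str(first["sex"]),
            comorbidity_flags=comorb,
            donor_relation=str(first["donor_relation"]),
            donor_sex=str(first["donor_sex"]),
        )
        records = []
        for _, row in group.iterrows():
            status = StatusFlags(
                alive=bool(int(row["alive"])),
                acute_gvhd=bool(int(row["acute_gvhd"])),
                chronic_gvhd=bool(int(row["chronic_gvhd"])),
                relapse=bool(int(row["relapse"])),
            )
            drugs = str(row["drugs"])
            action = None
            if drugs:
                drug_set = frozenset(drugs.split(";"))
                idx = codec.index_of(drug_set) if codec is not None else -1
                action = TreatmentAction(drug_set, idx)
            records.append(
                StageRecord(
                    stage_time=int(row["stage_time"]),
                    status=status,
                    action=action,
                    reward_in=immediate_reward(status, rewards),
                )
            )
        traj = Trajectory(str(pid), baseline, records)
        traj.validate()
        trajectories.append(traj)
    return trajectories, schema, codec
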