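"""Task environment: trial sequences, reward rules, sessions.

A session is built from *units* of three trials, one of each type (A vs B,
C vs D, E vs F), randomly ordered within the unit. Rewards follow three rules:

- A vs B: choosing A pays 1 point immediately; B pays nothing.
- C vs D: never pays immediately; the choice (C -> reward, D -> none) is
  pushed onto a FIFO queue of pending outcomes.
- E vs F: pops the oldest pending outcome and pays it, whatever was touched.

The unit structure guarantees the pending queue never holds more than two
entries and every C choice is eventually paid, except possibly the last one
when the session's final C vs D trial falls after its final E vs F trial.

A session optionally terminates early once the participant chooses C in at
least ``criterion_threshold`` of ``bin_size`` consecutive C vs D trials for
``criterion_consecutive_bins`` consecutive bins (bins counted contiguously
from the start of the session).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "TrialType",
    "StimulusRole",
    "SessionConfig",
    "RewardQueue",
    "TrialRecord",
    "SessionLog",
    "CriterionTracker",
    "PolicyContractError",
    "generate_sequence",
    "run_session",
    "pending_depth_profile",
    "lag_distribution",
]


class TrialType(str, Enum):
    """The three stimulus pairs; doubles as the task state s(t)."""

    AB = "AB"
    CD = "CD"
    EF = "EF"

    @property
    def pair(self) -> tuple["StimulusRole", "StimulusRole"]:
        return _PAIRS[self]


class StimulusRole(str, Enum):
    """The six stimulus roles; the participant's choice a(t) is one of these."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"

    @property
    def trial_type(self) -> TrialType:
        return _ROLE_TYPE[self]

    @property
    def index(self) -> int:
        """Stable 0-based position (A=0 .. F=5), used by array-backed agents."""
        return _ROLE_INDEX[self]


_PAIRS = {
    TrialType.AB: (StimulusRole.A, StimulusRole.B),
    TrialType.CD: (StimulusRole.C, StimulusRole.D),
    TrialType.EF: (StimulusRole.E, StimulusRole.F),
}
_ROLE_TYPE = {role: tt for tt, pair in _PAIRS.items() for role in pair}
_ROLE_INDEX = {role: i for i, role in enumerate(StimulusRole)}
TRIAL_TYPES = (TrialType.AB, TrialType.CD, TrialType.EF)


class PolicyContractError(RuntimeError):
    """A policy returned a stimulus that is not part of the presented pair."""


@dataclass(frozen=True)
class SessionConfig:
    """Session-level parameters.

    Defaults reproduce the human experiment: 167 units (501 trials) with
    early termination once C is chosen >=8/10 in two consecutive bins of
    10 C vs D trials.
    """

    n_units: int = 167
    bin_size: int = 10
    criterion_threshold: int = 8
    criterion_consecutive_bins: int = 2
    termination_enabled: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError(f"n_units must be positive, got {self.n_units}")
        if self.bin_size < 1:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if not (1 <= self.criterion_threshold <= self.bin_size):
            raise ValueError(
                "criterion_threshold must be in [1, bin_size], got "
                f"{self.criterion_threshold} with bin_size={self.bin_size}"
            )
        if self.criterion_consecutive_bins < 1:
            raise ValueError("criterion_consecutive_bins must be positive")

    def replace(self, **kwargs) -> "SessionConfig":
        return replace(self, **kwargs)


class RewardQueue:
    """FIFO of pending delayed outcomes (True = C was chosen)."""

    def __init__(self) -> None:
        self._pending: deque[bool] = deque()

    def push(self, c_chosen: bool) -> None:
        self._pending.append(bool(c_chosen))

    def pop(self) -> Optional[bool]:
        """Consume the oldest entry; None if the queue is empty."""
        return self._pending.popleft() if self._pending else None

    def __len__(self) -> int:
        return len(self._pending)


@dataclass(frozen=True)
class TrialRecord:
    """One executed trial."""

    index: int  # 1-based position in the session
    unit_index: int  # 1-based unit number
    trial_type: TrialType
    choice: StimulusRole
    rewarded: int  # r(t), 0 or 1
    pending_before: int  # queue depth before this trial executed
    cumulative_points: int


@dataclass
class SessionLog:
    """A complete trial-by-trial record of one session."""

    config: SessionConfig
    trials: list[TrialRecord]
    terminated_early: bool = False
    termination_trial: Optional[int] = None
    participant_id: str = ""
    agent_meta: str = ""

    def __len__(self) -> int:
        return len(self.trials)

    def trials_of(self, trial_type: TrialType) -> list[TrialRecord]:
        return [t for t in self.trials if t.trial_type is trial_type]

    def choices_of(self, trial_type: TrialType) -> list[StimulusRole]:
        return [t.choice for t in self.trials if t.trial_type is trial_type]

    def indicators(self, target: StimulusRole) -> np.ndarray:
        """0/1 array over this target's trial type: was `target` chosen?"""
        return np.array(
            [int(t.choice is target) for t in self.trials if t.trial_type is target.trial_type],
            dtype=int,
        )

    @property
    def total_points(self) -> int:
        return self.trials[-1].cumulative_points if self.trials else 0


class CriterionTracker:
    """Online detector of the learning/termination criterion.

    Feed the choice made at every C vs D trial in order; `update` returns
    True at the trial completing the n-th consecutive qualifying bin.
    """

    def __init__(self, target: StimulusRole = StimulusRole.C, bin_size: int = 10,
                 threshold: int = 8, n_consecutive: int = 2) -> None:
        self.target = target
        self.bin_size = bin_size
        self.threshold = threshold
        self.n_consecutive = n_consecutive
        self._n_seen = 0
        self._bin_count = 0
        self._streak = 0
        self.met = False
        self.completing_trial: Optional[int] = None  # ordinal among CD trials
        self.qualifying_bins: Optional[tuple[int, ...]] = None

    def update(self, choice: StimulusRole) -> bool:
        if self.met:
            return True
        self._n_seen += 1
        if choice is self.target:
            self._bin_count += 1
        if self._n_seen % self.bin_size == 0:  # a bin just completed
            if self._bin_count >= self.threshold:
                self._streak += 1
            else:
                self._streak = 0
            self._bin_count = 0
            if self._streak >= self.n_consecutive:
                self.met = True
                self.completing_trial = self._n_seen
                last_bin = self._n_seen // self.bin_size
                self.qualifying_bins = tuple(
                    range(last_bin - self.n_consecutive + 1, last_bin + 1)
                )
        return self.met


def generate_sequence(n_units: int, rng: np.random.Generator) -> list[TrialType]:
    """Draw a quasi-random trial sequence of ``n_units`` three-trial units.

    Each consecutive block of three is an independent uniform permutation of
    {AB, CD, EF}, so every type appears exactly once per unit and exactly
    ``n_units`` times overall.
    """
    if n_units < 1:
        raise ValueError(f"n_units must be positive, got {n_units}")
    seq: list[TrialType] = []
    for _ in range(n_units):
        perm = rng.permutation(3)
        seq.extend(TRIAL_TYPES[i] for i in perm)
    return seq


Policy = Callable[[TrialType, Sequence[TrialRecord]], StimulusRole]


def run_session(
    policy: Policy,
    config: SessionConfig = SessionConfig(),
    rng: Optional[np.random.Generator] = None,
    participant_id: str = "",
    agent_meta: str = "",
    sequence: Optional[Sequence[TrialType]] = None,
) -> SessionLog:
    """Execute one session of the task against an arbitrary choice policy.

    The policy is called once per trial with the presented pair and the
    history of completed trials, and must return one of the pair's two
    roles. Sequence randomness comes from ``rng`` (or ``config.seed`` when
    ``rng`` is omitted); any randomness inside the policy is its own. An
    explicit ``sequence`` overrides generation (useful for scripted replays).
    """
    if sequence is None:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        sequence = generate_sequence(config.n_units, rng)
    queue = RewardQueue()
    tracker = CriterionTracker(
        bin_size=config.bin_size,
        threshold=config.criterion_threshold,
        n_consecutive=config.criterion_consecutive_bins,
    )
    trials: list[TrialRecord] = []
    points = 0
    terminated = False
    termination_trial: Optional[int] = None

    for i, trial_type in enumerate(sequence, start=1):
        choice = policy(trial_type, trials)
        if choice not in trial_type.pair:
            raise PolicyContractError(
                f"policy returned {choice.value} for a {trial_type.value} trial"
            )
        pending_before = len(queue)
        reward = _settle_reward(trial_type, choice, queue)
        points += reward
        trials.append(
            TrialRecord(
                index=i,
                unit_index=(i - 1) // 3 + 1,
                trial_type=trial_type,
                choice=choice,
                rewarded=reward,
                pending_before=pending_before,
                cumulative_points=points,
            )
        )
        if trial_type is TrialType.CD and tracker.update(choice) and config.termination_enabled:
            terminated = True
            termination_trial = i
            break

    return SessionLog(
        config=config,
        trials=trials,
        terminated_early=terminated,
        termination_trial=termination_trial,
        participant_id=participant_id,
        agent_meta=agent_meta,
    )


def _settle_reward(trial_type: TrialType, choice: StimulusRole, queue: RewardQueue) -> int:
    """Apply the reward rules for one trial, mutating the pending queue."""
    if trial_type is TrialType.AB:
        return int(choice is StimulusRole.A)
    if trial_type is TrialType.CD:
        queue.push(choice is StimulusRole.C)
        return 0
    head = queue.pop()  # EF: pay the oldest pending outcome, if any
    return int(bool(head))


def pending_depth_profile(sequence: Iterable[TrialType]) -> list[int]:
    """Queue depth before each trial under an always-choosing policy.

    Each CD trial enqueues one pending outcome and each EF trial consumes one
    (when any is pending); the unit structure bounds the depth at 2.
    """
    depths: list[int] = []
    depth = 0
    for trial_type in sequence:
        depths.append(depth)
        if trial_type is TrialType.CD:
            depth += 1
        elif trial_type is TrialType.EF and depth > 0:
            depth -= 1
    return depths


def lag_distribution(log: SessionLog) -> list[int]:
    """Trial lags between each C vs D trial and the E vs F trial paying it.

    Replays the FIFO over the logged trial sequence: for every CD trial whose
    pending entry was consumed, emits (EF index - CD index). Entries still
    pending at session end are omitted. On generated sequences every lag lies
    in {1, ..., 5}.
    """
    pending_idx: deque[int] = deque()
    lags: list[int] = []
    for t in log.trials:
        if t.trial_type is TrialType.CD:
            pending_idx.append(t.index)
        elif t.trial_type is TrialType.EF and pending_idx:
            lags.append(t.index - pending_idx.popleft())
    return lags
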