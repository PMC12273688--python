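"""Eligibility-trace reinforcement-learning agents.

Two model-free algorithms play the delayed-feedback task: actor-critic
(separate policy parameters q_X and state values v_s) and Q-learning (the
q values double as action values). Both choose by a softmax over the
presented pair,

    P{a(t) = X} = 1 / (1 + exp(beta * (q_Y - q_X))),

and propagate a reward-prediction error delta(t) to past actions through
eligibility traces

    eta_X(t) = lambda * eta_X(t-1) + 1{a(t) = X},
    q_X(t+1) = q_X(t) + alpha * eta_X(t) * delta(t),
    v_{X,Y}(t+1) = v_{X,Y}(t) + alpha * (eta_X(t) + eta_Y(t)) * delta(t),

with delta(t) = r(t) + gamma * v_{s(t+1)} - v_{s(t)} for actor-critic and
delta(t) = r(t) + gamma * max_{X in next pair} q_X(t) - q_{a(t)}(t) for
Q-learning. All quantities start at zero. Four canonical parameter presets
(slow_learning, high_exploration, short_trace, long_trace) span the regimes
in which the task is and is not solvable by such agents: only a long trace
(lambda = 0.5) lets the delayed outcome reach the C choice that caused it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from tracetask.task import (
    CriterionTracker,
    RewardQueue,
    SessionConfig,
    SessionLog,
    StimulusRole,
    TrialRecord,
    TrialType,
    _settle_reward,
    generate_sequence,
)

__all__ = [
    "AgentParams",
    "AgentState",
    "PRESETS",
    "softmax_prob",
    "update_traces",
    "rpe_actor_critic",
    "rpe_q_learning",
    "apply_updates",
    "agent_step",
    "run_agent_session",
]

ALGORITHMS = ("actor_critic", "q_learning")

# 0-based state index per trial type, aligned with StimulusRole.index // 2.
_STATE_INDEX = {TrialType.AB: 0, TrialType.CD: 1, TrialType.EF: 2}


@dataclass(frozen=True)
class AgentParams:
    """Learning parameters (alpha, beta, lambda, gamma) plus the algorithm."""

    algorithm: str
    alpha: float
    beta: float
    lam: float
    gamma: float = 0.5
    preset: Optional[str] = None  # name when built from a preset

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")
        if not 0 <= self.alpha <= 1:
            # alpha = 0 is the degenerate no-learning limit, kept legal so the
            # frozen-values sanity property can be exercised directly.
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if not 0 <= self.lam <= 1:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if not 0 <= self.gamma <= 1:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")

    @classmethod
    def from_preset(cls, name: str, algorithm: str) -> "AgentParams":
        try:
            alpha, beta, lam = PRESETS[name]
        except KeyError:
            raise ValueError(f"unknown preset {name!r}; expected one of {sorted(PRESETS)}") from None
        return cls(algorithm=algorithm, alpha=alpha, beta=beta, lam=lam, gamma=0.5, preset=name)


#: The four canonical (alpha, beta, lambda) presets; gamma = 0.5 for all.
PRESETS: dict[str, tuple[float, float, float]] = {
    "slow_learning": (0.001, 4.0, 0.5),
    "high_exploration": (0.1, 0.01, 0.5),
    "short_trace": (0.1, 4.0, 0.01),
    "long_trace": (0.1, 4.0, 0.5),
}


@dataclass
class AgentState:
    """Evolving agent variables: q_X (6), eligibility traces eta_X (6), v_s (3)."""

    q: np.ndarray = field(default_factory=lambda: np.zeros(6))
    eta: np.ndarray = field(default_factory=lambda: np.zeros(6))
    v: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def copy(self) -> "AgentState":
        return AgentState(self.q.copy(), self.eta.copy(), self.v.copy())


def softmax_prob(q_first: float, q_second: float, beta: float) -> float:
    """Probability of choosing the first option of a pair.

    Computed as a logistic in beta * (q_first - q_second); saturates instead
    of overflowing for extreme arguments. beta = 0 gives 0.5 always.
    """
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    return float(expit(beta * (q_first - q_second)))


def update_traces(state: AgentState, chosen: StimulusRole, lam: float) -> AgentState:
    """Decay all six traces by lam, then add 1 to the chosen role's trace."""
    out = state.copy()
    out.eta *= lam
    out.eta[chosen.index] += 1.0
    return out


def rpe_actor_critic(r: int, v_current: float, v_next: float, gamma: float) -> float:
    """delta = r + gamma * v(next state) - v(current state)."""
    return r + gamma * v_next - v_current


def rpe_q_learning(r: int, q_chosen: float, q_next_max: float, gamma: float) -> float:
    """delta = r + gamma * max over next pair's q - q(chosen), pre-update values."""
    return r + gamma * q_next_max - q_chosen


def apply_updates(state: AgentState, delta: float, alpha: float) -> AgentState:
    """Credit delta to every role and state in proportion to its trace mass."""
    out = state.copy()
    out.q += alpha * out.eta * delta
    out.v += alpha * (out.eta[0::2] + out.eta[1::2]) * delta
    return out


def agent_step(
    state: AgentState,
    trial_type: TrialType,
    next_trial_type: Optional[TrialType],
    params: AgentParams,
    rng: np.random.Generator,
    reward_fn,
) -> tuple[StimulusRole, AgentState]:
    """One full trial: choose, observe reward, update traces, compute delta, learn.

    ``reward_fn(trial_type, choice)`` is the environment callback returning
    r(t). delta uses pre-update q/v; on the final trial (``next_trial_type``
    is None) the next-state term is taken as 0.
    """
    first, second = trial_type.pair
    p_first = softmax_prob(state.q[first.index], state.q[second.index], params.beta)
    choice = first if rng.random() < p_first else second
    r = reward_fn(trial_type, choice)

    new_state = update_traces(state, choice, params.lam)
    if params.algorithm == "actor_critic":
        v_next = 0.0 if next_trial_type is None else float(state.v[_STATE_INDEX[next_trial_type]])
        delta = rpe_actor_critic(r, float(state.v[_STATE_INDEX[trial_type]]), v_next, params.gamma)
    else:
        if next_trial_type is None:
            q_next_max = 0.0
        else:
            nf, ns = next_trial_type.pair
            q_next_max = float(max(state.q[nf.index], state.q[ns.index]))
        delta = rpe_q_learning(r, float(state.q[choice.index]), q_next_max, params.gamma)
    new_state = apply_updates(new_state, delta, params.alpha)
    return choice, new_state


def run_agent_session(
    params: AgentParams,
    config: Optional[SessionConfig] = None,
    rng: Optional[np.random.Generator] = None,
    participant_id: str = "",
) -> SessionLog:
    """Run one agent through a full session and return its log.

    Defaults to the simulation protocol: 160 units (480 trials) with the
    termination criterion disabled. A single random stream drives both the
    trial sequence and the softmax draws, so a fixed seed reproduces the
    session exactly.
    """
    if config is None:
        config = SessionConfig(n_units=160, termination_enabled=False, seed=None)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sequence = generate_sequence(config.n_units, rng)
    n = len(sequence)

    queue = RewardQueue()
    tracker = CriterionTracker(
        bin_size=config.bin_size,
        threshold=config.criterion_threshold,
        n_consecutive=config.criterion_consecutive_bins,
    )
    state = AgentState()
    trials: list[TrialRecord] = []
    points = 0
    terminated = False
    termination_trial: Optional[int] = None

    last_reward = [0]

    def reward_fn(trial_type: TrialType, choice: StimulusRole) -> int:
        last_reward[0] = _settle_reward(trial_type, choice, queue)
        return last_reward[0]

    meta = f"algorithm={params.algorithm} preset={params.preset or 'custom'} seed={config.seed}"
    for i, trial_type in enumerate(sequence, start=1):
        next_type = sequence[i] if i < n else None
        pending_before = len(queue)
        choice, state = agent_step(state, trial_type, next_type, params, rng, reward_fn)
        points += last_reward[0]
        trials.append(
            TrialRecord(
                index=i,
                unit_index=(i - 1) // 3 + 1,
                trial_type=trial_type,
                choice=choice,
                rewarded=last_reward[0],
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
        agent_meta=meta,
    )
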