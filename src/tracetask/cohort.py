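"""Synthetic participant cohorts with ground-truth behavioural archetypes.

Human cohorts on this task are strikingly heterogeneous: some participants
learn to choose C and hit the termination criterion, some perseverate on the
never-rewarded D, many develop a superstitious preference for E or F (which
never causes reward), and nearly everyone rapidly learns A over B. The
archetypes here are stylised scripted policies reproducing those patterns so
the classification pipeline can be validated against known labels. The
default choice probabilities are package choices (tuned for statistical
power at the default session length), not measured human values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from tracetask.task import (
    Policy,
    SessionConfig,
    SessionLog,
    StimulusRole,
    TrialRecord,
    TrialType,
    run_session,
)

__all__ = ["ArchetypeSpec", "CohortSpec", "ARCHETYPES", "archetype_policy", "generate_cohort"]

ARCHETYPE_NAMES = (
    "c_learner",
    "d_perseverator",
    "e_superstitious",
    "f_superstitious",
    "random_chooser",
    "immediate_only",
)


@dataclass(frozen=True)
class ArchetypeSpec:
    """A scripted participant: independent per-pair choice probabilities.

    ``p_C`` may ramp from ``p_C_start`` to ``p_C`` after the ``ramp_switch``-th
    C vs D trial, modelling a participant who discovers the delayed
    contingency partway through the session.
    """

    name: str
    p_A: float = 0.5
    p_C: float = 0.5
    p_E: float = 0.5
    p_C_start: Optional[float] = None  # None = flat p_C throughout
    ramp_switch: int = 30  # last CD trial still using p_C_start
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for label, p in (("p_A", self.p_A), ("p_C", self.p_C), ("p_E", self.p_E)):
            if not 0 <= p <= 1:
                raise ValueError(f"{label} must be in [0, 1], got {p}")
        if self.p_C_start is not None and not 0 <= self.p_C_start <= 1:
            raise ValueError(f"p_C_start must be in [0, 1], got {self.p_C_start}")

    def p_c_at(self, cd_ordinal: int) -> float:
        """C-choice probability at the cd_ordinal-th C vs D trial (1-based)."""
        if self.p_C_start is not None and cd_ordinal <= self.ramp_switch:
            return self.p_C_start
        return self.p_C


#: Default archetype parameterisations (package choices, not human estimates).
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "c_learner": ArchetypeSpec("c_learner", p_A=0.95, p_C=0.95, p_E=0.5, p_C_start=0.5, ramp_switch=30),
    "d_perseverator": ArchetypeSpec("d_perseverator", p_A=0.95, p_C=0.15, p_E=0.5),
    "e_superstitious": ArchetypeSpec("e_superstitious", p_A=0.95, p_C=0.5, p_E=0.9),
    "f_superstitious": ArchetypeSpec("f_superstitious", p_A=0.95, p_C=0.5, p_E=0.1),
    "random_chooser": ArchetypeSpec("random_chooser", p_A=0.5, p_C=0.5, p_E=0.5),
    "immediate_only": ArchetypeSpec("immediate_only", p_A=0.95, p_C=0.5, p_E=0.5),
}


def archetype_policy(spec: ArchetypeSpec, rng: Optional[np.random.Generator] = None) -> Policy:
    """Build the scripted choice policy for an archetype.

    Every choice is drawn independently with the spec's per-pair
    probabilities; the C probability may ramp by C-vs-D trial count. The
    policy keeps its own random stream (``spec.seed`` unless ``rng`` given).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    def policy(trial_type: TrialType, history: Sequence[TrialRecord]) -> StimulusRole:
        first, second = trial_type.pair
        if trial_type is TrialType.AB:
            p_first = spec.p_A
        elif trial_type is TrialType.CD:
            cd_ordinal = 1 + sum(t.trial_type is TrialType.CD for t in history)
            p_first = spec.p_c_at(cd_ordinal)
        else:
            p_first = spec.p_E
        return first if rng.random() < p_first else second

    return policy


@dataclass(frozen=True)
class CohortSpec:
    """A cohort: archetype counts, a shared session config, one master seed.

    Per-participant seeds are spawned deterministically from the master seed
    by participant ordinal, so adding participants to the composition never
    reshuffles the sessions of existing ones.
    """

    composition: tuple[tuple[str, int], ...]
    config: SessionConfig = field(default_factory=SessionConfig)
    master_seed: int = 0

    @classmethod
    def from_counts(cls, counts: dict[str, int], config: Optional[SessionConfig] = None,
                    master_seed: int = 0) -> "CohortSpec":
        for name, n in counts.items():
            if name not in ARCHETYPES:
                raise ValueError(f"unknown archetype {name!r}; expected one of {ARCHETYPE_NAMES}")
            if n < 0:
                raise ValueError(f"count for {name!r} must be non-negative, got {n}")
        return cls(
            composition=tuple(counts.items()),
            config=config or SessionConfig(),
            master_seed=master_seed,
        )


def generate_cohort(spec: CohortSpec) -> list[tuple[SessionLog, str]]:
    """Simulate every participant; returns (session log, archetype label) pairs.

    Sessions run through :func:`tracetask.task.run_session` with the spec's
    config (termination enabled by default). Each participant gets two
    independent child streams spawned from the master seed — one for the
    trial sequence, one for the policy — keyed by participant ordinal.
    """
    out: list[tuple[SessionLog, str]] = []
    ordinal = 0
    for name, count in spec.composition:
        base = ARCHETYPES[name]
        for _ in range(count):
            seq_rng, pol_rng = (
                np.random.default_rng(s)
                for s in np.random.SeedSequence([spec.master_seed, ordinal]).spawn(2)
            )
            pid = f"{name}_{ordinal:03d}"
            policy = archetype_policy(base, rng=pol_rng)
            log = run_session(
                policy,
                config=spec.config,
                rng=seq_rng,
                participant_id=pid,
                agent_meta=f"archetype={name} master_seed={spec.master_seed} ordinal={ordinal}",
            )
            out.append((log, name))
            ordinal += 1
    return out
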