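import numpy as np
import pytest

from tracetask.task import StimulusRole, TrialRecord, TrialType


def always(role: StimulusRole):
    """Policy that always picks `role` on its own pair, first role elsewhere."""

    def policy(trial_type, history):
        first, second = trial_type.pair
        if role in (first, second):
            return role
        return first

    return policy


def coin_policy(rng: np.random.Generator):
    """Fair-coin policy over each presented pair."""

    def policy(trial_type, history):
        first, second = trial_type.pair
        return first if rng.random() < 0.5 else second

    return policy


def brute_force_rewards(trial_types, choices):
    """Independent replay of the reward rules by full-history scanning.

    For every EF trial, scans the entire history for the earliest C vs D
    trial not yet consumed by a previous EF trial, and pays its outcome.
    Never uses a queue; the data structure under test is avoided on purpose.
    """
    rewards = []
    consumed = set()
    for i, (tt, choice) in enumerate(zip(trial_types, choices)):
        if tt is TrialType.AB:
            rewards.append(int(choice is StimulusRole.A))
        elif tt is TrialType.CD:
            rewards.append(0)
        else:
            pending = [
                j
                for j in range(i)
                if trial_types[j] is TrialType.CD and j not in consumed
            ]
            if pending:
                j = min(pending)
                consumed.add(j)
                rewards.append(int(choices[j] is StimulusRole.C))
            else:
                rewards.append(0)
    return rewards


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
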