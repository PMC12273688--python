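"""CSV interchange, config parsing and run manifests.

Session logs travel as comma-separated UTF-8 text with a mandatory header:

    participant_id, trial, unit, pair, choice, rewarded, pending_before, points_cum

``pair`` is one of AB/CD/EF, ``choice`` one of A–F belonging to the pair,
``rewarded`` 0/1. Reading re-validates every trial invariant (contiguous
1-based indices, in-pair choices, reward rules, running point totals) and
rejects malformed files naming the offending row.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from tracetask.task import SessionConfig, SessionLog, StimulusRole, TrialRecord, TrialType

__all__ = [
    "SessionLogFormatError",
    "LOG_COLUMNS",
    "write_session_log",
    "read_session_log",
    "parse_session_config",
    "load_session_config",
    "RunManifest",
    "write_manifest",
]

LOG_COLUMNS = [
    "participant_id",
    "trial",
    "unit",
    "pair",
    "choice",
    "rewarded",
    "pending_before",
    "points_cum",
]


class SessionLogFormatError(ValueError):
    """A session-log file violates the documented format or a trial invariant."""


def write_session_log(log: SessionLog, path: Union[str, Path]) -> None:
    rows = [
        {
            "participant_id": log.participant_id,
            "trial": t.index,
            "unit": t.unit_index,
            "pair": t.trial_type.value,
            "choice": t.choice.value,
            "rewarded": t.rewarded,
            "pending_before": t.pending_before,
            "points_cum": t.cumulative_points,
        }
        for t in log.trials
    ]
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(path, index=False)


def read_session_log(path: Union[str, Path], config: Optional[SessionConfig] = None) -> SessionLog:
    """Load and fully re-validate a session-log CSV.

    ``config`` supplies the session parameters the log was produced under
    (defaults are used otherwise); termination status is inferred from the
    trial count.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.EmptyDataError:
        raise SessionLogFormatError(f"{path}: empty file") from None
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SessionLogFormatError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise SessionLogFormatError(f"{path}: no trials")

    config = config or SessionConfig()
    trials: list[TrialRecord] = []
    points = 0
    queue: list[bool] = []  # replay of the pending-outcome FIFO
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        where = f"{path} row {pos}"
        if int(row.trial) != pos:
            raise SessionLogFormatError(f"{where}: non-contiguous trial index {row.trial}")
        try:
            pair = TrialType(row.pair)
            choice = StimulusRole(row.choice)
        except ValueError as exc:
            raise SessionLogFormatError(f"{where}: {exc}") from None
        if choice not in pair.pair:
            raise SessionLogFormatError(f"{where}: choice {choice.value} not in pair {pair.value}")
        rewarded = int(row.rewarded)
        if rewarded not in (0, 1):
            raise SessionLogFormatError(f"{where}: rewarded must be 0/1, got {row.rewarded}")
        if pair is TrialType.CD and rewarded:
            raise SessionLogFormatError(f"{where}: a CD trial can never be rewarded")
        if pair is TrialType.AB and rewarded != int(choice is StimulusRole.A):
            raise SessionLogFormatError(f"{where}: AB reward must equal 1[choice == A]")
        if pair is TrialType.CD:
            queue.append(choice is StimulusRole.C)
        elif pair is TrialType.EF:
            due = int(queue.pop(0)) if queue else 0
            if rewarded != due:
                raise SessionLogFormatError(
                    f"{where}: EF reward {rewarded} contradicts the pending outcome {due}"
                )
        pending = int(row.pending_before)
        if not 0 <= pending <= 2:
            raise SessionLogFormatError(f"{where}: pending_before out of range: {pending}")
        points += rewarded
        if int(row.points_cum) != points:
            raise SessionLogFormatError(
                f"{where}: points_cum {row.points_cum} != running total {points}"
            )
        trials.append(
            TrialRecord(
                index=pos,
                unit_index=int(row.unit),
                trial_type=pair,
                choice=choice,
                rewarded=rewarded,
                pending_before=pending,
                cumulative_points=points,
            )
        )

    n_expected = 3 * config.n_units
    terminated = len(trials) < n_expected
    return SessionLog(
        config=config,
        trials=trials,
        terminated_early=terminated,
        termination_trial=trials[-1].index if terminated else None,
        participant_id=str(df["participant_id"].iloc[0]),
    )


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SessionConfig)}


def parse_session_config(doc: dict) -> SessionConfig:
    """Build a SessionConfig from a JSON-compatible mapping; unknown keys error."""
    unknown = set(doc) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown session-config key(s): {sorted(unknown)}")
    return SessionConfig(**doc)


def load_session_config(path: Union[str, Path]) -> SessionConfig:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: session config must be a JSON object")
    return parse_session_config(doc)


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a CLI run byte-for-byte."""

    command: str
    config: dict
    master_seed: Optional[int]
    session_seeds: tuple
    version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, config: dict, master_seed: Optional[int],
               session_seeds=()) -> "RunManifest":
        from tracetask import __version__

        return cls(
            command=command,
            config=config,
            master_seed=master_seed,
            session_seeds=tuple(session_seeds),
            version=__version__,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )


def write_manifest(manifest: RunManifest, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, default=str)
        fh.write("\n")
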