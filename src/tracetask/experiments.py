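"""The simulation grid: algorithms x parameter presets, many seeded runs.

Protocol: each run is a 480-trial session (160 units, 16 bins of 10 trials
per pair type) with the termination criterion disabled, repeated 200 times
per algorithm/preset cell. Each run is summarised by the choice counts of
A, C and E in the final 10-trial bin of each pair type and by the weighted
choice rates P_A, P_C, P_E over the last 30 trials of each type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from tracetask.agents import ALGORITHMS, PRESETS, AgentParams, run_agent_session
from tracetask.analysis import ChoiceRateSpec, ChoiceRates, choice_rates
from tracetask.task import SessionConfig, SessionLog, StimulusRole, TrialType

__all__ = ["GridSpec", "RunSummary", "run_grid", "summarize_final_bin", "scatter_summary"]


@dataclass(frozen=True)
class GridSpec:
    """Which cells to simulate and at what size."""

    algorithms: tuple[str, ...] = ALGORITHMS
    presets: tuple[str, ...] = tuple(PRESETS)
    n_runs: int = 200
    n_units: int = 160
    master_seed: int = 0

    def __post_init__(self) -> None:
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {a!r}")
        for p in self.presets:
            if p not in PRESETS:
                raise ValueError(f"unknown preset {p!r}; expected one of {sorted(PRESETS)}")
        if self.n_runs < 1 or self.n_units < 1:
            raise ValueError("n_runs and n_units must be positive")


@dataclass(frozen=True)
class RunSummary:
    """One simulated session, reduced to its end-of-session behaviour."""

    algorithm: str
    preset: str
    run: int
    seed: int
    count_A: int  # A choices in the final 10-trial AB bin
    count_C: int
    count_E: int
    rates: ChoiceRates


def run_grid(spec: GridSpec = GridSpec(), keep_logs: bool = False):
    """Simulate the full grid; one RunSummary per session.

    Per-run seeds are derived deterministically from the master seed and the
    (algorithm, preset, run) coordinates, so partial grids reproduce the
    corresponding cells of the full grid exactly. Returns the list of
    summaries, plus the session logs when ``keep_logs`` is set.
    """
    config = SessionConfig(n_units=spec.n_units, termination_enabled=False)
    summaries: list[RunSummary] = []
    logs: list[SessionLog] = []
    for algorithm in spec.algorithms:
        for preset in spec.presets:
            params = AgentParams.from_preset(preset, algorithm)
            for run in range(spec.n_runs):
                ss = np.random.SeedSequence(
                    [spec.master_seed, ALGORITHMS.index(algorithm), sorted(PRESETS).index(preset), run]
                )
                seed = int(ss.generate_state(1)[0] % (2**31))
                rng = np.random.default_rng(ss)
                log = run_agent_session(
                    params, config=config, rng=rng, participant_id=f"{algorithm}_{preset}_{run:03d}"
                )
                a, c, e = summarize_final_bin(log)
                summaries.append(
                    RunSummary(
                        algorithm=algorithm,
                        preset=preset,
                        run=run,
                        seed=seed,
                        count_A=a,
                        count_C=c,
                        count_E=e,
                        rates=choice_rates(log),
                    )
                )
                if keep_logs:
                    logs.append(log)
    return (summaries, logs) if keep_logs else summaries


def summarize_final_bin(log: SessionLog, bin_size: int = 10) -> tuple[int, int, int]:
    """Counts of A, C, E choices in the last full bin of each pair type."""
    counts = []
    for role in (StimulusRole.A, StimulusRole.C, StimulusRole.E):
        ind = log.indicators(role)
        if ind.size < bin_size:
            raise ValueError(
                f"need at least {bin_size} {role.trial_type.value} trials, got {ind.size}"
            )
        n_full = ind.size // bin_size
        counts.append(int(ind[(n_full - 1) * bin_size : n_full * bin_size].sum()))
    return tuple(counts)


def summaries_frame(summaries: Iterable[RunSummary]) -> pd.DataFrame:
    """Flatten RunSummary objects into a tidy table."""
    return pd.DataFrame(
        {
            "algorithm": s.algorithm,
            "preset": s.preset,
            "run": s.run,
            "seed": s.seed,
            "count_A": s.count_A,
            "count_C": s.count_C,
            "count_E": s.count_E,
            "p_A": s.rates.p_A,
            "p_C": s.rates.p_C,
            "p_E": s.rates.p_E,
        }
        for s in summaries
    )


def scatter_summary(
    summaries: Sequence[RunSummary],
    human_rates: Optional[pd.DataFrame] = None,
) -> dict[str, pd.DataFrame]:
    """Paired choice-rate coordinates for the (P_C, P_A) and (P_C, P_E) panels.

    Returns per-panel tables of simulated points (keyed by algorithm and
    preset); when ``human_rates`` (columns p_A, p_C, p_E, optionally
    report_category) is supplied it is carried through unchanged under the
    'human' key for overlaying.
    """
    if not summaries:
        raise ValueError("scatter_summary requires at least one run summary")
    df = summaries_frame(summaries)
    out = {
        "pc_pa": df[["algorithm", "preset", "run", "p_C", "p_A"]].copy(),
        "pc_pe": df[["algorithm", "preset", "run", "p_C", "p_E"]].copy(),
    }
    if human_rates is not None:
        missing = {"p_A", "p_C", "p_E"} - set(human_rates.columns)
        if missing:
            raise ValueError(f"human_rates is missing columns {sorted(missing)}")
        out["human"] = human_rates.copy()
    return out


def plot_scatter(panels: dict[str, pd.DataFrame], path: Optional[str] = None):
    """Render the two scatter panels; writes a PNG when ``path`` is given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4.2), sharex=True)
    for ax, key, ylab in zip(axes, ("pc_pa", "pc_pe"), ("$P_A$", "$P_E$")):
        df = panels[key]
        ycol = "p_A" if key == "pc_pa" else "p_E"
        for (alg, preset), grp in df.groupby(["algorithm", "preset"]):
            ax.scatter(grp["p_C"], grp[ycol], s=6, alpha=0.4, label=f"{alg}/{preset}")
        if "human" in panels:
            h = panels["human"]
            ax.scatter(h["p_C"], h[ycol], s=30, facecolors="none",
                       edgecolors="k", label="human")
        ax.set_xlabel("$P_C$")
        ax.set_ylabel(ylab)
        ax.set_xlim(-0.02, 1.02)
        ax.set_ylim(-0.02, 1.02)
    axes[0].legend(fontsize=6, loc="lower left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
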