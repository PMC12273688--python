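"""Per-participant behavioural statistics and the six-criterion classification.

For each session the battery computes, per the study conventions (alpha =
0.05, two-tailed, no multiplicity adjustment):

1. learning criterion for C (>=8/10 in two consecutive bins of C vs D trials);
2. the same criterion for D;
3. overall C-vs-D bias (exact binomial test against 0.5);
4. change in C choice between session halves (2x2 chi-square, by default with
   continuity correction, matching R's ``chisq.test``);
5. overall E-vs-F bias (exact binomial test);
6. association between E/F choice and the apparently immediate delayed reward
   (Fisher's exact test).

Final choice tendencies are summarised by exponentially weighted choice rates
P_X over the last 30 trials of each pair type (decay 0.9 per trial back).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tracetask.task import SessionLog, StimulusRole, TrialType

__all__ = [
    "ChoiceRateSpec",
    "ChoiceRates",
    "CriterionResult",
    "TestResult",
    "ClassificationRecord",
    "REPORT_CATEGORIES",
    "weighted_choice_rate",
    "choice_rates",
    "detect_criterion",
    "overall_bias_test",
    "halves_change_test",
    "immediate_reward_association_test",
    "classify_participant",
    "cohort_table",
]

ALPHA = 0.05
REPORT_CATEGORIES = ("full", "partial", "none", "not_available")


@dataclass(frozen=True)
class ChoiceRateSpec:
    """Exponential weighting of the last `window` trials of one pair type."""

    decay: float = 0.9
    window: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.decay < 1:
            raise ValueError(f"decay must be in (0, 1), got {self.decay}")
        if self.window < 1:
            raise ValueError(f"window must be positive, got {self.window}")


@dataclass(frozen=True)
class ChoiceRates:
    """End-of-session weighted choice rates P_A, P_C, P_E."""

    p_A: float
    p_C: float
    p_E: float


@dataclass(frozen=True)
class CriterionResult:
    met: bool
    completing_trial: Optional[int] = None  # ordinal among that pair's trials
    qualifying_bins: Optional[tuple[int, ...]] = None  # 1-based bin indices


@dataclass(frozen=True)
class TestResult:
    """One statistical test: the effect summary, its direction and p-value."""

    statistic: float  # fraction or test statistic, see each test
    direction: Optional[str]
    p_value: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return not self.degenerate and self.p_value < ALPHA


@dataclass(frozen=True)
class ClassificationRecord:
    """One participant's row of the six-criterion table."""

    participant_id: str
    report_category: str
    c_criterion: CriterionResult
    d_criterion: CriterionResult
    overall_c: TestResult  # statistic = fraction of C among C vs D trials
    half_change: TestResult  # direction: increase/decrease of C in 2nd half
    ef_bias: TestResult  # statistic = fraction of E among E vs F trials
    immediate_reward: TestResult  # direction: E/F enriched for reward
    rates: Optional[ChoiceRates] = None


def weighted_choice_rate(indicators: Sequence[int], spec: ChoiceRateSpec = ChoiceRateSpec()) -> float:
    """Exponentially weighted average of 0/1 choice indicators.

    Uses the last ``min(window, len)`` entries with weights decay^tau
    (tau = 0 at the most recent trial), normalised to sum to one.
    """
    x = np.asarray(indicators, dtype=float)
    if x.size == 0:
        raise ValueError("weighted_choice_rate requires a non-empty series")
    w = min(spec.window, x.size)
    weights = spec.decay ** np.arange(w)
    return float(np.dot(weights, x[::-1][:w]) / weights.sum())


def choice_rates(log: SessionLog, spec: ChoiceRateSpec = ChoiceRateSpec()) -> ChoiceRates:
    """P_A, P_C, P_E over the last `window` trials of each pair type."""
    return ChoiceRates(
        p_A=weighted_choice_rate(log.indicators(StimulusRole.A), spec),
        p_C=weighted_choice_rate(log.indicators(StimulusRole.C), spec),
        p_E=weighted_choice_rate(log.indicators(StimulusRole.E), spec),
    )


def detect_criterion(
    choices: Sequence[StimulusRole],
    target: StimulusRole,
    bin_size: int = 10,
    threshold: int = 8,
    n_consecutive: int = 2,
) -> CriterionResult:
    """Detect >=threshold target choices in n_consecutive successive full bins.

    Bins are non-overlapping blocks of ``bin_size`` trials of one pair type,
    counted from the start; a trailing partial bin never qualifies. Returns
    the first occurrence: ``completing_trial`` is the ordinal (within this
    pair type) of the trial ending the last qualifying bin.
    """
    n_bins = len(choices) // bin_size
    streak = 0
    for b in range(n_bins):
        count = sum(c is target for c in choices[b * bin_size : (b + 1) * bin_size])
        streak = streak + 1 if count >= threshold else 0
        if streak >= n_consecutive:
            return CriterionResult(
                met=True,
                completing_trial=(b + 1) * bin_size,
                qualifying_bins=tuple(range(b - n_consecutive + 2, b + 2)),
            )
    return CriterionResult(met=False)


def overall_bias_test(n_target: int, n_total: int) -> TestResult:
    """Exact two-sided binomial test of the target-choice count against 0.5.

    Two-sided by the point-probability method (the sum of all outcome
    probabilities no larger than the observed one), the convention of R's
    ``binom.test``. ``statistic`` is the sample fraction.
    """
    if not 0 <= n_target <= n_total:
        raise ValueError(f"need 0 <= n_target <= n_total, got {n_target}/{n_total}")
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    p = stats.binomtest(n_target, n_total, 0.5, alternative="two-sided").pvalue
    frac = n_target / n_total
    direction = "above" if frac > 0.5 else ("below" if frac < 0.5 else None)
    return TestResult(statistic=frac, direction=direction, p_value=float(p))


def halves_change_test(
    first_half: tuple[int, int],
    second_half: tuple[int, int],
    continuity_correction: bool = True,
) -> TestResult:
    """2x2 chi-square test of C-vs-D choice by session half.

    ``first_half`` and ``second_half`` are (n_C, n_D) counts. Direction is
    'increase' when the second-half C fraction exceeds the first-half one.
    A zero marginal (all C or all D overall, or an empty half) makes the
    test undefined; the result is then flagged degenerate with p = 1.
    """
    table = np.array([first_half, second_half], dtype=float)
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    f1 = first_half[0] / row_sums[0] if row_sums[0] else np.nan
    f2 = second_half[0] / row_sums[1] if row_sums[1] else np.nan
    direction = None
    if np.isfinite(f1) and np.isfinite(f2) and f1 != f2:
        direction = "increase" if f2 > f1 else "decrease"
    if (row_sums == 0).any() or (col_sums == 0).any():
        return TestResult(statistic=0.0, direction=direction, p_value=1.0, degenerate=True)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return TestResult(statistic=float(chi2), direction=direction, p_value=float(p))


def immediate_reward_association_test(
    ef_choices: Sequence[StimulusRole],
    ef_rewards: Sequence[int],
) -> TestResult:
    """Fisher's exact test of reward arrival by E/F choice.

    Builds the 2x2 table (choice E/F x rewarded yes/no) from the apparent
    immediate rewards delivered at E vs F trials, and reports which stimulus
    was enriched for reward. ``statistic`` is the table's odds ratio.
    """
    if len(ef_choices) != len(ef_rewards):
        raise ValueError("choices and rewards must have equal length")
    if len(ef_choices) == 0:
        raise ValueError("immediate_reward_association_test requires a non-empty input")
    if any(c not in (StimulusRole.E, StimulusRole.F) for c in ef_choices):
        raise ValueError("ef_choices must contain only E or F")
    e_rew = sum(r for c, r in zip(ef_choices, ef_rewards) if c is StimulusRole.E)
    e_tot = sum(1 for c in ef_choices if c is StimulusRole.E)
    f_rew = sum(r for c, r in zip(ef_choices, ef_rewards) if c is StimulusRole.F)
    f_tot = len(ef_choices) - e_tot
    table = [[e_rew, e_tot - e_rew], [f_rew, f_tot - f_rew]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    rate_e = e_rew / e_tot if e_tot else np.nan
    rate_f = f_rew / f_tot if f_tot else np.nan
    direction = None
    if np.isfinite(rate_e) and np.isfinite(rate_f) and rate_e != rate_f:
        direction = "E" if rate_e > rate_f else "F"
    degenerate = e_tot == 0 or f_tot == 0
    return TestResult(
        statistic=float(odds) if math.isfinite(odds) else float("inf"),
        direction=direction,
        p_value=float(p),
        degenerate=degenerate,
    )


def classify_participant(
    log: SessionLog,
    report_category: str = "not_available",
    continuity_correction: bool = True,
    rate_spec: ChoiceRateSpec = ChoiceRateSpec(),
) -> ClassificationRecord:
    """Assemble one participant's six-criterion classification row.

    The halves test splits the C vs D trials of the session at the midpoint
    of their own presentation order (first ceil(n/2) trials vs the rest).
    """
    if report_category not in REPORT_CATEGORIES:
        raise ValueError(f"report_category must be one of {REPORT_CATEGORIES}")
    cfg = log.config
    cd_choices = log.choices_of(TrialType.CD)
    ef_trials = log.trials_of(TrialType.EF)

    c_crit = detect_criterion(
        cd_choices, StimulusRole.C, cfg.bin_size, cfg.criterion_threshold, cfg.criterion_consecutive_bins
    )
    d_crit = detect_criterion(
        cd_choices, StimulusRole.D, cfg.bin_size, cfg.criterion_threshold, cfg.criterion_consecutive_bins
    )

    n_c = sum(c is StimulusRole.C for c in cd_choices)
    overall_c = overall_bias_test(n_c, len(cd_choices)) if cd_choices else _not_computable()

    split = (len(cd_choices) + 1) // 2
    if split and len(cd_choices) - split:
        first = cd_choices[:split]
        second = cd_choices[split:]
        half_change = halves_change_test(
            (sum(c is StimulusRole.C for c in first), sum(c is StimulusRole.D for c in first)),
            (sum(c is StimulusRole.C for c in second), sum(c is StimulusRole.D for c in second)),
            continuity_correction=continuity_correction,
        )
    else:
        half_change = _not_computable()

    n_e = sum(t.choice is StimulusRole.E for t in ef_trials)
    ef_bias = overall_bias_test(n_e, len(ef_trials)) if ef_trials else _not_computable()
    if ef_bias.direction is not None:
        ef_bias = TestResult(
            statistic=ef_bias.statistic,
            direction="E" if ef_bias.direction == "above" else "F",
            p_value=ef_bias.p_value,
            degenerate=ef_bias.degenerate,
        )

    if ef_trials:
        immediate = immediate_reward_association_test(
            [t.choice for t in ef_trials], [t.rewarded for t in ef_trials]
        )
    else:
        immediate = _not_computable()

    try:
        rates = choice_rates(log, rate_spec)
    except ValueError:
        rates = None

    return ClassificationRecord(
        participant_id=log.participant_id,
        report_category=report_category,
        c_criterion=c_crit,
        d_criterion=d_crit,
        overall_c=overall_c,
        half_change=half_change,
        ef_bias=ef_bias,
        immediate_reward=immediate,
        rates=rates,
    )


def _not_computable() -> TestResult:
    return TestResult(statistic=float("nan"), direction=None, p_value=1.0, degenerate=True)


def cohort_table(
    logs: Iterable[SessionLog],
    reports: Optional[dict[str, str]] = None,
    continuity_correction: bool = True,
) -> pd.DataFrame:
    """Classification table: one row per participant, Fig-5 style.

    ``reports`` optionally maps participant_id to a report category; missing
    entries default to 'not_available'. Raises on duplicate participant ids.
    """
    logs = list(logs)
    if not logs:
        raise ValueError("cohort_table requires at least one session log")
    ids = [log.participant_id for log in logs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate participant_id(s): {dupes}")
    reports = reports or {}
    rows = []
    for log in logs:
        rec = classify_participant(
            log,
            report_category=reports.get(log.participant_id, "not_available"),
            continuity_correction=continuity_correction,
        )
        rows.append(
            {
                "participant_id": rec.participant_id,
                "report_category": rec.report_category,
                "c_criterion_met": rec.c_criterion.met,
                "c_criterion_trial": rec.c_criterion.completing_trial,
                "d_criterion_met": rec.d_criterion.met,
                "d_criterion_trial": rec.d_criterion.completing_trial,
                "overall_c_fraction": rec.overall_c.statistic,
                "overall_c_p": rec.overall_c.p_value,
                "overall_c_significant": rec.overall_c.significant,
                "half_change_direction": rec.half_change.direction,
                "half_change_p": rec.half_change.p_value,
                "half_change_significant": rec.half_change.significant,
                "e_fraction": rec.ef_bias.statistic,
                "ef_bias_direction": rec.ef_bias.direction,
                "ef_bias_p": rec.ef_bias.p_value,
                "ef_bias_significant": rec.ef_bias.significant,
                "immediate_reward_direction": rec.immediate_reward.direction,
                "immediate_reward_p": rec.immediate_reward.p_value,
                "immediate_reward_significant": rec.immediate_reward.significant,
                "p_A": rec.rates.p_A if rec.rates else np.nan,
                "p_C": rec.rates.p_C if rec.rates else np.nan,
                "p_E": rec.rates.p_E if rec.rates else np.nan,
                "n_trials": len(log),
                "terminated_early": log.terminated_early,
            }
        )
    return pd.DataFrame(rows)
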