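"""Behavioural statistics: choice rates, criterion detection, bias tests."""

import math

import numpy as np
import pytest
from scipy.stats import binom, hypergeom

from tracetask.analysis import (
    ChoiceRateSpec,
    classify_participant,
    cohort_table,
    detect_criterion,
    halves_change_test,
    immediate_reward_association_test,
    overall_bias_test,
    weighted_choice_rate,
)
from tracetask.task import SessionConfig, StimulusRole, TrialType, run_session

from conftest import always

A, B, C, D, E, F = StimulusRole


def binomial_oracle(k, n):
    """Two-sided exact binomial p by direct enumeration of all n+1 outcomes."""
    pmf = np.array([math.comb(n, i) * 0.5**n for i in range(n + 1)])
    return min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-12)].sum())


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration at fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = hypergeom.pmf(np.arange(lo, hi + 1), n, r1, c1)
    return float(min(1.0, pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum()))


def criterion_oracle(indicators, bin_size=10, threshold=8, n_consecutive=2):
    """Enumerate every window of consecutive full bins directly."""
    n_bins = len(indicators) // bin_size
    counts = [sum(indicators[b * bin_size : (b + 1) * bin_size]) for b in range(n_bins)]
    for b in range(n_bins - n_consecutive + 1):
        if all(counts[b + j] >= threshold for j in range(n_consecutive)):
            return True, (b + n_consecutive) * bin_size
    return False, None


class TestWeightedChoiceRate:
    def test_all_ones_and_zeros(self):
        assert weighted_choice_rate([1] * 30) == pytest.approx(1.0)
        assert weighted_choice_rate([0] * 30) == pytest.approx(0.0)

    def test_alternating_series_closed_form(self):
        # ...,1,0,1 ending in 1: weights at even lags tau pick up the ones
        x = [1 if i % 2 == 0 else 0 for i in range(30)][::-1]
        num = sum(0.9**tau for tau in range(0, 30, 2))
        den = sum(0.9**tau for tau in range(30))
        assert weighted_choice_rate(x) == pytest.approx(num / den)

    def test_invariant_to_prepended_history(self, rng):
        tail = list(rng.integers(0, 2, size=30))
        assert weighted_choice_rate([0, 1, 1, 0] * 10 + tail) == pytest.approx(
            weighted_choice_rate(tail)
        )

    def test_monotone_in_single_flip(self, rng):
        x = list(rng.integers(0, 2, size=30))
        base = weighted_choice_rate(x)
        for i in range(30):
            if x[i] == 0:
                y = list(x)
                y[i] = 1
                assert weighted_choice_rate(y) > base

    def test_short_series_renormalises(self):
        assert weighted_choice_rate([1, 1, 1]) == pytest.approx(1.0)
        assert weighted_choice_rate([1]) == pytest.approx(1.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            weighted_choice_rate([])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ChoiceRateSpec(decay=1.0)
        with pytest.raises(ValueError):
            ChoiceRateSpec(window=0)


class TestDetectCriterion:
    def test_twenty_straight_target_choices(self):
        res = detect_criterion([C] * 20, C)
        assert res.met and res.completing_trial == 20 and res.qualifying_bins == (1, 2)

    def test_seven_eight_eight(self):
        choices = [C] * 7 + [D] * 3 + [C] * 8 + [D] * 2 + [C] * 8 + [D] * 2
        res = detect_criterion(choices, C)
        assert res.met and res.completing_trial == 30 and res.qualifying_bins == (2, 3)

    def test_eight_seven_eight_not_met(self):
        choices = [C] * 8 + [D] * 2 + [C] * 7 + [D] * 3 + [C] * 8 + [D] * 2
        assert not detect_criterion(choices, C).met

    def test_trailing_partial_bin_never_qualifies(self):
        assert not detect_criterion([C] * 19, C).met

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(2000):
            n = int(rng.integers(0, 60))
            p = rng.uniform(0.3, 0.95)
            ind = (rng.random(n) < p).astype(int)
            choices = [C if i else D for i in ind]
            res = detect_criterion(choices, C)
            met, trial = criterion_oracle(list(ind))
            assert res.met == met
            assert res.completing_trial == trial


class TestOverallBiasTest:
    def test_balanced_split_has_p_one(self):
        assert overall_bias_test(10, 20).p_value == pytest.approx(1.0)

    def test_all_target(self):
        assert overall_bias_test(20, 20).p_value == pytest.approx(2 * 0.5**20)

    def test_session_scale_case_matches_oracle(self):
        res = overall_bias_test(100, 167)
        assert res.p_value == pytest.approx(binomial_oracle(100, 167), rel=1e-9)
        assert res.significant == (binomial_oracle(100, 167) < 0.05)

    def test_matches_oracle_on_sweep(self):
        for n in (1, 2, 7, 30, 167):
            for k in range(0, n + 1, max(1, n // 13)):
                assert overall_bias_test(k, n).p_value == pytest.approx(
                    binomial_oracle(k, n), rel=1e-9
                )

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            overall_bias_test(5, 4)
        with pytest.raises(ValueError):
            overall_bias_test(0, 0)


class TestHalvesChangeTest:
    def test_identical_halves(self):
        res = halves_change_test((40, 44), (40, 44))
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)
        assert res.direction is None

    def test_strong_increase_detected(self):
        res = halves_change_test((42, 42), (70, 13))
        assert res.direction == "increase"
        # continuity-corrected chi-square evaluated by the hand formula
        table = np.array([[42, 42], [70, 13]], dtype=float)
        n = table.sum()
        exp = np.outer(table.sum(1), table.sum(0)) / n
        chi2 = ((np.abs(table - exp) - 0.5) ** 2 / exp).sum()
        assert res.statistic == pytest.approx(chi2)
        assert res.p_value < 0.05

    def test_swapped_halves_invert_direction_same_p(self):
        r1 = halves_change_test((42, 42), (70, 13))
        r2 = halves_change_test((70, 13), (42, 42))
        assert r2.direction == "decrease"
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_marginal_is_degenerate(self):
        res = halves_change_test((40, 0), (44, 0))
        assert res.degenerate and res.p_value == 1.0 and not res.significant

    def test_correction_switch(self):
        with_c = halves_change_test((30, 20), (20, 30))
        without = halves_change_test((30, 20), (20, 30), continuity_correction=False)
        assert without.statistic > with_c.statistic


class TestImmediateRewardTest:
    def test_proportional_rows_give_p_one(self):
        choices = [E] * 10 + [F] * 10
        rewards = ([1] * 5 + [0] * 5) * 2
        res = immediate_reward_association_test(choices, rewards)
        assert res.p_value == pytest.approx(1.0)
        assert res.direction is None

    def test_perfect_association_matches_hypergeometric_oracle(self):
        choices = [E] * 10 + [F] * 10
        rewards = [1] * 10 + [0] * 10
        res = immediate_reward_association_test(choices, rewards)
        assert res.p_value == pytest.approx(fisher_oracle(10, 0, 0, 10), rel=1e-9)
        assert res.direction == "E"

    def test_zero_row_is_degenerate(self):
        res = immediate_reward_association_test([E] * 8, [1, 0] * 4)
        assert res.degenerate and res.p_value == pytest.approx(1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            immediate_reward_association_test([], [])
        with pytest.raises(ValueError):
            immediate_reward_association_test([E, A], [0, 1])
        with pytest.raises(ValueError):
            immediate_reward_association_test([E, F], [0])

    def test_matches_oracle_on_small_tables(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(2)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 9, size=4)
            if (a + b == 0) or (c + d == 0):
                continue
            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7, abs=1e-12)


class TestClassification:
    def test_always_c_participant(self, rng):
        log = run_session(always(C), config=SessionConfig(termination_enabled=False), rng=rng,
                          participant_id="p1")
        rec = classify_participant(log)
        assert rec.c_criterion.met
        assert not rec.d_criterion.met
        assert rec.overall_c.statistic == pytest.approx(1.0)
        assert rec.overall_c.significant
        assert rec.half_change.degenerate  # no D choices at all -> zero marginal
        assert rec.rates.p_C == pytest.approx(1.0)

    def test_invalid_report_category(self, rng):
        log = run_session(always(C), config=SessionConfig(n_units=2), rng=rng)
        with pytest.raises(ValueError):
            classify_participant(log, report_category="excellent")

    def test_cohort_table_shape_and_determinism(self, rng):
        logs = [
            run_session(always(C), config=SessionConfig(termination_enabled=False),
                        rng=np.random.default_rng(i), participant_id=f"p{i}")
            for i in range(3)
        ]
        t1 = cohort_table(logs)
        t2 = cohort_table(logs)
        assert len(t1) == 3
        assert t1.equals(t2)
        assert (t1["report_category"] == "not_available").all()

    def test_duplicate_participants_rejected(self, rng):
        log = run_session(always(C), config=SessionConfig(n_units=10, termination_enabled=False), rng=rng)
        with pytest.raises(ValueError, match="duplicate"):
            cohort_table([log, log])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_table([])

    def test_reports_map_applied(self, rng):
        log = run_session(always(C), config=SessionConfig(n_units=10, termination_enabled=False),
                          rng=rng, participant_id="s1")
        table = cohort_table([log], reports={"s1": "partial"})
        assert table.loc[0, "report_category"] == "partial"
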