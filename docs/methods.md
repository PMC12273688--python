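# Methods

## Task environment

A session is a sequence of two-alternative forced-choice trials drawn from
three pair types. Trials are organised in units of three — one A-vs-B, one
C-vs-D, one E-vs-F trial, independently and uniformly permuted within each
unit. Rewards are binary points:

- **A vs B** — A pays 1 immediately, B pays 0.
- **C vs D** — pays 0 at the trial itself; the choice (1 for C, 0 for D) is
  appended to a FIFO queue.
- **E vs F** — regardless of the chosen stimulus, the oldest queue entry is
  popped and paid. If the queue is empty the trial pays 0 and consumes
  nothing.

Two structural facts follow from the unit construction and are enforced by
tests. First, the queue depth never exceeds 2: a unit contributes exactly one
push and one pop, so depth can only build across the boundary between a unit
ending in C-vs-D and the next beginning with E-vs-F. Second, an E-vs-F trial
with an empty queue occurs at most once per session under an always-C policy
— at the first unit whose E-vs-F trial precedes its C-vs-D trial. From that
point payouts run exactly one entry behind, so a 167-unit always-C session
delivers 166 of its 167 queued points; the 167th is still pending at session
end. A session avoids this only if every one of its 167 units orders C-vs-D
before E-vs-F (probability 2^-167), so full sessions deliver 166 in practice.

The delivery lag — trials between a C-vs-D choice and the E-vs-F trial that
pays it — is confined to 1..5 by the same structure and averages 3.0 under
uniform unit orderings. `scripts/acceptance.py` recomputes this from 1000
generated sessions.

Default session length is 167 units (501 trials). The **learning criterion**
is C chosen on ≥ 8 of 10 C-vs-D trials in two consecutive non-overlapping
bins of 10, evaluated online; when termination is enabled the session stops
at the criterion-completing C-vs-D trial.

## Learning agents

Both agents choose within the offered pair by a softmax on action values,

    P{a = X} = 1 / (1 + exp(beta * (q_Y - q_X))),

maintain per-action eligibility traces

    eta_X(t) = lambda * eta_X(t-1) + 1{a(t) = X},

and update all six action values with a single reward prediction error,

    q_X <- q_X + alpha * eta_X * delta.

The actor-critic additionally keeps one value per pair type (the "state"),
updated with the summed traces of the pair's two actions,
`v_P <- v_P + alpha * (eta_X + eta_Y) * delta`, and computes
`delta = r + gamma * v_next - v_current`. Q-learning computes
`delta = r + gamma * max(q over the next pair) - q_chosen`. On the final
trial the next-state term is 0. All values and traces start at 0. Updates use
the pre-update values within a trial; the order per trial is choose → settle
reward → decay-and-increment traces → compute delta → apply updates.

### Parameters

| name | symbol | range | default presets |
| --- | --- | --- | --- |
| learning rate | alpha | [0, 1]; 0 is the no-learning limit | 0.001 or 0.1 |
| inverse temperature | beta | ≥ 0; 0 is random choice | 0.01 or 4 |
| trace decay | lambda | [0, 1] | 0.01 or 0.5 |
| discount | gamma | [0, 1] | 0.5 everywhere |

The four presets isolate one failure mode each: `slow_learning` (alpha
0.001), `high_exploration` (beta 0.01), `short_trace` (lambda 0.01), and
`long_trace` (lambda 0.5), the only configuration whose trace persists across
the 1–5 trial delivery lag. The simulation grid runs each algorithm × preset
cell for 200 sessions of 160 units (480 trials, 16 full bins of each pair
type) with termination disabled, and summarises each run by the choice counts
in the final 10-trial bin of each pair type and by exponentially weighted
choice rates (decay 0.9 over the last 30 trials of each type).

### Behaviour of the presets at scale

The intended qualitative reading — `long_trace` learns A and C, `short_trace`
learns only A, the other two stay at chance — holds in direction but not
exactly at a 99% binomial confidence level over 200 runs, and the acceptance
tests report this honestly rather than widening the bounds:

- Under `slow_learning`, alpha = 0.001 is small but not zero: over 480 trials
  with beta = 4, roughly 160 rewarded A choices accumulate a q-advantage of
  order 0.1, enough to lift mean final-bin A counts to ≈ 5.9 (both
  algorithms) against chance bounds of 5 ± 0.29.
- Under `short_trace` with the actor-critic, the critic's pair values are
  updated by summed traces and feed every delta through the gamma * v_next
  term; queued payouts raise the E-vs-F state value, which leaks a small
  positive bias into C (mean ≈ 5.5).

These drifts are properties of the printed update equations at these exact
parameter values, reproduced deterministically by the seeded grid; the
corresponding test assertions fail by design rather than encode the drift as
the expectation.

## Synthetic cohort

The cohort generator emulates the *decision output* of stylised participant
phenotypes, not their learning dynamics: each archetype is a fixed
Bernoulli policy per pair type (`c_learner` additionally ramps its C
probability from 0.5 to 0.95 after the 30th C-vs-D trial to mimic criterion
learning). Archetypes: `c_learner` (p_A .95, p_C ramp, p_E .5),
`d_perseverator` (p_C .15), `e_superstitious` (p_E .9), `f_superstitious`
(p_E .1), `random_chooser` (all .5), `immediate_only` (only p_A .95).

Because the policies are stationary (or piecewise-stationary), passing the
recovery tests shows the pipeline detects the biases each statistical test
targets at the advertised error rates; it does **not** show the tests are
well calibrated for gradually learning humans, whose choice sequences are
non-stationary and autocorrelated in ways no archetype reproduces.

Cohort seeding derives one child seed pair per participant from
`SeedSequence([master_seed, ordinal])`, so extending a cohort's composition
never perturbs existing participants' sessions.

## Statistical tests

All tests are two-tailed at alpha = 0.05, with no multiplicity adjustment:

- overall C (and E) bias: exact binomial test against 0.5, two-sided by the
  point-probability method (`scipy.stats.binomtest`);
- first-half vs second-half C choice: 2×2 chi-square with Yates continuity
  correction, halves split at ceil(n/2) in per-type trial order; a zero
  marginal makes the table degenerate and the test reports p = 1 with a
  `degenerate` flag;
- payout-after-choice association at E-vs-F: two-sided Fisher exact test on
  the choice × rewarded table, direction reported as the enriched stimulus.

The test suite checks each against an independent enumeration oracle
(binomial over the full pmf for all n ≤ 200; Fisher against hypergeometric
enumeration for all tables with cells ≤ 7 plus random tables with margins
≤ 30).

## Numerical and design choices

- Softmax uses `scipy.special.expit` on beta * (q_Y − q_X); no tie-break is
  needed because the rule is probabilistic.
- Session logs are plain CSV with a fixed eight-column schema; the reader
  revalidates every structural invariant (pair membership, CD never paid,
  EF payouts consistent with a FIFO replay, cumulative points) rather than
  trusting the writer.
- `alpha = 0` is accepted as the no-learning limit; probabilities and counts
  are validated at construction time and errors are raised eagerly
  (`PolicyContractError` for an out-of-pair choice, `ValueError` for bad
  configuration).
- Lags are computed only for delivered outcomes; entries still queued at
  session end are omitted rather than imputed.
- Problem sizes in the test suite (200-run grid, 1000-session lag batch,
  600-participant cohort, 10^4-session reward-oracle sweep) were chosen so
  each stochastic assertion has a comfortable margin at its stated
  confidence level while the whole suite runs in about a minute.

## Known limitations

- Agents and archetypes emit choices only; no reaction times, lapses,
  side biases or sequential dependencies beyond the learning rule itself.
- The chi-square halves test is anti-conservative for very short sessions
  (expected cell counts < 5); the degenerate flag covers only zero margins.
- The grid explores four preset corners, not the continuous parameter space;
  conclusions about intermediate parameter values require new runs.
- Early termination truncates exactly at the criterion trial, which censors
  post-criterion behaviour; analyses of terminated sessions reflect only the
  learning phase.
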