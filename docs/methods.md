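# Methods

## The model

`iotalearn` treats an association as a measurable property of the
distribution of events in time. All percept-level quantities are
functions of counts `n` and cumulative durations `T` read off a
time-stamped event record:

- A **rate** is `λ = n/T`. A **conditional rate** counts events inside a
  state's presence windows over that state's cumulative duration; the
  **contextual rate** counts all events over total context time,
  regardless of what else is present.
- **Informativeness** `ι = λ_cond/λ_ctx` is unitless; multiplying every
  time stamp by `c > 0` leaves it unchanged (time-scale invariance),
  which the package exposes directly (`scale_times`) and tests.
- **Communicated information.** Modeling wait times as exponential with
  differential entropy `H = 1 − ln λ`, the entropy difference between
  the contextual and conditional distributions is exactly `ln ι`. Both
  routes are implemented and their identity is a standing test.
- **Evidence.** `nDKL` multiplies the exponential-rate KL divergence
  `ln ι + 1/ι − 1` by the effective sample size
  `n_e = n_cond/(1 + n_cond/n_ctx)`. Under no association the statistic
  is distributed gamma(.5, 1); p-values use the exact gamma upper tail
  (scipy), odds are `(1−p)/p`. The contextual count is inclusive of the
  conditional events (in the one-reinforcement case both counts are the
  same event, giving `n_e = 0.5`).
- **Learning Rate Law.** `α = (ι − 1)/k` exactly (the `≅ ι/k`
  approximation appears nowhere in code); `RtoAcq = k/(ι − 1)`;
  `k = RtoAcq·(ι − 1)`. `k` is a configuration parameter: 250 for
  pigeon/rat delay protocols, ~5200 for head-fixed-mouse trace
  protocols; both defaults are named constants, and tests always pass
  `k` explicitly. The trade-off form `n_R(ι − 1) > k` is the response
  decision rule. Predictions are for the median subject.
- **Credit assignment.** `P[i, j]` is the cumulative duration of
  predictor `j` while `i` is present divided by predictor `i`'s
  duration (context listed first). Attributed rates solve `Pλ̂ = λ` by
  a stable linear solve (`numpy.linalg.solve`), not explicit inversion.
  Condition numbers above 1e8 (configurable) raise an error naming the
  collinear predictors: perfectly compounded CSs are reported for
  merging rather than split by an arbitrary tie-break. Negative
  attributed rates are returned as inhibitory predictions.
- **Change detection.** For a window of events `t_1..t_n` with origin
  `t_0` and current time `t`, the profile element at event `i` is
  `n_e(i)·[ln(λ_i/λ(t)) + λ(t)/λ_i − 1]` with `λ_i = i/(t_i − t_0)`,
  `λ(t) = n/(t − t_0)`, `n_e(i) = i/(1 + i/n)`; the probability form
  substitutes the Bernoulli KL of the running reinforcement-per-trial
  estimate against the current estimate. A change is reported when the
  profile maximum exceeds the criterion (default 3.3 nats ≈ 100:1 odds);
  the argmax (earliest on ties) localizes it, and subsequent statistics
  use only data after that point.
- **Time allocation.** Mean dwell at location I is `1/(k·λ_R|J)`; the
  dwell ratio (Matching Law) is `λ_R|I/λ_R|J`, independent of `k`; the
  cycling rate is reported in normalized form `1/(1/λ_1 + 1/λ_2)` with
  an optional `k` scaling, since the normalized form is what is usually
  plotted. Programmed (not obtained) VI rates are used: `λ_R = 1/VI`.
  Revealed-preference probes carry each key's trained dwell process
  unchanged, so predictions depend only on the training pairs.

## Numerical and boundary choices

- **Interval boundaries.** Named states use closed-at-end membership
  `[on, off]` for event counting, so a reinforcement stamped exactly at
  CS offset belongs to the CS — the delay-conditioning convention that
  makes the retrospective contingency 1. Complement windows are open at
  both ends; a state and its complement therefore partition the
  context's events exactly, for any event type on a boundary.
  Durations are plain `Σ(end − start)` either way.
- **Censoring.** Forward intervals with no later target and backward
  intervals with no earlier target are dropped by default; flags close
  them at `t_end`/`t0` for sensitivity analyses.
- **Degenerate associations.** A zero mean wait (perfect co-timing)
  yields an association tagged `maximal` (value `inf`) rather than a
  bare float infinity in reports; a zero contextual rate raises a
  no-evidence error rather than returning a number.
- **Available information** has no closed form in continuous time; it
  is operationalized as the information a perfectly co-timed predictor
  communicates at a finite timing resolution (default 0.01 s, the
  resolution at which co-timed stamps are indistinguishable):
  `ln(μ_ctx/resolution)`. Contingency is the communicated/available
  ratio, clipped to [0, 1] with a warning; two maximal arguments give 1.
- **Cycle means from sparse records.** The reinforcement-to-
  reinforcement mean uses successive intervals when two or more events
  exist and falls back to the contextual mean wait `T/n` for a single
  event (the two agree asymptotically); this is what lets the
  taste-aversion case (one taste, one nausea) be computed at all.
- **Bernoulli KL conventions.** `0·ln 0 = 0`; a reference probability
  of exactly 0 or 1 with a disagreeing estimate returns `inf`, which
  any finite criterion treats as an immediate detection.
- **Minimum evidence.** No change decision is attempted with fewer than
  2 events/trials in the current window; the formulas degenerate at
  `n = 1` (the single profile element is identically 0 when the two
  estimates coincide).
- **Logs and bases.** Internal computation is in nats; reporting
  defaults to bits; the base is an explicit argument wherever a log is
  taken.

## The extinction simulation

`simulate_pree` trains with Bernoulli(p) outcomes until ~24
reinforcements have been delivered (`n_trials = round(24/p)`, so every
group's pre-change estimate rests on comparable evidence), then appends
unreinforced trials until the online detector reports a change; 16
replicates per probability at criterion 3.3 nats, each replicate on its
own seeded substream.

The detector in this simulation is the **rate-form** profile applied to
the reinforcement time stamps on the trial clock. This choice is
deliberate: the rate statistic is time-scale invariant, so thinning the
training probability by a factor stretches the whole detection problem
by that factor, which is precisely the scalar extinction effect — a
tenfold leaner schedule takes tenfold more unreinforced trials to
extinguish, and the number of *omitted* reinforcements to extinction is
level across probabilities. The Bernoulli (probability-form) profile is
also implemented and tested; applied to the same design it is only
asymptotically scalar (log-log slope ≈ −1.25 over p ∈ [.1, .75] rather
than −1), because its KL term is not invariant under trial-thinning at
high p. The probability form is the right tool where trials are
well-defined and the retrospective contingency is 1, and it is what the
closed-loop virtual subject uses on its CS-offset outcomes.

## What the simulators emulate — and what they do not

The generators reproduce protocol *structure*: fixed-duration CSs,
fixed or exponential ITIs (exponential draws truncated at 10× the mean
to bound session length), reinforcement co-timed with CS offset (delay),
gap states only on reinforced trials (trace), session-wide Poisson
shocks (truly-random control), exponential arming with delivery at the
first subsequent response (VI), and Poisson departure scheduling
(concurrent allocation). Co-timed events share one stamp with a stable
response-before-reinforcement order. They do **not** emulate individual
differences, latencies and motor noise, satiation or warm-up trends,
obtained-rate feedback between stay patterns and earned reinforcements,
or changeover delays. Passing tests therefore certify the model's
internal laws and the estimators' behavior under the model's own
assumptions, not goodness of fit to any animal's data; archival-data
regressions are out of scope.

## Null-calibration regime

The gamma(.5, 1) law for nDKL is an asymptotic result for a conditional
sample that is a small share of the contextual sample (the model's
typical regime: a CS occupying a small fraction of context time, or an
event early in a long window). The calibration test therefore simulates
a stationary Poisson process with the conditional window at 0.1% of the
context (~1,000 conditional events per replicate, 10,000 replicates)
and checks both Kolmogorov–Smirnov fit and the 3.3-nat tail frequency.
When the conditional window is a large share of the context the
statistic is conservative (under-dispersed), because the inclusive
contextual count correlates the two rate estimates; detection
thresholds then err on the side of fewer false alarms.

## Problem sizes

Simulation-backed tests use sizes chosen to keep sampling error well
inside their tolerances while the whole suite runs in seconds: 10,000
replicates for the null calibration, 400-trial records for
partial-reinforcement contrasts, 16 × 4 extinction replicates, 200-event
records for the online-vs-brute-force equivalence, and a 200,000-s
session for dwell statistics.

## Known limitations

- The credit-assignment matrix is cumulative-to-date; trial-by-trial
  attribution dynamics are the caller's loop.
- Spontaneous recovery, renewal and reinstatement are not modeled (no
  quantitative rule exists for them in this framework).
- The virtual subject implements the acquisition trade-off and the
  extinction change decision; it does not model response latencies
  within the CS or partial-reinforcement response-rate scaling.
- `k` (one-shot constant) and `k_response` (response-rate scalar) are
  preparation-dependent inputs, not fitted quantities.
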