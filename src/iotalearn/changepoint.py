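"""Real-time change-point detection on event rates and probabilities.

The detector compares, at each past event i, the rate (or probability)
estimated from the data up to i against the estimate from all data in
the current window, weighting the divergence by an effective sample
size:

    rate mode:  nDKL_i = n_e(i) * [ln(lambda_i/lambda(t)) + lambda(t)/lambda_i - 1]
    prob mode:  nDKL_i = n_e(i) * KL_Bernoulli(p_i, p(n))

with lambda_i = i/(t_i - t0), lambda(t) = n/(t - t0), p_i the running
reinforcements-per-trial, and n_e(i) = i/(1 + i/n).  Under a stationary
process each profile element is distributed gamma(.5, 1), so a decision
criterion of 3.3 nats corresponds to odds of about 100:1 against the
null.  When the profile maximum exceeds the criterion, the argmax
estimates where the change occurred, and subsequent estimates are based
only on data after that point (window truncation).

Applied to extinction after partial reinforcement, this machinery
reproduces the scalar partial-reinforcement extinction effect: the
number of consecutive unreinforced trials to extinction grows as the
reciprocal of the training reinforcement probability, so the number of
*omitted* reinforcements to extinction is approximately constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evidence import kl_bernoulli

#: decision criterion corresponding to ~100:1 odds against the null
DEFAULT_CRITERION_NATS = 3.3

#: below this many events/trials in a window the statistics degenerate
MIN_EVENTS = 2


@dataclass
class ChangePointReport:
    """Outcome of one detection decision.

    ``detected`` iff ``max_ndkl`` exceeded the criterion; then
    ``change_index`` is the argmax (1-based event/trial index within the
    full series, first occurrence on ties) and 0 otherwise.
    ``window_start`` is the index just after which post-detection
    statistics restart.
    """

    detected: bool
    change_index: int
    change_time: float
    max_ndkl: float
    criterion: float
    window_start: int = 0


def rate_vectors(times, t0: float = 0.0, t_current: float | None = None):
    """Per-event rate estimates, the current rate, and effective sizes.

    ``times`` are the n event stamps; returns (lambda_vec, lambda_t,
    n_e_vec) with lambda_i = i/(t_i - t0), lambda_t = n/(t_current - t0)
    and n_e(i) = i/(1 + i/n).  Note n_e(n) = n/2 always.
    """
    t = np.asarray(times, dtype=float)
    n = t.size
    if n < 1:
        raise ValueError("at least one event is required")
    if t_current is None:
        t_current = float(t[-1])
    if np.any(t <= t0) or t_current <= t0:
        raise ValueError("event times must exceed the window origin t0")
    i = np.arange(1, n + 1, dtype=float)
    lam = i / (t - t0)
    lam_t = n / (t_current - t0)
    n_e = i / (1.0 + i / n)
    return lam, lam_t, n_e


def ndkl_profile_rate(times, t0: float = 0.0, t_current: float | None = None):
    """Elementwise nDKL of the running rate estimates against the current
    whole-window estimate (nats); non-negative."""
    lam, lam_t, n_e = rate_vectors(times, t0, t_current)
    return n_e * (np.log(lam / lam_t) + lam_t / lam - 1.0)


def ndkl_profile_prob(outcomes):
    """Elementwise nDKL of running reinforcement-probability estimates
    against the current estimate, from 0/1 trial outcomes."""
    x = np.asarray(outcomes, dtype=float)
    n = x.size
    if n < 1:
        raise ValueError("at least one trial is required")
    if np.any((x != 0) & (x != 1)):
        raise ValueError("trial outcomes must be 0 or 1")
    i = np.arange(1, n + 1, dtype=float)
    p = np.cumsum(x) / i
    p_n = p[-1]
    n_e = i / (1.0 + i / n)
    return n_e * kl_bernoulli(p, np.full(n, p_n))


def detect_change(
    profile,
    criterion_nats: float = DEFAULT_CRITERION_NATS,
    times=None,
    window_start: int = 0,
) -> ChangePointReport:
    """Apply the decision criterion to an nDKL profile.

    Tie-break: earliest index.  ``times`` (aligned with the profile)
    supplies ``change_time``; indices in the report are 1-based and
    offset by ``window_start`` so they refer to the full series.
    """
    prof = np.asarray(profile, dtype=float)
    if prof.size == 0:
        raise ValueError("profile is empty")
    arg = int(np.argmax(prof))  # first occurrence on ties
    mx = float(prof[arg])
    detected = mx > criterion_nats
    if detected:
        idx = window_start + arg + 1
        t_chg = float(times[arg]) if times is not None else float("nan")
    else:
        idx, t_chg = 0, float("nan")
    return ChangePointReport(
        detected=detected,
        change_index=idx,
        change_time=t_chg,
        max_ndkl=mx,
        criterion=criterion_nats,
        window_start=window_start,
    )


def segment_rate(
    times,
    t0: float = 0.0,
    t_current: float | None = None,
    criterion_nats: float = DEFAULT_CRITERION_NATS,
) -> list[ChangePointReport]:
    """Online scan of an event-time series for rate changes.

    Events are presented one at a time; after each new event the profile
    over the current window is recomputed and the criterion applied.
    After a detection the window restarts just after the change point,
    so all later estimates depend only on post-change data.
    """
    t = np.asarray(times, dtype=float)
    n = t.size
    if t_current is None:
        t_current = float(t[-1]) if n else t0
    reports: list[ChangePointReport] = []
    w = 0            # index of first event in current window
    w_t0 = t0        # window origin time
    for upto in range(1, n + 1):
        if upto - w < MIN_EVENTS:
            continue
        window = t[w:upto]
        prof = ndkl_profile_rate(window, w_t0, float(t[upto - 1]))
        rep = detect_change(prof, criterion_nats, times=window, window_start=w)
        if rep.detected:
            reports.append(rep)
            w = rep.change_index          # events after the change point
            w_t0 = float(t[w - 1])        # window restarts just after it
    return reports


def segment_prob(
    outcomes,
    criterion_nats: float = DEFAULT_CRITERION_NATS,
) -> list[ChangePointReport]:
    """Online scan of 0/1 trial outcomes for probability changes;
    mirrors :func:`segment_rate` with trial indices as time."""
    x = np.asarray(outcomes, dtype=float)
    n = x.size
    reports: list[ChangePointReport] = []
    w = 0
    for upto in range(1, n + 1):
        if upto - w < MIN_EVENTS:
            continue
        window = x[w:upto]
        prof = ndkl_profile_prob(window)
        trial_idx = np.arange(w + 1, upto + 1, dtype=float)
        rep = detect_change(prof, criterion_nats, times=trial_idx, window_start=w)
        if rep.detected:
            reports.append(rep)
            w = rep.change_index
    return reports


@dataclass
class PreeResult:
    """Per-probability summary of the extinction simulation."""

    p_train: float
    trials_to_detection: np.ndarray      # per replicate; nan if cap reached
    omitted_reinforcements: np.ndarray   # trials * p_train
    mean_trials: float = field(init=False)
    sd_trials: float = field(init=False)
    mean_omitted: float = field(init=False)
    sd_omitted: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_trials = float(np.nanmean(self.trials_to_detection))
        self.sd_trials = float(np.nanstd(self.trials_to_detection))
        self.mean_omitted = float(np.nanmean(self.omitted_reinforcements))
        self.sd_omitted = float(np.nanstd(self.omitted_reinforcements))


def _extinction_trials(
    train: np.ndarray,
    criterion_nats: float,
    max_extinction: int,
) -> float:
    """Trials after extinction onset until the detector first reports a
    change; nan when the cap is reached without a detection.

    The detector is the rate-form profile applied to the reinforcement
    time stamps on the trial clock (reinforcement i at the trial index
    where it occurred).  Because the reinforcement-rate statistic is
    time-scale invariant, thinning the training probability by a factor
    stretches the whole problem by that factor, which is what makes the
    extinction effect scalar.
    """
    n_train = train.size
    # reinforcement time stamps on the trial clock
    times = np.flatnonzero(train) + 1.0
    # online scan of the training phase; restart the window after any
    # (rare) detection due to clustering, as the online rule prescribes
    w, w_t0 = 0, 0.0
    for k in range(1, times.size + 1):
        if k - w < MIN_EVENTS:
            continue
        window = times[w:k]
        rep = detect_change(
            ndkl_profile_rate(window, w_t0, float(window[-1])),
            criterion_nats, times=window, window_start=w,
        )
        if rep.detected:
            w = rep.change_index
            w_t0 = float(times[w - 1])
    window = times[w:]
    if window.size < MIN_EVENTS:
        return float("nan")
    # extinction: no new reinforcements; only the clock advances
    for m in range(1, max_extinction + 1):
        t_now = float(n_train + m)
        rep = detect_change(
            ndkl_profile_rate(window, w_t0, t_now), criterion_nats
        )
        if rep.detected:
            return float(m)
    return float("nan")


def simulate_pree(
    p_train_list=(0.75, 0.5, 0.33, 0.1),
    reps: int = 16,
    criterion_nats: float = DEFAULT_CRITERION_NATS,
    seed: int = 0,
    n_reinforcements: int = 24,
    max_extinction: int = 10_000,
) -> list[PreeResult]:
    """Partial-reinforcement extinction simulation.

    For each training probability p: generate Bernoulli(p) outcomes for
    ``round(n_reinforcements / p)`` training trials (so every group
    earns about the same number of reinforcements), then an all-zero
    extinction run; count trials from extinction onset until the online
    detector first reports a change.  Omitted reinforcements =
    trials-to-detection times p; the scalar effect predicts this product
    is level across p, and trials-to-detection grows as 1/p.

    Each (probability, replicate) pair draws from its own seeded
    substream, so results are reproducible and independent of ordering.
    """
    results = []
    for pi, p in enumerate(p_train_list):
        if not (0 < p <= 1):
            raise ValueError("training probabilities must lie in (0, 1]")
        n_train = max(MIN_EVENTS, round(n_reinforcements / p))
        trials = np.empty(reps)
        for r in range(reps):
            rng = np.random.default_rng([seed, pi, r])
            train = (rng.random(n_train) < p).astype(float)
            if train.sum() == 0:  # degenerate draw: force one reinforcement
                train[rng.integers(n_train)] = 1.0
            trials[r] = _extinction_trials(train, criterion_nats, max_extinction)
        results.append(
            PreeResult(
                p_train=float(p),
                trials_to_detection=trials,
                omitted_reinforcements=trials * p,
            )
        )
    return results
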