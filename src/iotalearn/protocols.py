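"""Seeded protocol simulators: the package's synthetic-record factory.

Each generator emits an :class:`~iotalearn.events.EventRecord` with the
exact event structure of a standard conditioning protocol:

* delay conditioning -- reinforcement coincides with CS termination;
* trace conditioning -- a gap separates CS offset from reinforcement,
  and the gap state exists only on reinforced trials;
* the truly-random control -- reinforcements scheduled by a homogeneous
  Poisson process, indifferent to the CS;
* variable-interval schedules -- reinforcement armed at exponentially
  distributed intervals and delivered co-timed with the first response
  after arming (single or concurrent).

All randomness flows through numpy Generators seeded with named
substreams (ITI, arming, responding, departures), so identical seeds
give identical records.  Exponential ITIs are truncated at 10x their
mean to bound session length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .allocation import ConcurrentPair, dwell_times
from .changepoint import DEFAULT_CRITERION_NATS, MIN_EVENTS, detect_change, ndkl_profile_prob
from .events import Event, EventRecord, RateEstimate
from .learning import LearningRateParams, ResponseRateMap, predict_response_rate, tradeoff_met

# substream tags so each stochastic process has its own stream
_ITI, _REINF, _ARMING, _RESPONDING, _DEPARTURES = range(5)

#: exponential ITI draws are truncated here, in units of the mean
ITI_TRUNCATION_FACTOR = 10.0


@dataclass
class ProtocolConfig:
    """Parameters of a conditioning protocol.

    Units are seconds and per-second rates.  ``iti_distribution`` is
    ``"fixed"`` or ``"exponential"`` (exponential draws truncated at 10x
    the mean).  ``p_reinforce`` thins reinforced trials for partial
    reinforcement.
    """

    kind: Literal[
        "delay", "trace", "truly_random", "vi_single", "vi_concurrent"
    ] = "delay"
    cs_label: str = "A"
    cs_seconds: float = 10.0
    gap_seconds: float = 0.0
    iti_mean_seconds: float = 300.0
    iti_distribution: Literal["fixed", "exponential"] = "exponential"
    p_reinforce: float = 1.0
    poisson_rate_per_second: float = 0.0
    response_rate_per_second: float = 0.0
    vi_seconds: float = 60.0
    vi_seconds_2: float = 60.0
    n_trials: int = 20
    session_seconds: float = 3600.0
    reinf_label: str = "food"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cs_seconds <= 0 or self.iti_mean_seconds <= 0:
            raise ValueError("durations must be positive")
        if not (0 <= self.p_reinforce <= 1):
            raise ValueError("p_reinforce must lie in [0, 1]")
        if self.kind == "trace" and self.gap_seconds <= 0:
            raise ValueError("trace conditioning requires a positive gap")


def _rng(config: ProtocolConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _draw_iti(config: ProtocolConfig, rng: np.random.Generator) -> float:
    if config.iti_distribution == "fixed":
        return config.iti_mean_seconds
    x = rng.exponential(config.iti_mean_seconds)
    return min(x, ITI_TRUNCATION_FACTOR * config.iti_mean_seconds)


def gen_delay(config: ProtocolConfig) -> EventRecord:
    """Delay conditioning: ITI, then a CS whose termination coincides
    with reinforcement on reinforced trials (probability p_reinforce)."""
    rng_iti = _rng(config, _ITI)
    rng_reinf = _rng(config, _REINF)
    events = [Event(0.0, "context_on")]
    t = 0.0
    for _ in range(config.n_trials):
        t += _draw_iti(config, rng_iti)
        events.append(Event(t, f"cs_on:{config.cs_label}"))
        t += config.cs_seconds
        if rng_reinf.random() < config.p_reinforce:
            # co-timed: reinforcement then CS offset, stable order
            events.append(Event(t, f"reinf:{config.reinf_label}"))
        events.append(Event(t, f"cs_off:{config.cs_label}"))
    events.append(Event(t, "context_off"))
    return EventRecord(events=events, t0=0.0, t_end=t)


def gen_trace(config: ProtocolConfig) -> EventRecord:
    """Trace conditioning: a gap of fixed duration separates CS offset
    from reinforcement.

    The gap state (``gap_on``/``gap_off``) exists only on reinforced
    trials; on unreinforced trials the same clock time elapses but
    nothing marks it, so it is context (ITI) time.
    """
    rng_iti = _rng(config, _ITI)
    rng_reinf = _rng(config, _REINF)
    events = [Event(0.0, "context_on")]
    t = 0.0
    for _ in range(config.n_trials):
        t += _draw_iti(config, rng_iti)
        events.append(Event(t, f"cs_on:{config.cs_label}"))
        t += config.cs_seconds
        events.append(Event(t, f"cs_off:{config.cs_label}"))
        reinforced = rng_reinf.random() < config.p_reinforce
        if reinforced:
            events.append(Event(t, f"gap_on:{config.cs_label}"))
            t += config.gap_seconds
            events.append(Event(t, f"reinf:{config.reinf_label}"))
            events.append(Event(t, f"gap_off:{config.cs_label}"))
        else:
            t += config.gap_seconds
    events.append(Event(t, "context_off"))
    return EventRecord(events=events, t0=0.0, t_end=t)


def gen_truly_random(config: ProtocolConfig) -> EventRecord:
    """The truly-random control: the CS schedule of a delay protocol,
    but reinforcements from a homogeneous Poisson process running over
    the whole session, indifferent to the CS."""
    if config.poisson_rate_per_second <= 0:
        raise ValueError("truly_random requires a positive poisson_rate_per_second")
    rng_iti = _rng(config, _ITI)
    rng_reinf = _rng(config, _REINF)
    events = [Event(0.0, "context_on")]
    t = 0.0
    for _ in range(config.n_trials):
        t += _draw_iti(config, rng_iti)
        events.append(Event(t, f"cs_on:{config.cs_label}"))
        t += config.cs_seconds
        events.append(Event(t, f"cs_off:{config.cs_label}"))
    session_end = t
    # Poisson reinforcements: exponential waits over the whole session
    rt = rng_reinf.exponential(1.0 / config.poisson_rate_per_second)
    while rt < session_end:
        events.append(Event(rt, f"reinf:{config.reinf_label}"))
        rt += rng_reinf.exponential(1.0 / config.poisson_rate_per_second)
    events.append(Event(session_end, "context_off"))
    return EventRecord(events=events, t0=0.0, t_end=session_end)


def _vi_responses_and_reinfs(
    rng_arm: np.random.Generator,
    rng_resp: np.random.Generator,
    vi_seconds: float,
    response_rate: float,
    windows: list[tuple[float, float]],
    reinf_label: str,
    response_label: str = "press",
) -> list[Event]:
    """One VI schedule running inside the given presence windows.

    The schedule arms at exponentially distributed intervals after each
    harvest; an armed reinforcement is delivered co-timed with the first
    response after arming.  Responses are Poisson at ``response_rate``
    while present.
    """
    events: list[Event] = []
    armed_at = windows[0][0] + rng_arm.exponential(vi_seconds) if windows else 0.0
    for ws, we in windows:
        t = ws
        while True:
            t += rng_resp.exponential(1.0 / response_rate)
            if t >= we:
                break
            events.append(Event(t, f"response:{response_label}"))
            if t >= armed_at:
                events.append(Event(t, f"reinf:{reinf_label}"))
                armed_at = t + rng_arm.exponential(vi_seconds)
    return events


def gen_vi(config: ProtocolConfig) -> EventRecord:
    """Variable-interval operant protocol.

    ``vi_single``: one schedule over the whole session.
    ``vi_concurrent``: two schedules at two locations; the subject
    alternates with exponentially distributed dwells at the
    Dwell-Time-Equation means, responding only where it is.
    """
    if config.response_rate_per_second <= 0:
        raise ValueError("VI simulation requires a positive response rate")
    rng_arm = _rng(config, _ARMING)
    rng_resp = _rng(config, _RESPONDING)
    T = config.session_seconds
    events = [Event(0.0, "context_on")]
    if config.kind == "vi_single":
        events += _vi_responses_and_reinfs(
            rng_arm, rng_resp, config.vi_seconds, config.response_rate_per_second,
            [(0.0, T)], config.reinf_label,
        )
    elif config.kind == "vi_concurrent":
        rng_dep = _rng(config, _DEPARTURES)
        pair = ConcurrentPair.from_vi("left", "right", config.vi_seconds, config.vi_seconds_2)
        pred = dwell_times(pair)
        t = 0.0
        visits: dict[str, list[tuple[float, float]]] = {"left": [], "right": []}
        here, mu = ("left", pred.mu_d_i), ("right", pred.mu_d_j)
        while t < T:
            label, mean_dwell = here
            leave = min(t + rng_dep.exponential(mean_dwell), T)
            visits[label].append((t, leave))
            events.append(Event(t, f"enter:{label}"))
            events.append(Event(leave, f"exit:{label}"))
            t = leave
            here, mu = mu, here
        rng_arm2 = np.random.default_rng([config.seed, _ARMING, 1])
        rng_resp2 = np.random.default_rng([config.seed, _RESPONDING, 1])
        events += _vi_responses_and_reinfs(
            rng_arm, rng_resp, config.vi_seconds, config.response_rate_per_second,
            visits["left"], config.reinf_label, response_label="left",
        )
        events += _vi_responses_and_reinfs(
            rng_arm2, rng_resp2, config.vi_seconds_2, config.response_rate_per_second,
            visits["right"], config.reinf_label, response_label="right",
        )
    else:
        raise ValueError(f"gen_vi cannot build kind {config.kind!r}")
    events.append(Event(T, "context_off"))
    return EventRecord(events=events, t0=0.0, t_end=T)


@dataclass
class SubjectLog:
    """Decision trace of a simulated subject."""

    acquisition_trial: int | None = None       # trial of first responding
    extinction_trial: int | None = None        # trial responding ceased
    decisions: list[dict] = field(default_factory=list)


def run_virtual_subject(
    config: ProtocolConfig,
    k_learn: float = 250.0,
    k_crit: float = DEFAULT_CRITERION_NATS,
    k_response: float = 18.0,
    n_extinction_trials: int = 0,
    seed: int | None = None,
) -> tuple[EventRecord, SubjectLog]:
    """Closed-loop subject on a delay protocol.

    The subject tracks informativeness from its own record; it begins
    responding during the CS (Poisson, rate = k_response times the CS
    reinforcement rate) once the trade-off n_R*(iota-1) > k_learn is
    met, and stops when the probability change-detector (criterion
    ``k_crit`` nats, applied to CS-offset outcomes) reports a change
    during unreinforced trials.
    """
    cfg = config
    if seed is not None:
        cfg = ProtocolConfig(**{**config.__dict__, "seed": seed})
    params = LearningRateParams(k_learn=k_learn)
    rmap = ResponseRateMap(k_response=k_response)
    rng_iti = _rng(cfg, _ITI)
    rng_reinf = _rng(cfg, _REINF)
    rng_resp = _rng(cfg, _RESPONDING)

    events = [Event(0.0, "context_on")]
    log = SubjectLog()
    t = 0.0
    outcomes: list[float] = []
    off_times: list[float] = []
    responding = False
    w = 0        # change-detector / statistics window start (trial index)
    t_w = 0.0    # context time at which the current window opened

    def window_stats(now: float):
        """Counts and durations since the last detected change point."""
        n_trials_w = len(outcomes) - w
        n_r_w = int(sum(outcomes[w:]))
        t_cs_w = n_trials_w * cfg.cs_seconds
        t_ctx_w = now - t_w
        return n_r_w, t_cs_w, t_ctx_w

    total = cfg.n_trials + n_extinction_trials
    for trial in range(1, total + 1):
        p = cfg.p_reinforce if trial <= cfg.n_trials else 0.0
        t += _draw_iti(cfg, rng_iti)
        cs_on = t
        events.append(Event(t, f"cs_on:{cfg.cs_label}"))
        t += cfg.cs_seconds
        if responding:
            n_r_w, t_cs_w, _ = window_stats(t)
            lam_cs = n_r_w / t_cs_w if t_cs_w > 0 else 0.0
            rate = predict_response_rate(lam_cs, rmap)
            n_resp = rng_resp.poisson(rate * cfg.cs_seconds)
            for rt in sorted(rng_resp.uniform(cs_on, t, n_resp)):
                events.append(Event(float(rt), "response:cr"))
        reinforced = rng_reinf.random() < p
        if reinforced:
            events.append(Event(t, f"reinf:{cfg.reinf_label}"))
        events.append(Event(t, f"cs_off:{cfg.cs_label}"))
        outcomes.append(1.0 if reinforced else 0.0)
        off_times.append(t)

        # perception: within the current window, informativeness is the
        # ratio of the CS rate to the contextual rate
        n_r_w, t_cs_w, t_ctx_w = window_stats(t)
        if n_r_w > 0 and not responding:
            iota = (n_r_w / t_cs_w) / (n_r_w / t_ctx_w)
            if tradeoff_met(n_r_w, iota, params):
                responding = True
                if log.acquisition_trial is None:
                    log.acquisition_trial = trial
                log.decisions.append(
                    {"trial": trial, "event": "acquire", "iota": iota,
                     "n_r": n_r_w}
                )
        if len(outcomes) - w >= MIN_EVENTS:
            prof = ndkl_profile_prob(np.asarray(outcomes[w:]))
            rep = detect_change(prof, k_crit, window_start=w)
            if rep.detected:
                w = rep.change_index
                t_w = off_times[w - 1]
                if responding and not outcomes[-1]:
                    # rate fell: stop responding; post-change statistics
                    # start from just after the change point
                    responding = False
                    log.extinction_trial = trial
                    log.decisions.append(
                        {"trial": trial, "event": "extinguish",
                         "max_ndkl": rep.max_ndkl}
                    )
    events.append(Event(t, "context_off"))
    return EventRecord(events=events, t0=0.0, t_end=t), log
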