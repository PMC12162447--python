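"""Time allocation on concurrent schedules: the Dwell-Time Equation.

On concurrent variable-interval schedules subjects do not "choose": they
schedule departures from each location with a Poisson process, so dwell
times are exponentially distributed with a flat hazard.  The mean dwell
at location I is set by the reinforcement rate at the *other* location:

    mu_D|I = 1 / (k * lambda_R|J),

with k the proportionality between the contextual reinforcement rate
and the cycling rate.  Herrnstein's Matching Law follows by
substitution -- the dwell ratio equals the reinforcement-rate ratio and
is k-free -- and so does the cycling rate as a harmonic combination of
the two reinforcement rates.  Because the trained departure rates carry
over unchanged into probe pairings, revealed "preference" between keys
from different training pairs is predicted by the training contexts
alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import Event, EventRecord


@dataclass
class ConcurrentPair:
    """Two concurrently available locations with programmed
    reinforcement rates (per second; ~ reciprocal VI parameters)."""

    label_i: str
    label_j: str
    lambda_r_i: float
    lambda_r_j: float
    k_cycle: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_r_i <= 0 or self.lambda_r_j <= 0:
            raise ValueError("reinforcement rates must be positive")
        if self.k_cycle <= 0:
            raise ValueError("k_cycle must be positive")

    @classmethod
    def from_vi(cls, label_i, label_j, vi_i_seconds, vi_j_seconds, k_cycle=1.0):
        """Build from VI schedule parameters (programmed mean intervals)."""
        return cls(label_i, label_j, 1.0 / vi_i_seconds, 1.0 / vi_j_seconds, k_cycle)


@dataclass
class DwellPrediction:
    mu_d_i: float        # mean dwell at I, seconds
    mu_d_j: float        # mean dwell at J, seconds
    lambda_c: float      # cycling rate, cycles per second (k-scaled)
    dwell_ratio: float   # mu_d_i / mu_d_j = lambda_r_i / lambda_r_j


def dwell_times(pair: ConcurrentPair) -> DwellPrediction:
    """Mean dwell at each location: the reciprocal of k_cycle times the
    other location's reinforcement rate."""
    mu_i = 1.0 / (pair.k_cycle * pair.lambda_r_j)
    mu_j = 1.0 / (pair.k_cycle * pair.lambda_r_i)
    return DwellPrediction(
        mu_d_i=mu_i,
        mu_d_j=mu_j,
        lambda_c=1.0 / (mu_i + mu_j),
        dwell_ratio=mu_i / mu_j,
    )


def matching_ratio(pair: ConcurrentPair) -> float:
    """Dwell-time ratio mu_D|I / mu_D|J = lambda_R|I / lambda_R|J;
    independent of k_cycle (the Matching Law)."""
    return pair.lambda_r_i / pair.lambda_r_j


def cycling_rate(pair: ConcurrentPair, scaled: bool = False) -> float:
    """Cycles per unit time: 1/(1/lambda_R|1 + 1/lambda_R|2).

    The normalized (k-free) form by default, which is what is usually
    plotted; ``scaled=True`` multiplies by k_cycle.
    """
    normalized = 1.0 / (1.0 / pair.lambda_r_i + 1.0 / pair.lambda_r_j)
    return pair.k_cycle * normalized if scaled else normalized


def revealed_preference(
    pair_a: ConcurrentPair,
    pair_b: ConcurrentPair,
    probe: tuple[str, str],
) -> float:
    """Predicted dwell ratio (probe[0] over probe[1]) when keys trained
    in different pairs are probed together.

    Each key carries the departure process it ran during training, so
    the ratio depends only on the training contexts (the alternative
    rates), never on the probe pairing itself.
    """
    def trained_dwell(pair: ConcurrentPair, label: str) -> float:
        d = dwell_times(pair)
        if label == pair.label_i:
            return d.mu_d_i
        if label == pair.label_j:
            return d.mu_d_j
        raise KeyError(f"label {label!r} was not trained in pair "
                       f"({pair.label_i}, {pair.label_j})")

    return trained_dwell(pair_a, probe[0]) / trained_dwell(pair_b, probe[1])


def simulate_allocation(
    pair: ConcurrentPair, session_seconds: float, seed: int = 0
) -> EventRecord:
    """Simulate a session of alternating visits with exponentially
    distributed dwell durations at the Dwell-Time-Equation means.

    Emits ``enter:<label>`` / ``exit:<label>`` events plus context
    on/off, compatible with every temporal-map analysis.
    """
    pred = dwell_times(pair)
    if session_seconds <= max(pred.mu_d_i, pred.mu_d_j):
        raise ValueError("session shorter than an expected dwell")
    rng = np.random.default_rng([seed, 0])
    events = [Event(0.0, "context_on")]
    t = 0.0
    here, mu = (pair.label_i, pred.mu_d_i), (pair.label_j, pred.mu_d_j)
    while t < session_seconds:
        label, mean_dwell = here
        stay = rng.exponential(mean_dwell)
        leave = min(t + stay, session_seconds)
        events.append(Event(t, f"enter:{label}"))
        events.append(Event(leave, f"exit:{label}"))
        t = leave
        here, mu = mu, here
    events.append(Event(session_seconds, "context_off"))
    return EventRecord(events=events, t0=0.0, t_end=session_seconds)
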