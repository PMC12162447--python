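"""Informativeness, communicated information, and association percepts.

Informativeness (iota) is the ratio of a conditional reinforcement rate
to the contextual rate.  Because both rates carry the same time unit,
iota is unitless and time-scale invariant.  The information a predictor
communicates about the wait to the next reinforcement is the difference
between the differential entropies of the contextual and conditional
exponential interval distributions, which reduces to ln(iota).

The association percepts are logs of informativeness ratios computed
either prospectively (looking forward from a response to the next
reinforcement) or retrospectively (looking back from a reinforcement to
the most recent response).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .events import (
    EventRecord,
    NoEvidenceError,
    RateEstimate,
    backward_intervals,
    forward_intervals,
)

_LOG_BASES = {2: math.log(2.0), 10: math.log(10.0), math.e: 1.0, "e": 1.0}


def _log_in_base(x: float, base) -> float:
    try:
        denom = _LOG_BASES[base]
    except KeyError:
        raise ValueError(f"unsupported log base {base!r}; use 2, 10 or 'e'") from None
    return math.log(x) / denom


@dataclass
class Informativeness:
    """The unitless ratio iota of a conditional to a contextual rate."""

    value: float
    direction: str  # "prospective" | "retrospective"
    numerator_rate: RateEstimate | None = None
    denominator_rate: RateEstimate | None = None


@dataclass
class Association:
    """log_base(iota): zero when iota = 1, negative for inhibitory ratios.

    ``maximal`` tags the degenerate co-timed case (zero mean wait), for
    which the predictor communicates all available information; ``value``
    is then ``math.inf`` and should be rendered as "maximal" in reports.
    """

    value: float
    base: object
    informativeness: Informativeness | None = None
    maximal: bool = False


@dataclass
class EntropyValue:
    """Differential entropy of an exponential interval distribution, nats."""

    value: float
    rate_parameter: float


def informativeness(
    conditional: RateEstimate,
    contextual: RateEstimate,
    direction: str = "prospective",
) -> Informativeness:
    """iota = conditional rate / contextual rate.

    Raises :class:`NoEvidenceError` when the contextual rate is zero
    (no reinforcement observed yet: there is nothing to compare).
    """
    if contextual.rate <= 0:
        raise NoEvidenceError("contextual rate is zero: informativeness undefined")
    if conditional.rate <= 0:
        raise NoEvidenceError("conditional rate is zero: informativeness undefined")
    return Informativeness(
        value=conditional.rate / contextual.rate,
        direction=direction,
        numerator_rate=conditional,
        denominator_rate=contextual,
    )


def association(iota: Informativeness | float, base=2) -> Association:
    """The perceived association: the log of the informativeness."""
    obj = iota if isinstance(iota, Informativeness) else Informativeness(float(iota), "prospective")
    if obj.value <= 0:
        raise ValueError("informativeness must be positive")
    return Association(value=_log_in_base(obj.value, base), base=base, informativeness=obj)


def exponential_entropy(rate: float) -> EntropyValue:
    """H = 1 - ln(lambda) nats, the differential entropy of an
    exponential interval distribution with rate parameter ``lambda``."""
    if rate <= 0:
        raise ValueError("rate parameter must be positive")
    return EntropyValue(value=1.0 - math.log(rate), rate_parameter=rate)


def communicated_information(
    contextual: RateEstimate, conditional: RateEstimate
) -> float:
    """Entropy reduction H(contextual) - H(conditional) in nats.

    Algebraically identical to ln(iota); both routes are exposed so the
    identity can be verified on data.
    """
    return (
        exponential_entropy(contextual.rate).value
        - exponential_entropy(conditional.rate).value
    )


def _mean_cycle(times: list[float], record: EventRecord) -> float:
    """Mean event-to-event interval; with a single event, the contextual
    mean wait (record duration / count), to which the successive-interval
    mean converges."""
    if not times:
        raise NoEvidenceError("no events of the anchoring code")
    if len(times) >= 2:
        return (times[-1] - times[0]) / (len(times) - 1)
    return record.duration / len(times)


def prospective_association(
    record: EventRecord,
    response_code: str,
    reinf_code: str,
    base=2,
) -> Association:
    """log of (mean reinforcement-to-reinforcement interval) /
    (mean forward wait from a response to the next reinforcement).

    The factor by which making a response reduces the expected wait for
    the next reinforcement.  A zero mean forward wait (every response
    co-timed with a reinforcement) is tagged ``maximal``.
    """
    reinf_times = record.times_of(reinf_code)
    mu_rr = _mean_cycle(reinf_times, record)
    waits = forward_intervals(record, response_code, reinf_code)
    if not waits:
        raise NoEvidenceError("no response is followed by a reinforcement")
    mu_fw = sum(waits) / len(waits)
    iota = Informativeness(
        value=math.inf if mu_fw == 0 else mu_rr / mu_fw, direction="prospective"
    )
    if mu_fw == 0:
        return Association(value=math.inf, base=base, informativeness=iota, maximal=True)
    return Association(value=_log_in_base(iota.value, base), base=base, informativeness=iota)


def retrospective_association(
    record: EventRecord,
    response_code: str,
    reinf_code: str,
    base=2,
) -> Association:
    """log of (mean response-to-response interval) / (mean interval
    looking back from a reinforcement to the most recent response).

    Mirror of :func:`prospective_association`; a zero mean backward
    interval (every reinforcement co-timed with the response that
    triggered it, as on VI schedules) is tagged ``maximal``.
    """
    resp_times = record.times_of(response_code)
    mu_resp = _mean_cycle(resp_times, record)
    looks = backward_intervals(record, reinf_code, response_code)
    if not looks:
        raise NoEvidenceError("no reinforcement is preceded by a response")
    mu_bw = sum(looks) / len(looks)
    iota = Informativeness(
        value=math.inf if mu_bw == 0 else mu_resp / mu_bw, direction="retrospective"
    )
    if mu_bw == 0:
        return Association(value=math.inf, base=base, informativeness=iota, maximal=True)
    return Association(value=_log_in_base(iota.value, base), base=base, informativeness=iota)


def available_information(
    contextual: RateEstimate, resolution: float = 0.01
) -> float:
    """Information (nats) communicated by a perfectly co-timed predictor.

    Operationalized at a finite timing resolution (default 0.01 s, the
    resolution at which co-timed response and reinforcement stamps are
    indistinguishable): the log of the ratio of the contextual mean wait
    to the resolution.  This is the ceiling against which communicated
    information is compared to form a contingency.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    mu_ctx = 1.0 / contextual.rate
    if mu_ctx <= resolution:
        raise NoEvidenceError("contextual mean wait below timing resolution")
    return math.log(mu_ctx / resolution)


def contingency(communicated: float, available: float) -> float:
    """Communicated information divided by the available information.

    Clipped to [0, 1]; clipping emits a warning.  Two maximal (infinite)
    arguments -- the co-timed delay-conditioning case -- give 1.
    """
    if math.isinf(communicated) and math.isinf(available):
        return 1.0
    if available <= 0 or not math.isfinite(available):
        if math.isinf(available):
            return 0.0
        raise ValueError("available information must be positive")
    ratio = communicated / available
    if ratio < 0 or ratio > 1:
        warnings.warn(
            f"contingency {ratio:.3g} outside [0, 1]; clipped", stacklevel=2
        )
        ratio = min(max(ratio, 0.0), 1.0)
    return ratio
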