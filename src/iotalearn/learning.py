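"""The Learning Rate Law and its comparison baseline.

The learning rate -- the reciprocal of the median number of
reinforcements before conditioned responding appears -- is an almost
scalar function of informativeness:

    alpha = (iota - 1) / k,   1 <= iota <= k + 1,

where k is the informativeness that produces one-shot acquisition in the
median subject.  Equivalently, reinforcements-to-acquisition
RtoAcq = k / (iota - 1), so k = RtoAcq * (iota - 1) can be estimated
from any acquisition experiment.  The trade-off form of the same law,
n_R * (iota - 1) > k, is the decision rule for beginning to respond.

Observed response rates are a scalar multiple of the reinforcement rate
the responded-to state predicts (scale factor ~18 for pigeon hopper
entry).  The Rescorla-Wagner delta rule is included strictly as the
classical trial-based baseline the rate-based account replaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

#: default one-shot informativeness constants, by preparation
#: (delay protocols with pigeons/rats; trace protocols with head-fixed mice)
K_LEARN_DELAY_PIGEON_RAT = 250.0
K_LEARN_TRACE_MOUSE = 5200.0


@dataclass
class LearningRateParams:
    """k: the informativeness giving one-shot acquisition (median subject)."""

    k_learn: float = K_LEARN_DELAY_PIGEON_RAT

    def __post_init__(self) -> None:
        if self.k_learn <= 1:
            raise ValueError("k_learn must exceed 1")


@dataclass
class ResponseRateMap:
    """Scalar map from predicted reinforcement rate to response rate."""

    k_response: float = 18.0

    def __post_init__(self) -> None:
        if self.k_response <= 0:
            raise ValueError("k_response must be positive")


def _iota_value(iota) -> float:
    return getattr(iota, "value", iota)


def learning_rate(iota, params: LearningRateParams) -> float:
    """alpha = (iota - 1)/k, the per-reinforcement learning rate.

    Zero at iota = 1 (no excitatory learning); clipped to 1 (with a
    warning) beyond the one-shot point iota = k + 1.
    """
    i = _iota_value(iota)
    if i < 1:
        raise ValueError("iota < 1: no excitatory learning predicted")
    alpha = (i - 1.0) / params.k_learn
    if alpha > 1.0:
        warnings.warn(
            f"learning rate {alpha:.3g} > 1 clipped to 1 (one-shot regime)",
            stacklevel=2,
        )
        alpha = 1.0
    return alpha


def reinforcements_to_acquisition(iota, params: LearningRateParams) -> float:
    """RtoAcq = k/(iota - 1), the predicted median number of
    reinforcements before conditioned responding appears."""
    i = _iota_value(iota)
    if i <= 1:
        raise ValueError("iota must exceed 1 for a finite acquisition count")
    return params.k_learn / (i - 1.0)


def estimate_k(rto_acq: float, iota, rounded: bool = True) -> float:
    """k = RtoAcq * (iota - 1), estimated from an observed acquisition
    median; rounded to the nearest integer for reporting by default."""
    i = _iota_value(iota)
    if i <= 1:
        raise ValueError("iota must exceed 1")
    if rto_acq <= 0:
        raise ValueError("RtoAcq must be positive")
    k = rto_acq * (i - 1.0)
    return float(round(k)) if rounded else k


def tradeoff_met(n_r: int, iota, params: LearningRateParams) -> bool:
    """True when n_R * (iota - 1) exceeds k: the accumulated product of
    reinforcement count and informativeness licenses responding."""
    if n_r < 0:
        raise ValueError("reinforcement count cannot be negative")
    i = _iota_value(iota)
    return n_r * (i - 1.0) > params.k_learn


def predict_response_rate(
    reinforcement_rate: float, map: ResponseRateMap = ResponseRateMap()
) -> float:
    """Predicted response rate: k_response times the reinforcement rate."""
    if reinforcement_rate < 0:
        raise ValueError("reinforcement rate cannot be negative")
    return map.k_response * reinforcement_rate


@dataclass
class RWState:
    """Rescorla-Wagner associative strengths (comparison baseline only)."""

    associations: dict[str, float] = field(default_factory=dict)
    alpha_rw: float = 0.1
    lambda_asymptote: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha_rw <= 1):
            raise ValueError("alpha_rw must lie in (0, 1]")


def rescorla_wagner_step(
    state: RWState, present: set[str], reinforced: bool
) -> RWState:
    """One delta-rule trial: dA_i = alpha * (Lambda*[reinforced] - sum of
    present associations), applied to the present labels only."""
    unknown = set(present) - set(state.associations)
    if unknown:
        raise KeyError(f"labels not in state: {sorted(unknown)}")
    total = sum(state.associations[l] for l in present)
    target = state.lambda_asymptote if reinforced else 0.0
    delta = state.alpha_rw * (target - total)
    new_assoc = dict(state.associations)
    for l in present:
        new_assoc[l] += delta
    return replace(state, associations=new_assoc)
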