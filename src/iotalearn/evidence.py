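"""Strength of evidence for an association: the nDKL statistic.

nDKL is the Kullback-Leibler divergence of the conditional interval
distribution from the contextual one, multiplied by an effective sample
size that depends only on the two reinforcement counts.  It is
computable from a sample of one, which is what licenses one-shot
learning when the temporal relation is sufficiently informative.  Under
the null (informativeness 1) the statistic is distributed gamma(.5, 1),
which yields exact p-values and odds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import EventRecord, NoEvidenceError, RateEstimate, conditional_rate, state_windows


def nats_to_bits(x: float) -> float:
    return x / math.log(2.0)


def bits_to_nats(x: float) -> float:
    return x * math.log(2.0)


@dataclass
class EvidenceResult:
    """nDKL with its ingredients and gamma(.5, 1) calibration."""

    n_effective: float
    dkl: float          # nats per observation
    ndkl: float         # nats
    p_value: float
    odds_against_null: float
    direction: str = "excitatory"  # "inhibitory" when iota < 1


def effective_n(n_conditional: int, n_contextual: int) -> float:
    """n_cond / (1 + n_cond/n_ctx); 0.5 when both counts are 1."""
    if n_conditional < 1 or n_contextual < 1:
        raise NoEvidenceError("both reinforcement counts must be at least 1")
    return n_conditional / (1.0 + n_conditional / n_contextual)


def kl_exponential(lambda_conditional: float, lambda_contextual: float) -> float:
    """KL divergence (nats/observation) between exponential interval
    distributions: ln(iota) + 1/iota - 1 with iota the rate ratio.

    Non-negative, zero iff the rates are equal, and asymmetric in its
    arguments: divergences are harder to detect in one direction than
    the other.
    """
    if lambda_conditional <= 0 or lambda_contextual <= 0:
        raise ValueError("rates must be positive")
    iota = lambda_conditional / lambda_contextual
    return math.log(iota) + 1.0 / iota - 1.0


def kl_bernoulli(p_hat, p_ref):
    """Bernoulli KL divergence in nats/trial, with 0*ln(0) = 0.

    Accepts scalars or arrays.  When the reference probability is 0 or 1
    and the estimate disagrees, the divergence is infinite (returned as
    ``inf``, which any finite decision criterion treats as maximal).
    """
    p = np.asarray(p_hat, dtype=float)
    q = np.asarray(p_ref, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any((q < 0) | (q > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(p > 0, p * np.log(np.where(p > 0, p, 1) / np.where(q > 0, q, np.nan)), 0.0)
        term2 = np.where(
            p < 1,
            (1 - p) * np.log(np.where(p < 1, 1 - p, 1) / np.where(q < 1, 1 - q, np.nan)),
            0.0,
        )
    out = term1 + term2
    # reference at an edge, estimate disagreeing -> infinite divergence
    out = np.where(np.isnan(out), np.inf, out)
    out = np.where((p == q), 0.0, out)
    if np.ndim(p_hat) == 0 and np.ndim(p_ref) == 0:
        return float(out)
    return out


def gamma_tail_p(ndkl_nats: float) -> float:
    """Upper-tail probability of gamma(shape .5, scale 1) at ``ndkl``."""
    return float(stats.gamma.sf(ndkl_nats, a=0.5, scale=1.0))


def ndkl(
    n_conditional: int,
    n_contextual: int,
    rate_conditional: float,
    rate_contextual: float,
) -> EvidenceResult:
    """Assemble the full evidence statistic from counts and rates.

    The contextual count includes the conditional reinforcements (in the
    single-reinforcement worked case both counts are the same event).
    """
    n_e = effective_n(n_conditional, n_contextual)
    dkl = kl_exponential(rate_conditional, rate_contextual)
    nd = n_e * dkl
    p = gamma_tail_p(nd)
    odds = (1.0 - p) / p if p > 0 else math.inf
    direction = "excitatory" if rate_conditional >= rate_contextual else "inhibitory"
    return EvidenceResult(
        n_effective=n_e,
        dkl=dkl,
        ndkl=nd,
        p_value=p,
        odds_against_null=odds,
        direction=direction,
    )


def ndkl_from_rates(
    conditional: RateEstimate, contextual: RateEstimate
) -> EvidenceResult:
    """Evidence statistic from two :class:`RateEstimate` objects."""
    return ndkl(conditional.count, contextual.count, conditional.rate, contextual.rate)


def ndkl_from_record(
    record: EventRecord, cs_label: str, reinf_code: str
) -> EvidenceResult:
    """Evidence for the association between a CS state and reinforcement,
    computed directly off a temporal map."""
    cond = conditional_rate(record, reinf_code, state_windows(record, cs_label))
    ctx = conditional_rate(record, reinf_code, None)
    return ndkl_from_rates(cond, ctx)
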