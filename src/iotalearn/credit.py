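"""Assignment of credit: attributed rates from observed rates.

Each candidate predictor (the context first, then the CSs) has an
observed conditional reinforcement rate.  The temporal-probability
matrix P holds, in entry (i, j), the probability that predictor j is
present at a randomly chosen moment when predictor i is present -- a
ratio of cumulative durations, hence unitless.  The observed rates are
P times the *attributed* rates, so the attributed column is recovered by
a linear solve.  Negative attributed rates are meaningful (inhibitory
prediction); identical predictors make P singular and are reported as a
merged compound rather than split arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventRecord, StateWindow, state_windows


class SingularMatrixError(ValueError):
    """The temporal-probability matrix is singular or near-singular."""


@dataclass
class TemporalProbabilityMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("diagonal of a temporal-probability matrix is 1")
        if np.any(self.matrix < -1e-12) or np.any(self.matrix > 1 + 1e-12):
            raise ValueError("temporal probabilities must lie in [0, 1]")


@dataclass
class CreditSolution:
    labels: list[str]
    observed: np.ndarray    # conditional rates, per second
    attributed: np.ndarray  # solved rates, per second
    residual: float         # max |P @ attributed - observed|


def _overlap(a: StateWindow, b: StateWindow) -> float:
    """Cumulative duration of b while a is present."""
    total = 0.0
    for s1, e1 in a.intervals:
        for s2, e2 in b.intervals:
            total += max(0.0, min(e1, e2) - max(s1, s2))
    return total


def build_matrix(
    record: EventRecord, predictor_labels: list[str]
) -> TemporalProbabilityMatrix:
    """Temporal probabilities from a record's state windows.

    Entry (i, j) = duration of predictor j while i is present, divided
    by the duration of predictor i.  Conventionally the context is the
    first label, making the upper-right entry 1/informativeness when all
    reinforcement occurs during the CS.
    """
    windows = [state_windows(record, lab) for lab in predictor_labels]
    for w in windows:
        if w.duration <= 0:
            raise ValueError(f"predictor {w.label} has zero cumulative duration")
    n = len(windows)
    P = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            P[i, j] = _overlap(windows[i], windows[j]) / windows[i].duration
    return TemporalProbabilityMatrix(labels=list(predictor_labels), matrix=P)


def _collinear_pairs(P: np.ndarray, labels: list[str]) -> list[tuple[str, str]]:
    pairs = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if np.allclose(P[i], P[j], atol=1e-10):
                pairs.append((labels[i], labels[j]))
    return pairs


def attribute(
    matrix: TemporalProbabilityMatrix,
    observed_rates,
    cond_threshold: float = 1e8,
) -> CreditSolution:
    """Solve P @ attributed = observed by a stable linear solve.

    Raises :class:`SingularMatrixError`, naming collinear predictors
    (e.g. perfectly compounded CSs with identical presence windows),
    when the condition number exceeds ``cond_threshold``; callers should
    merge such predictors into one compound before re-solving.
    """
    P = matrix.matrix
    lam = np.asarray(observed_rates, dtype=float)
    if lam.shape != (len(matrix.labels),):
        raise ValueError("observed rates must align with the matrix labels")
    cond = np.linalg.cond(P)
    if not np.isfinite(cond) or cond > cond_threshold:
        pairs = _collinear_pairs(P, matrix.labels)
        detail = (
            f" (collinear predictors: {pairs})" if pairs else ""
        )
        raise SingularMatrixError(
            f"temporal-probability matrix is singular or ill-conditioned "
            f"(condition number {cond:.3g}){detail}; merge compounded "
            f"predictors into a single predictor"
        )
    attributed = np.linalg.solve(P, lam)
    residual = float(np.max(np.abs(P @ attributed - lam)))
    return CreditSolution(
        labels=list(matrix.labels),
        observed=lam,
        attributed=attributed,
        residual=residual,
    )


def contextual_vs_attributed(solution: CreditSolution) -> list[dict]:
    """Pair each predictor's observed conditional rate with the rate the
    solution attributes to it.

    The distinction matters most for the context: its conditional rate
    may be substantial (it predicts the CSs during which reinforcement
    occurs) while its attributed rate is zero.
    """
    return [
        {
            "predictor": lab,
            "observed_rate": float(obs),
            "attributed_rate": float(att),
        }
        for lab, obs, att in zip(
            solution.labels, solution.observed, solution.attributed
        )
    ]
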