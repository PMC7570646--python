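"""Decision-level fusion of per-sensor probability lists.

Each sensor emits, once per decision tick, a probability-ordered list of
activities ``{(A_i, p_i)}``.  The fusion stage scales every sensor's
probabilities by a weight ``W_k`` and sums per activity; the fused decision
is the argmax.  Weights derive from three modulation coefficients:

* ``H_k`` — an activity-independent cost coefficient per sensor (hardware,
  installation, maintenance, user acceptance), constant in time;
* ``R_k(A)`` — the activity-dependent reliability of sensor ``k``, read from
  the single-sensor rows of a reliability table (percent scale; the scale
  cancels in normalization);
* ``L(n) = n^-p`` — a penalty attenuating sensors by their position ``n`` in
  the per-activity reliability ranking.  Small ``p`` equalizes the ranking
  (genuinely multimodal blending); large ``p`` approaches winner-take-all
  switching to the single best sensor.

The contribution of sensor ``k`` for activity ``A`` is
``C_k = H_k * R_k(A) * L(n_k)`` and the weights are ``W_k = C_k / sum(C)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    ACTIVITIES,
    SENSORS,
    ReliabilityTable,
    ValidationError,
    validate_activity,
)

__all__ = [
    "CostProfile",
    "PenaltyParams",
    "ProbabilityList",
    "FusionDecision",
    "penalty",
    "rank_sensors",
    "contributions",
    "normalize",
    "fuse",
    "target_weights",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class CostProfile:
    """Per-sensor cost coefficients ``H_k`` (> 0, constant in time).

    Extreme values defeat adaptation (a near-zero cost weight effectively
    removes a sensor; a huge one pins it); values of comparable magnitude
    are recommended.  The default is 1 for every sensor.
    """

    H: Mapping[str, float]

    def __post_init__(self) -> None:
        for k, v in self.H.items():
            if k not in SENSORS:
                raise ValidationError(f"unknown sensor id {k!r} in cost profile")
            if not v > 0:
                raise ValidationError(f"cost H[{k}] must be > 0, got {v}")

    @classmethod
    def uniform(cls, value: float = 1.0) -> "CostProfile":
        return cls({s: value for s in SENSORS})


@dataclass(frozen=True)
class PenaltyParams:
    """Rank-penalty exponent ``p`` of ``L(n) = n^-p``, with ``p`` in (0.1, 10)."""

    p: float = 1.0

    def __post_init__(self) -> None:
        if not (0.1 < self.p < 10.0):
            raise ValidationError(f"penalty exponent p must lie in (0.1, 10), got {self.p}")


def penalty(n: int, params: PenaltyParams) -> float:
    """Penalty factor ``L(n) = n^-p`` for reliability rank ``n`` (1 = best)."""
    if int(n) != n or n < 1:
        raise ValidationError(f"rank must be an integer >= 1, got {n}")
    return float(n) ** (-params.p)


@dataclass(frozen=True)
class ProbabilityList:
    """One sensor's output at a decision tick: activities by descending probability.

    ``sensor`` is the emitting sensor (or sensor-set) id.  Entries must be
    unique activities with probabilities in [0, 1], non-increasing, summing
    to 1 within 1e-9.
    """

    sensor: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("probability list must be non-empty")
        labels = [a for a, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate activity in probability list: {labels}")
        probs = np.array([p for _, p in self.entries], dtype=float)
        for a in labels:
            validate_activity(a)
        if np.any(probs < -_PROB_TOL) or np.any(probs > 1 + _PROB_TOL):
            raise ValidationError("probabilities must lie in [0, 1]")
        if np.any(np.diff(probs) > _PROB_TOL):
            raise ValidationError("probability list must be in non-increasing order")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError(f"probabilities must sum to 1, got {probs.sum()!r}")

    @classmethod
    def from_scores(cls, sensor: str, scores: Mapping[str, float]) -> "ProbabilityList":
        """Build a normalized, ordered list from unnormalized activity scores."""
        total = float(sum(scores.values()))
        if total <= 0:
            raise ValidationError("scores must have positive sum")
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(sensor=sensor, entries=tuple((a, v / total) for a, v in items))

    @property
    def top(self) -> str:
        return self.entries[0][0]

    def probability(self, activity: str) -> float:
        for a, p in self.entries:
            if a == activity:
                return p
        return 0.0


@dataclass(frozen=True)
class FusionDecision:
    """Fused decision: argmax of the weighted per-activity score sum.

    ``tie`` records whether the winning score was shared (broken by canonical
    activity-code order).
    """

    activity: str
    score: float
    per_activity_scores: dict[str, float]
    weights_used: dict[str, float]
    tie: bool = False


def rank_sensors(
    table: ReliabilityTable,
    activity: str,
    active: Iterable[str] = SENSORS,
) -> dict[str, int]:
    """Competition ranking of active sensors by single-sensor reliability.

    Ties share the smallest rank of their group and the following rank is
    skipped ("1224" style), so a unique leader always has rank 1.
    """
    active = sorted(set(active), key=SENSORS.index)
    if not active:
        raise ValidationError("active sensor set must be non-empty")
    rel = {s: table.single_sensor_reliability(s, activity) for s in active}
    ordered = sorted(active, key=lambda s: (-rel[s], s))
    ranks: dict[str, int] = {}
    for i, s in enumerate(ordered):
        if i > 0 and rel[s] == rel[ordered[i - 1]]:
            ranks[s] = ranks[ordered[i - 1]]
        else:
            ranks[s] = i + 1
    return ranks


def contributions(
    cost: CostProfile,
    table: ReliabilityTable,
    activity: str,
    params: PenaltyParams = PenaltyParams(),
    active: Iterable[str] = SENSORS,
) -> dict[str, float]:
    """Per-sensor contribution ``C_k = H_k * R_k(A) * L(n_k)`` for an activity.

    Sensors not in ``active`` are excluded (their weight downstream is 0).
    ``R_k`` is taken from the single-sensor rows on the printed percent scale.
    """
    active = sorted(set(active), key=SENSORS.index)
    if not active:
        raise ValidationError("active sensor set must be non-empty")
    for s in active:
        if s not in cost.H:
            raise ValidationError(f"cost profile missing sensor {s!r}")
    ranks = rank_sensors(table, activity, active)
    return {
        s: cost.H[s]
        * table.single_sensor_reliability(s, activity)
        * penalty(ranks[s], params)
        for s in active
    }


def normalize(C: Mapping[str, float]) -> dict[str, float]:
    """Normalize contributions to weights ``W_k = C_k / sum(C)``."""
    if not C:
        raise ValidationError("contribution vector must be non-empty")
    for k, v in C.items():
        if v < 0:
            raise ValidationError(f"contribution C[{k}] must be >= 0, got {v}")
    total = float(sum(C.values()))
    if total <= 0:
        raise ValidationError("all contributions are zero; weights undefined")
    return {k: v / total for k, v in C.items()}


def target_weights(
    cost: CostProfile,
    table: ReliabilityTable,
    activity: str,
    params: PenaltyParams = PenaltyParams(),
    active: Iterable[str] = SENSORS,
) -> dict[str, float]:
    """Normalized weight vector maximizing reliability for ``activity``."""
    return normalize(contributions(cost, table, activity, params, active))


def fuse(
    outputs: Sequence[ProbabilityList],
    W: Mapping[str, float],
) -> FusionDecision:
    """Weighted decision-level fusion of sensor probability lists.

    The score of activity ``A`` is ``sum_k W_k * p_{A,k}``, a sensor
    contributing 0 for activities absent from its list.  The decision is the
    maximum-score activity; exact score ties are broken by canonical activity
    order and flagged.
    """
    if not outputs:
        raise ValidationError("at least one sensor output is required")
    for out in outputs:
        if out.sensor not in W:
            raise ValidationError(f"no weight supplied for sensor {out.sensor!r}")
    scores: dict[str, float] = {}
    for out in outputs:
        w = float(W[out.sensor])
        for a, p in out.entries:
            scores[a] = scores.get(a, 0.0) + w * p
    top_score = max(scores.values())
    winners = [a for a, v in scores.items() if v == top_score]
    activity = min(winners)
    return FusionDecision(
        activity=activity,
        score=scores[activity],
        per_activity_scores=scores,
        weights_used=dict(W),
        tie=len(winners) > 1,
    )
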