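"""Feedback adaptation of sensor contributions.

Re-weighting sensors after a recognition closes an information loop: the new
weights could change the very decision they were derived from.  Stability is
enforced explicitly — the modulator may move the weight vector from its
current value ``W_start`` toward a reliability-optimal target ``W_target``
only as far as the fused decision stays unchanged.  The admissible point is
found by bisecting the straight segment between the two vectors (which keeps
the weights normalized along the whole path).

Two adaptation policies are provided:

* *conservative*: the target weights confirm the currently detected
  activity — the system expects a stable status;
* *predictive*: the target weights prepare for the most probable **next**
  activity, looked up in a habits database (a first-order transition model
  learned from the subject's past activity sequences).

Sensor-set selection uses the per-activity reliability hierarchy together
with a consistency rule: among equally reliable sets, keep the previously
used one (or the closest to it) to avoid churn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    ACTIVITIES,
    SENSORS,
    ReliabilityTable,
    SensorHierarchy,
    ValidationError,
    build_hierarchy,
    sensor_set,
    validate_activity,
)
from .fusion import (
    CostProfile,
    FusionDecision,
    PenaltyParams,
    ProbabilityList,
    fuse,
    normalize,
    target_weights,
)

__all__ = [
    "HabitsDB",
    "AdaptationState",
    "StabilityResult",
    "ConfigurationError",
    "stability_limit",
    "consistency_select",
    "habits_update",
    "habits_predict",
    "conservative_step",
    "predictive_step",
    "available_pool",
]


class ConfigurationError(RuntimeError):
    """Raised when the system cannot operate (e.g. no sensor available)."""


# ---------------------------------------------------------------------------
# Habits database
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HabitsDB:
    """First-order transition counts between activity codes.

    Stores raw counts (not probabilities) so the model can be updated
    incrementally and persisted losslessly; transition probabilities are
    derived on demand by row normalization.
    """

    transition_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), n in self.transition_counts.items():
            validate_activity(a)
            validate_activity(b)
            if n < 0:
                raise ValidationError(f"negative transition count for {(a, b)}")

    @property
    def marginal_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (a, _), n in self.transition_counts.items():
            out[a] = out.get(a, 0) + n
        return out

    def row(self, current: str) -> dict[str, int]:
        validate_activity(current)
        return {
            b: n for (a, b), n in self.transition_counts.items() if a == current and n > 0
        }

    def row_probabilities(self, current: str) -> dict[str, float]:
        row = self.row(current)
        total = sum(row.values())
        return {b: n / total for b, n in row.items()} if total else {}

    def is_empty(self) -> bool:
        return not any(n > 0 for n in self.transition_counts.values())

    # -- persistence (counts only) --------------------------------------
    def to_dict(self) -> dict[str, dict[str, int]]:
        nested: dict[str, dict[str, int]] = {}
        for (a, b), n in sorted(self.transition_counts.items()):
            if n > 0:
                nested.setdefault(a, {})[b] = n
        return nested

    @classmethod
    def from_dict(cls, nested: Mapping[str, Mapping[str, int]]) -> "HabitsDB":
        counts = {
            (a, b): int(n)
            for a, row in nested.items()
            for b, n in row.items()
        }
        return cls(transition_counts=counts)


def habits_update(db: HabitsDB, sequence: Sequence[str]) -> HabitsDB:
    """Return a habits database with counts of each adjacent pair added.

    Counting is additive: updating with two sequences equals updating with
    their concatenation when the boundary pair is included explicitly.
    """
    for a in sequence:
        validate_activity(a)
    counts = dict(db.transition_counts)
    for a, b in zip(sequence, sequence[1:]):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return HabitsDB(transition_counts=counts)


def habits_predict(db: HabitsDB, current: str) -> str:
    """Most probable next activity after ``current``.

    Falls back to the overall most frequent source activity when the current
    row is empty, and to ``current`` itself (no adaptation) when the database
    is empty.  Count ties are broken by canonical activity order.
    """
    validate_activity(current)
    row = db.row(current)
    if row:
        return min(row, key=lambda a: (-row[a], ACTIVITIES.index(a)))
    marginals = db.marginal_counts
    marginals = {a: n for a, n in marginals.items() if n > 0}
    if marginals:
        return min(marginals, key=lambda a: (-marginals[a], ACTIVITIES.index(a)))
    return current


# ---------------------------------------------------------------------------
# Stability-constrained weight modulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StabilityResult:
    """Outcome of the stability-limited move from ``W_start`` toward ``W_target``.

    ``W_limit`` is the farthest admissible weight vector on the segment;
    fusing with it yields the same activity as fusing with ``W_start``.
    ``t`` is the mixing fraction reached (0 = start, 1 = target).
    """

    W_limit: dict[str, float]
    reached_target: bool
    iterations: int
    t: float = 0.0


def _check_normalized(W: Mapping[str, float], name: str) -> None:
    total = sum(W.values())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"{name} is not normalized (sum = {total})")
    if any(v < -1e-12 for v in W.values()):
        raise ValidationError(f"{name} has negative weights")


def _mix(W1: Mapping[str, float], W2: Mapping[str, float], t: float) -> dict[str, float]:
    return {k: (1.0 - t) * W1[k] + t * W2[k] for k in W1}


def stability_limit(
    outputs: Sequence[ProbabilityList],
    W_start: Mapping[str, float],
    W_target: Mapping[str, float],
    tol: float = 1e-3,
    max_iter: int = 32,
) -> StabilityResult:
    """Farthest point toward ``W_target`` that preserves the current decision.

    The weight path is the straight segment ``(1-t)*W_start + t*W_target``
    for ``t`` in [0, 1] (convexity keeps the vector normalized).  If the
    fused decision at the target already matches the decision at the start,
    the target is admissible outright.  Otherwise the flip point is bracketed
    by bisection on ``t`` until the interval is no longer than ``tol``; the
    stable (lower) end is returned.
    """
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    if set(W_start) != set(W_target):
        raise ValidationError("weight vectors must cover the same sensors")
    _check_normalized(W_start, "W_start")
    _check_normalized(W_target, "W_target")

    base = fuse(outputs, W_start).activity
    if fuse(outputs, dict(W_target)).activity == base:
        return StabilityResult(
            W_limit=dict(W_target), reached_target=True, iterations=0, t=1.0
        )
    lo, hi = 0.0, 1.0
    iterations = 0
    while hi - lo > tol and iterations < max_iter:
        mid = 0.5 * (lo + hi)
        if fuse(outputs, _mix(W_start, W_target, mid)).activity == base:
            lo = mid
        else:
            hi = mid
        iterations += 1
    return StabilityResult(
        W_limit=_mix(W_start, W_target, lo),
        reached_target=False,
        iterations=iterations,
        t=lo,
    )


# ---------------------------------------------------------------------------
# Sensor-set consistency rule
# ---------------------------------------------------------------------------


def consistency_select(hierarchy: SensorHierarchy, previous: str) -> str:
    """Pick a sensor set from the top tie-group, preferring continuity.

    The previously used set is kept whenever it belongs to the most reliable
    group; otherwise the group member sharing the most sensors with the
    previous set wins, remaining ties broken by canonical order (fewest
    sensors first, then alphabetical).
    """
    previous = sensor_set(previous)
    top = hierarchy.top_group
    if previous in top:
        return previous
    prev = set(previous)
    return min(top, key=lambda s: (-len(set(s) & prev), len(s), s))


def available_pool(available: Iterable[str]) -> tuple[str, ...]:
    """Candidate sensor sets over the available sensors.

    Multi-sensor combinations when two or more sensors are up; the lone
    singleton otherwise.
    """
    avail = sorted(set(available), key=SENSORS.index)
    if not avail:
        raise ConfigurationError("no sensors available")
    if len(avail) == 1:
        return (avail[0],)
    from itertools import combinations

    return tuple(
        "".join(c) for r in range(2, len(avail) + 1) for c in combinations(avail, r)
    )


# ---------------------------------------------------------------------------
# Adaptation steps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdaptationState:
    """State carried between decision ticks.

    ``current_weights`` covers all sensors; unavailable sensors hold weight
    exactly 0 and the remainder is normalized.  ``current_set`` is the sensor
    set currently preferred for feature extraction.
    """

    current_weights: dict[str, float]
    current_set: str
    availability: dict[str, bool] = field(default_factory=lambda: {s: True for s in SENSORS})
    current_decision: FusionDecision | None = None
    predicted_next: str | None = None
    mode: str = "conservative"
    last_stability: StabilityResult | None = None

    @property
    def available_sensors(self) -> tuple[str, ...]:
        return tuple(s for s in SENSORS if self.availability.get(s, True))

    @classmethod
    def initial(
        cls,
        availability: Mapping[str, bool] | None = None,
        mode: str = "conservative",
    ) -> "AdaptationState":
        avail = {s: True for s in SENSORS}
        if availability:
            avail.update(availability)
        up = [s for s in SENSORS if avail[s]]
        if not up:
            raise ConfigurationError("no sensors available")
        w = {s: (1.0 / len(up) if s in up else 0.0) for s in SENSORS}
        return cls(current_weights=w, current_set=sensor_set(up), availability=avail, mode=mode)

    def with_availability(self, overrides: Mapping[str, bool]) -> "AdaptationState":
        """Apply availability changes: dropped sensors are zero-weighted and
        the remaining weights renormalize immediately."""
        avail = dict(self.availability)
        avail.update(overrides)
        up = [s for s in SENSORS if avail.get(s, True)]
        if not up:
            raise ConfigurationError("no sensors available")
        w = {s: (self.current_weights.get(s, 0.0) if s in up else 0.0) for s in SENSORS}
        total = sum(w.values())
        if total <= 0:
            w = {s: (1.0 / len(up) if s in up else 0.0) for s in SENSORS}
        else:
            w = {s: v / total for s, v in w.items()}
        return replace(self, availability=avail, current_weights=w)


def _active_weights(state: AdaptationState) -> dict[str, float]:
    up = state.available_sensors
    w = {s: state.current_weights.get(s, 0.0) for s in up}
    total = sum(w.values())
    if total <= 0:
        w = {s: 1.0 / len(up) for s in up}
    else:
        w = {s: v / total for s, v in w.items()}
    return w


def _step(
    state: AdaptationState,
    outputs: Sequence[ProbabilityList],
    table: ReliabilityTable,
    cost: CostProfile,
    params: PenaltyParams,
    tol: float,
    target_activity_for: callable,
    mode: str,
) -> AdaptationState:
    up = state.available_sensors
    if not up:
        raise ConfigurationError("no sensors available")
    outputs = [o for o in outputs if o.sensor in up]
    if not outputs:
        raise ConfigurationError("no outputs from available sensors")

    w_now = _active_weights(state)
    decision = fuse(outputs, w_now)
    target_act = target_activity_for(decision.activity)
    active = tuple(o.sensor for o in outputs)
    w_target = target_weights(cost, table, target_act, params, active=active)
    # both vectors must span the same sensors for the segment search
    w_now_active = normalize({s: w_now.get(s, 0.0) for s in active}) if set(active) != set(w_now) else w_now
    stab = stability_limit(outputs, w_now_active, w_target, tol=tol)

    hierarchy = build_hierarchy(table, decision.activity, pool=available_pool(up))
    new_set = consistency_select(hierarchy, state.current_set)

    new_weights = {s: 0.0 for s in SENSORS}
    new_weights.update(stab.W_limit)
    return replace(
        state,
        current_weights=new_weights,
        current_set=new_set,
        current_decision=decision,
        predicted_next=target_act if mode == "predictive" else None,
        mode=mode,
        last_stability=stab,
    )


def conservative_step(
    state: AdaptationState,
    outputs: Sequence[ProbabilityList],
    table: ReliabilityTable,
    cost: CostProfile = CostProfile.uniform(),
    params: PenaltyParams = PenaltyParams(),
    tol: float = 1e-3,
) -> AdaptationState:
    """One confirmative adaptation tick.

    Fuses the current outputs with the current weights, derives the
    reliability-optimal weights *for the detected activity*, moves toward
    them under the stability constraint, and reselects the sensor set from
    the detected activity's hierarchy with the consistency rule.
    """
    return _step(state, outputs, table, cost, params, tol,
                 target_activity_for=lambda detected: detected,
                 mode="conservative")


def predictive_step(
    state: AdaptationState,
    outputs: Sequence[ProbabilityList],
    table: ReliabilityTable,
    cost: CostProfile = CostProfile.uniform(),
    params: PenaltyParams = PenaltyParams(),
    habits: HabitsDB = HabitsDB(),
    tol: float = 1e-3,
) -> AdaptationState:
    """One predictive adaptation tick.

    As :func:`conservative_step`, except the weight target is computed for
    the most probable **next** activity according to the habits database.
    The stability constraint is still enforced against the current decision,
    and the sensor set is selected for the detected (current) activity.
    With an empty habits database this reduces to the conservative step.
    """
    return _step(state, outputs, table, cost, params, tol,
                 target_activity_for=lambda detected: habits_predict(habits, detected),
                 mode="predictive")
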