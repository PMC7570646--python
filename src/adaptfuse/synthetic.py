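"""Synthetic inputs: activity sequences, sensor streams, feature vectors.

No public recording of the original four-sensor experiment exists, so every
consumer of sensor data in this package is exercised with synthetic inputs
whose statistics are configured explicitly:

* **Activity sequences** come from scripted scenarios (fixed pose orders with
  durations and sensor-availability events) or are sampled from a habits
  database (first-order Markov chain).
* **Sensor probability streams** emulate per-sensor classifiers whose top-1
  correctness per activity matches a configured confusion model — typically
  the single-sensor rows of the packaged reliability table divided by 100.
  Errors are spread uniformly over the eleven wrong activities by default
  (the published per-set confusion matrices are not available; the spread is
  pluggable).
* **Feature vectors** stand in for the real per-sensor signal processing.
  Each activity owns a fixed prototype: a random ±1 sign pattern on its own
  coordinate block, zero elsewhere, scaled to unit magnitude.  Prototypes are
  therefore mutually equidistant in the Manhattan metric, so class difficulty
  is uniform by construction and a single Gaussian noise scale maps
  monotonically onto a recognition rate (see :func:`calibrate_noise`).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .adaptation import HabitsDB
from .core import ACTIVITIES, SENSORS, ReliabilityTable, ValidationError, validate_activity
from .fusion import ProbabilityList
from .knn import FEATURE_LENGTHS, LabeledDataset, knn_classify_batch, split_train_test

__all__ = [
    "ConfusionModel",
    "ScenarioScript",
    "shelf_search_script",
    "gen_activity_sequence",
    "gen_sensor_stream",
    "gen_feature_vectors",
    "knn_recognition_rate",
    "calibrate_noise",
]

#: Pose order of the "searching a book on the shelf" compound action.
SHELF_SEARCH_POSES: tuple[str, ...] = ("4a", "4b", "3a", "3b", "5a", "5b", "1a", "1b")


@dataclass(frozen=True)
class ConfusionModel:
    """Per-(sensor, activity) probability that the top-1 output is correct.

    ``error_spread`` chooses how the remaining probability mass is assigned
    when a wrong activity is drawn; only ``"uniform"`` (maximum entropy over
    the 11 wrong codes) is built in.
    """

    correct_prob: dict[tuple[str, str], float]
    error_spread: str = "uniform"

    def __post_init__(self) -> None:
        if self.error_spread != "uniform":
            raise ValidationError(f"unknown error_spread {self.error_spread!r}")
        for (s, a), p in self.correct_prob.items():
            validate_activity(a)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"correct_prob[{s},{a}] = {p} outside [0, 1]")

    def probability(self, sensor: str, activity: str) -> float:
        return self.correct_prob[(sensor, activity)]

    @classmethod
    def from_reliability_table(
        cls, table: ReliabilityTable, sensors: Sequence[str] = SENSORS
    ) -> "ConfusionModel":
        """Reinterpret single-sensor correctness rows (%) as emission rates."""
        if table.mode != "activity":
            raise ValidationError("confusion model needs an activity-mode table")
        cp = {
            (s, a): table.single_sensor_reliability(s, a) / 100.0
            for s in sensors
            for a in ACTIVITIES
        }
        return cls(correct_prob=cp)

    @classmethod
    def perfect(cls, sensors: Sequence[str] = SENSORS) -> "ConfusionModel":
        return cls(correct_prob={(s, a): 1.0 for s in sensors for a in ACTIVITIES})

    @classmethod
    def uniform_rate(
        cls, rate: float, sensors: Sequence[str] = SENSORS
    ) -> "ConfusionModel":
        return cls(correct_prob={(s, a): rate for s in sensors for a in ACTIVITIES})

    @property
    def sensors(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.correct_prob}, key=SENSORS.index))

    def to_json(self) -> str:
        nested: dict[str, dict[str, float]] = {}
        for (s, a), p in sorted(self.correct_prob.items()):
            nested.setdefault(s, {})[a] = p
        return json.dumps({"error_spread": self.error_spread, "correct_prob": nested}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ConfusionModel":
        obj = json.loads(text)
        cp = {
            (s, a): float(p)
            for s, row in obj["correct_prob"].items()
            for a, p in row.items()
        }
        return cls(correct_prob=cp, error_spread=obj.get("error_spread", "uniform"))


@dataclass(frozen=True)
class ScenarioScript:
    """A scripted scenario: dwell times per activity plus availability events.

    Each segment is ``(duration_ticks, activity, availability_overrides)``;
    overrides declared with a segment take effect when the segment starts.
    """

    segments: tuple[tuple[int, str, dict[str, bool]], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("scenario script must have at least one segment")
        for dur, act, overrides in self.segments:
            if dur < 1:
                raise ValidationError(f"segment duration must be >= 1, got {dur}")
            validate_activity(act)
            for s in overrides:
                if s not in SENSORS:
                    raise ValidationError(f"unknown sensor {s!r} in availability override")

    @property
    def n_ticks(self) -> int:
        return sum(d for d, _, _ in self.segments)

    def expand(self) -> list[tuple[str, dict[str, bool]]]:
        """Per-tick (activity, overrides-at-this-tick) list; overrides appear
        only on the first tick of their segment."""
        out: list[tuple[str, dict[str, bool]]] = []
        for dur, act, overrides in self.segments:
            out.append((act, dict(overrides)))
            out.extend((act, {}) for _ in range(dur - 1))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "segments": [
                    {"duration": d, "activity": a, "availability": o}
                    for d, a, o in self.segments
                ]
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScenarioScript":
        obj = json.loads(text)
        try:
            segs = tuple(
                (int(s["duration"]), str(s["activity"]), dict(s.get("availability", {})))
                for s in obj["segments"]
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"malformed scenario JSON: {exc}") from exc
        return cls(segments=segs)


def shelf_search_script(repetitions: int = 1, dwell: int = 1) -> ScenarioScript:
    """The compound 'searching on the shelf' action: reaching up/forward,
    bending, squatting, each movement followed by its reverse."""
    if repetitions < 1 or dwell < 1:
        raise ValidationError("repetitions and dwell must be >= 1")
    segs = tuple(
        (dwell, pose, {}) for _ in range(repetitions) for pose in SHELF_SEARCH_POSES
    )
    return ScenarioScript(segments=segs)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def gen_activity_sequence(
    source: HabitsDB | ScenarioScript,
    n_ticks: int | None = None,
    seed: int | None = None,
    start: str | None = None,
) -> list[str]:
    """Activity label per tick, scripted or sampled from a habits chain.

    Script mode replays the segments deterministically (cycling if
    ``n_ticks`` exceeds the script length).  Habits mode starts from
    ``start`` (default: the most frequent source activity) and samples each
    next activity from the current row's transition probabilities.
    """
    if isinstance(source, ScenarioScript):
        ticks = [a for a, _ in source.expand()]
        if n_ticks is None:
            return ticks
        if n_ticks < 1:
            raise ValidationError("n_ticks must be >= 1")
        reps = -(-n_ticks // len(ticks))
        return (ticks * reps)[:n_ticks]

    db = source
    if db.is_empty():
        raise ValidationError("habits database is empty; cannot sample a sequence")
    if n_ticks is None or n_ticks < 1:
        raise ValidationError("n_ticks must be >= 1 in habits mode")
    rng = np.random.default_rng(seed)
    marginals = db.marginal_counts
    if start is None:
        start = min(marginals, key=lambda a: (-marginals[a], ACTIVITIES.index(a)))
    validate_activity(start)
    seq = [start]
    current = start
    for _ in range(n_ticks - 1):
        probs = db.row_probabilities(current)
        if not probs:
            # dead-end state: restart from the marginal source distribution
            total = sum(marginals.values())
            acts = sorted(marginals, key=ACTIVITIES.index)
            p = np.array([marginals[a] / total for a in acts])
            current = acts[rng.choice(len(acts), p=p)]
        else:
            acts = sorted(probs, key=ACTIVITIES.index)
            p = np.array([probs[a] for a in acts])
            current = acts[rng.choice(len(acts), p=p)]
        seq.append(current)
    return seq


def gen_sensor_stream(
    truth: Sequence[str],
    model: ConfusionModel,
    sharpness: float = 0.8,
    seed: int | None = None,
) -> dict[str, list[ProbabilityList]]:
    """Per-sensor probability-list streams consistent with a confusion model.

    At each tick the sensor's top activity equals the true one with the
    configured probability, otherwise a wrong activity is drawn per the error
    spread.  The emitted list puts ``sharpness`` mass on the drawn top
    activity and spreads the remainder uniformly, so lower-ranked activities
    retain non-zero support and fusion has something to blend.
    """
    if not truth:
        raise ValidationError("truth sequence must be non-empty")
    for a in truth:
        validate_activity(a)
    n_act = len(ACTIVITIES)
    if not (1.0 / n_act < sharpness <= 1.0):
        raise ValidationError(
            f"sharpness must lie in (1/{n_act}, 1] so the top stays first; got {sharpness}"
        )
    rng = np.random.default_rng(seed)
    rest = (1.0 - sharpness) / (n_act - 1)
    streams: dict[str, list[ProbabilityList]] = {}
    for sensor in model.sensors:
        ticks: list[ProbabilityList] = []
        for a in truth:
            if rng.random() < model.probability(sensor, a):
                top = a
            else:
                wrong = [x for x in ACTIVITIES if x != a]
                top = wrong[rng.integers(len(wrong))]
            entries = [(top, sharpness)] + [
                (x, rest) for x in ACTIVITIES if x != top
            ]
            ticks.append(ProbabilityList(sensor=sensor, entries=tuple(entries)))
        streams[sensor] = ticks
    return streams


def _prototypes(sensor: str, rng: np.random.Generator) -> np.ndarray:
    """One prototype row per activity: a random sign pattern on the
    activity's own coordinate block.  All pairwise Manhattan distances are
    equal (2 x block size), so no class is intrinsically harder."""
    length = FEATURE_LENGTHS[sensor]
    block = length // len(ACTIVITIES)
    protos = np.zeros((len(ACTIVITIES), length))
    for i in range(len(ACTIVITIES)):
        signs = rng.choice((-1.0, 1.0), size=block)
        protos[i, i * block : (i + 1) * block] = signs
    return protos


def gen_feature_vectors(
    labels: Sequence[str],
    sensor: str,
    noise_sd: float,
    seed: int | None = None,
    subjects: Sequence[str] | str = "S1",
) -> LabeledDataset:
    """Feature vectors of the sensor's canonical length around fixed prototypes.

    Each item is its activity's prototype plus independent Gaussian noise of
    scale ``noise_sd``.  The prototypes depend only on the seed, so datasets
    generated with the same seed share them (items differ).
    """
    if sensor not in SENSORS:
        raise ValidationError(f"unknown sensor id {sensor!r}")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    labels = [validate_activity(a) for a in labels]
    if isinstance(subjects, str):
        subjects = [subjects] * len(labels)
    if len(subjects) != len(labels):
        raise ValidationError("subjects must match labels in length")
    rng = np.random.default_rng(seed)
    protos = _prototypes(sensor, rng)
    idx = np.array([ACTIVITIES.index(a) for a in labels])
    X = protos[idx] + rng.normal(0.0, noise_sd, size=(len(labels), protos.shape[1]))
    return LabeledDataset(sensor_set=sensor, X=X, labels=tuple(labels), subjects=tuple(subjects))


def _one_cohort_rates(
    sensor: str,
    noise_sd: float,
    items_per_cell: int,
    k: int,
    seed: int | None,
    subjects: Sequence[str] | None,
) -> tuple[float, dict[str, float]]:
    labels = [a for a in ACTIVITIES for _ in range(items_per_cell)]
    if subjects is None:
        subj: Sequence[str] | str = "S1"
    else:
        subj = [subjects[i % len(subjects)] for i in range(len(labels))]
    data = gen_feature_vectors(labels, sensor, noise_sd, seed=seed, subjects=subj)
    train, test = split_train_test(data, (1, 3), seed=None if seed is None else seed + 1)
    preds = knn_classify_batch(train, test.X, k=k)
    correct = np.array([p.top == t for p, t in zip(preds, test.labels)])
    tl = np.asarray(test.labels)
    rates = {
        a: 100.0 * float(correct[tl == a].mean()) for a in ACTIVITIES
    }
    return 100.0 * float(correct.mean()), rates


def knn_recognition_rate(
    sensor: str,
    noise_sd: float,
    items_per_cell: int,
    k: int = 3,
    seed: int | None = None,
    subjects: Sequence[str] | None = None,
    per_activity: bool = False,
    replicates: int = 1,
):
    """Test-set recognition rate (%) of the k-NN pipeline at a noise level.

    Each replicate generates ``items_per_cell`` items per activity, splits
    1:3, and classifies the test part; rates are averaged over replicates
    (independent cohorts under derived seeds), which tightens the estimate
    of the underlying rate without changing the per-run problem size.  With
    ``per_activity`` a dict of per-activity rates is returned alongside the
    overall rate.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    overalls = []
    acc = {a: 0.0 for a in ACTIVITIES}
    for r in range(replicates):
        rseed = None if seed is None else seed + 1000 * r
        overall, rates = _one_cohort_rates(
            sensor, noise_sd, items_per_cell, k, rseed, subjects
        )
        overalls.append(overall)
        for a, v in rates.items():
            acc[a] += v
    overall = float(np.mean(overalls))
    if not per_activity:
        return overall
    return overall, {a: v / replicates for a, v in acc.items()}


def calibrate_noise(
    target_rate: float,
    sensor: str,
    items_per_cell: int = 200,
    k: int = 3,
    seed: int | None = None,
    iterations: int = 12,
) -> float:
    """Noise scale at which the k-NN pipeline hits a target recognition rate.

    The rate is a monotonically decreasing function of the noise scale (for
    equidistant prototypes), so a bisection over ``noise_sd`` suffices; each
    probe reuses the same seed, making the calibration deterministic.
    """
    if not (100.0 / len(ACTIVITIES) < target_rate < 100.0):
        raise ValidationError(
            f"target rate must be between chance and 100 (exclusive), got {target_rate}"
        )
    lo, hi = 0.0, 0.5
    while knn_recognition_rate(sensor, hi, items_per_cell, k, seed) > target_rate:
        hi *= 2.0
        if hi > 64.0:
            raise ValidationError("could not bracket the target rate")
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if knn_recognition_rate(sensor, mid, items_per_cell, k, seed) > target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
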