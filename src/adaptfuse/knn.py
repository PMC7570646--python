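"""k-nearest-neighbour activity classification on concatenated feature vectors.

Each sensor delivers a fixed-length, pre-normalized feature vector per
movement repetition (EMG: 320 values, foot pressure: 240, accelerometer: 120,
video: 320).  Multi-sensor classification simply concatenates the member
vectors in canonical sensor order, so e.g. the EMG+pressure vector has
560 values.  Classification uses plain k-NN with the Manhattan (L1) metric;
the class vote fractions among the k nearest neighbours double as the
probability list handed to the fusion stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import ACTIVITIES, SENSORS, ValidationError, sensor_set, validate_activity
from .fusion import ProbabilityList

__all__ = [
    "FEATURE_LENGTHS",
    "feature_length",
    "FeatureVector",
    "LabeledDataset",
    "concat_features",
    "split_train_test",
    "knn_classify",
    "knn_classify_batch",
]

#: Feature-vector length per single sensor.
FEATURE_LENGTHS: dict[str, int] = {"B": 320, "C": 240, "D": 120, "E": 320}


def feature_length(sets: str) -> int:
    """Length of the concatenated vector for a sensor set (additive)."""
    return sum(FEATURE_LENGTHS[s] for s in sensor_set(sets))


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length numeric feature vector tagged with its sensor set."""

    sensor_set: str
    values: np.ndarray

    def __post_init__(self) -> None:
        ss = sensor_set(self.sensor_set)
        object.__setattr__(self, "sensor_set", ss)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        expected = feature_length(ss)
        if vals.ndim != 1 or vals.shape[0] != expected:
            raise ValidationError(
                f"feature vector for {ss!r} must have length {expected}, "
                f"got shape {vals.shape}"
            )


@dataclass(frozen=True)
class LabeledDataset:
    """Feature vectors with activity labels and subject ids, one sensor set."""

    sensor_set: str
    X: np.ndarray  # (n_items, feature_length)
    labels: tuple[str, ...]
    subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        ss = sensor_set(self.sensor_set)
        object.__setattr__(self, "sensor_set", ss)
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "subjects", tuple(self.subjects))
        if X.ndim != 2 or X.shape[1] != feature_length(ss):
            raise ValidationError(
                f"dataset X must be (n, {feature_length(ss)}), got {X.shape}"
            )
        if not (X.shape[0] == len(self.labels) == len(self.subjects)):
            raise ValidationError("X, labels and subjects must have equal length")
        for a in self.labels:
            validate_activity(a)

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = list(idx)
        return LabeledDataset(
            sensor_set=self.sensor_set,
            X=self.X[idx],
            labels=tuple(self.labels[i] for i in idx),
            subjects=tuple(self.subjects[i] for i in idx),
        )


def concat_features(parts: Mapping[str, FeatureVector | np.ndarray]) -> FeatureVector:
    """Concatenate per-sensor vectors into a combined-set vector.

    Parts are joined in canonical sensor order B, C, D, E regardless of the
    mapping's ordering; each part must have its sensor's canonical length.
    """
    ss = sensor_set(parts.keys())
    chunks = []
    for s in ss:
        part = parts[s]
        vals = part.values if isinstance(part, FeatureVector) else np.asarray(part, dtype=float)
        if vals.ndim != 1 or vals.shape[0] != FEATURE_LENGTHS[s]:
            raise ValidationError(
                f"part for sensor {s!r} must have length {FEATURE_LENGTHS[s]}, "
                f"got shape {vals.shape}"
            )
        chunks.append(vals)
    return FeatureVector(sensor_set=ss, values=np.concatenate(chunks))


def split_train_test(
    data: LabeledDataset,
    ratio: tuple[int, int] = (1, 3),
    seed: int | None = None,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/test split, default 1:3 (a quarter for training).

    Items are shuffled within each activity stratum; the split is
    deterministic for a fixed seed.  A stratum too small to populate both
    parts is assigned wholly to the training set with a warning.
    """
    if ratio[0] <= 0 or ratio[1] <= 0:
        raise ValidationError("both ratio parts must be positive")
    if len(data) == 0:
        raise ValidationError("dataset must be non-empty")
    rng = np.random.default_rng(seed)
    frac_train = ratio[0] / (ratio[0] + ratio[1])
    train_idx: list[int] = []
    test_idx: list[int] = []
    labels = np.asarray(data.labels)
    for act in sorted(set(data.labels)):
        stratum = np.flatnonzero(labels == act)
        stratum = stratum[rng.permutation(len(stratum))]
        n_train = int(round(len(stratum) * frac_train))
        if len(stratum) < 2:
            warnings.warn(
                f"activity {act!r} has only {len(stratum)} item(s); "
                "assigning all to the training set"
            )
            n_train = len(stratum)
        else:
            n_train = min(max(n_train, 1), len(stratum) - 1)
        train_idx.extend(stratum[:n_train])
        test_idx.extend(stratum[n_train:])
    return data.subset(sorted(train_idx)), data.subset(sorted(test_idx))


def knn_classify(
    train: LabeledDataset,
    query: FeatureVector | np.ndarray,
    k: int = 3,
) -> ProbabilityList:
    """Classify one query vector; returns the vote-fraction probability list.

    Distances are Manhattan (L1).  Distance ties are resolved by dataset
    order (stable sort).  Labels with equal vote counts are ordered by their
    nearest neighbour's distance (so a 3-way tie at k=3 falls back to the
    1-NN decision, which keeps class error rates unbiased), with canonical
    activity order as the final tie-break.
    """
    qvals = query.values if isinstance(query, FeatureVector) else np.asarray(query, dtype=float)
    return knn_classify_batch(train, qvals[None, :], k=k)[0]


def knn_classify_batch(
    train: LabeledDataset,
    queries: np.ndarray,
    k: int = 3,
) -> list[ProbabilityList]:
    """Vectorized k-NN over many query rows (same contract as knn_classify)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(train) == 0:
        raise ValidationError("training set must be non-empty")
    k = min(k, len(train))
    Q = np.asarray(queries, dtype=float)
    if Q.ndim != 2 or Q.shape[1] != train.X.shape[1]:
        raise ValidationError(
            f"query length {Q.shape[-1] if Q.ndim else '?'} does not match "
            f"training vectors of length {train.X.shape[1]}"
        )
    D = cdist(Q, train.X, metric="cityblock")
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    labels = np.asarray(train.labels)
    out = []
    for qi, row in enumerate(order):
        votes: dict[str, int] = {}
        nearest: dict[str, float] = {}
        for j in row:
            lbl = labels[j]
            votes[lbl] = votes.get(lbl, 0) + 1
            d = float(D[qi, j])
            if lbl not in nearest or d < nearest[lbl]:
                nearest[lbl] = d
        entries = sorted(
            votes.items(),
            key=lambda kv: (-kv[1], nearest[kv[0]], ACTIVITIES.index(kv[0])),
        )
        out.append(
            ProbabilityList(
                sensor=train.sensor_set,
                entries=tuple((a, n / k) for a, n in entries),
            )
        )
    return out
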