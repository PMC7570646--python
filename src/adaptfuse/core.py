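"""Domain model for a multimodal assisted-living activity recognition system.

Four sensing modalities observe a monitored subject: surface EMG of the lower
limbs (sensor B), foot-pressure insoles (C), a chest-worn accelerometer (D),
and a video camera (E).  The subject performs twelve elementary reversible
activities of daily living, coded ``1a``/``1b`` through ``6a``/``6b`` (the
``b`` code is the reverse movement of its ``a`` partner, e.g. squatting and
getting back up).

The empirical backbone of the system is a *reliability table*: the percentage
of correctly recognized repetitions for every non-empty sensor combination,
tabulated either per activity or per monitored volunteer.  Two such tables,
measured on 20 volunteers with ~30 repetitions per activity, ship with the
package as the resources ``"table3"`` (per-activity) and ``"table4"``
(per-volunteer).  Everything downstream — sensor ranking, contribution
weighting, hierarchy-driven sensor-set selection — reads from these tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITIES",
    "SENSORS",
    "SENSOR_MODALITIES",
    "SENSOR_SAMPLING_HZ",
    "ALL_SENSOR_SETS",
    "MULTI_SENSOR_SETS",
    "SINGLE_SENSOR_SETS",
    "ValidationError",
    "sensor_set",
    "validate_activity",
    "ReliabilityTable",
    "SensorHierarchy",
    "EvaluationReport",
    "load_reliability_table",
    "build_hierarchy",
    "evaluate_recognition",
    "table_summary",
]

#: The closed vocabulary of elementary activity codes, in canonical order.
ACTIVITIES: tuple[str, ...] = (
    "1a", "1b", "2a", "2b", "3a", "3b", "4a", "4b", "5a", "5b", "6a", "6b",
)

#: Sensor identifiers in canonical order.
SENSORS: tuple[str, ...] = ("B", "C", "D", "E")

SENSOR_MODALITIES: dict[str, str] = {
    "B": "EMG",
    "C": "pressure",
    "D": "accelerometer",
    "E": "video",
}

#: Native sampling rate of each sensor, Hz.
SENSOR_SAMPLING_HZ: dict[str, int] = {"B": 200, "C": 100, "D": 100, "E": 25}


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


def validate_activity(code: str) -> str:
    if code not in ACTIVITIES:
        raise ValidationError(
            f"unknown activity code {code!r}; expected one of {ACTIVITIES}"
        )
    return code


def sensor_set(members: Iterable[str]) -> str:
    """Canonical string form of a sensor combination.

    Members are single-letter sensor ids; the canonical form concatenates
    them in the fixed order B < C < D < E (``sensor_set("EDB") == "BDE"``).
    """
    letters = list(members)
    if not letters:
        raise ValidationError("sensor set must be non-empty")
    if len(set(letters)) != len(letters):
        raise ValidationError(f"duplicate sensor in set {letters!r}")
    for s in letters:
        if s not in SENSORS:
            raise ValidationError(f"unknown sensor id {s!r}; expected one of {SENSORS}")
    return "".join(s for s in SENSORS if s in letters)


def _all_sets(min_size: int = 1) -> tuple[str, ...]:
    out = []
    for r in range(min_size, len(SENSORS) + 1):
        out.extend("".join(c) for c in combinations(SENSORS, r))
    return tuple(out)


#: All 15 non-empty sensor combinations, canonical order within each size.
ALL_SENSOR_SETS: tuple[str, ...] = _all_sets(1)
SINGLE_SENSOR_SETS: tuple[str, ...] = tuple(SENSORS)
#: The 11 combinations of two or more sensors.
MULTI_SENSOR_SETS: tuple[str, ...] = _all_sets(2)


# ---------------------------------------------------------------------------
# Reliability tables
# ---------------------------------------------------------------------------

_PACKAGED = {
    "table3": ("activity_recognition.csv", "activity_recognition_u.csv", "activity"),
    "table4": ("volunteer_recognition.csv", "volunteer_recognition_u.csv", "volunteer"),
}


@dataclass(frozen=True)
class ReliabilityTable:
    """Recognition correctness (%) per sensor set, by activity or volunteer.

    ``values`` rows are canonical sensor-set strings; columns are activity
    codes (mode ``"activity"``) or volunteer ids (mode ``"volunteer"``),
    optionally followed by an aggregate ``ALL`` column which is stored as
    published and never recomputed.  ``uncertainty`` holds the matching
    dispersion values (weighted standard deviations) when available.
    """

    values: pd.DataFrame
    mode: str
    uncertainty: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("activity", "volunteer"):
            raise ValidationError(f"unknown table mode {self.mode!r}")
        v = self.values.to_numpy(dtype=float)
        if np.any((v < 0.0) | (v > 100.0)):
            bad = np.argwhere((v < 0.0) | (v > 100.0))[0]
            raise ValidationError(
                f"correctness value out of [0, 100] at row "
                f"{self.values.index[bad[0]]!r}, column {self.values.columns[bad[1]]!r}"
            )
        if self.uncertainty is not None and (self.uncertainty.to_numpy() < 0).any():
            raise ValidationError("uncertainty values must be non-negative")

    @property
    def columns(self) -> tuple[str, ...]:
        """Data columns (the aggregate ALL column excluded)."""
        return tuple(c for c in self.values.columns if c != "ALL")

    @property
    def sets(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    def reliability(self, sets: str, column: str) -> float:
        """Correctness (%) of a sensor set for one column (activity/volunteer)."""
        sets = sensor_set(sets)
        if sets not in self.values.index:
            raise KeyError(f"sensor set {sets!r} not present in table")
        if column not in self.values.columns:
            raise KeyError(f"column {column!r} not present in table")
        return float(self.values.at[sets, column])

    def single_sensor_reliability(self, sensor: str, column: str) -> float:
        if sensor not in SENSORS:
            raise ValidationError(f"unknown sensor id {sensor!r}")
        return self.reliability(sensor, column)


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected a label column plus data columns")
    df = df.set_index(df.columns[0])
    seen: set[str] = set()
    canon = []
    for label in df.index:
        s = sensor_set(str(label))
        if s in seen:
            raise ValidationError(f"{path}: duplicate sensor-set row {label!r}")
        seen.add(s)
        canon.append(s)
    df.index = pd.Index(canon, name="set")
    try:
        df = df.astype(float)
    except ValueError as exc:  # pragma: no cover - message detail
        raise ValidationError(f"{path}: non-numeric cell ({exc})") from exc
    return df


def load_reliability_table(
    source: str | Path,
    uncertainty_source: str | Path | None = None,
    mode: str | None = None,
) -> ReliabilityTable:
    """Load a reliability table from a packaged resource or a CSV file.

    The packaged names ``"table3"`` (per-activity correctness) and
    ``"table4"`` (per-volunteer correctness) load the published values
    together with their dispersion tables.  Any other source is taken as a
    CSV path: comma separated, dot decimal, header row naming the columns,
    first column holding sensor-set labels.
    """
    if isinstance(source, str) and source in _PACKAGED:
        val_name, unc_name, packaged_mode = _PACKAGED[source]
        pkg = resources.files("adaptfuse.data")
        values = _read_csv(pkg / val_name)
        uncertainty = _read_csv(pkg / unc_name)
        return ReliabilityTable(values=values, mode=packaged_mode,
                                uncertainty=uncertainty)
    values = _read_csv(source)
    uncertainty = _read_csv(uncertainty_source) if uncertainty_source else None
    if mode is None:
        mode = "activity" if set(values.columns) - {"ALL"} <= set(ACTIVITIES) else "volunteer"
    return ReliabilityTable(values=values, mode=mode, uncertainty=uncertainty)


# ---------------------------------------------------------------------------
# Sensor-set hierarchy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorHierarchy:
    """Tie-grouped descending ranking of sensor sets for one activity.

    ``groups[0]`` holds the most reliable set(s); sets whose table values
    differ by at most the tie tolerance share a group.  ``values[i]`` is the
    reliability of the leading member of group ``i``.
    """

    activity: str
    groups: tuple[tuple[str, ...], ...]
    values: tuple[float, ...]

    @property
    def top_group(self) -> tuple[str, ...]:
        return self.groups[0]

    @property
    def top_value(self) -> float:
        return self.values[0]

    def flat(self) -> tuple[str, ...]:
        return tuple(s for g in self.groups for s in g)


def build_hierarchy(
    table: ReliabilityTable,
    activity: str,
    pool: Iterable[str] | None = None,
    tie_tol: float = 0.0,
) -> SensorHierarchy:
    """Rank a pool of sensor sets by recognition reliability for an activity.

    Sets are sorted by descending table value and grouped: a set joins the
    current group when its value is within ``tie_tol`` of the group leader.
    The default ``tie_tol=0`` groups exactly equal printed percentages, which
    is how the published per-activity rankings arise.  Within a group the
    iteration order is the canonical sensor-set string order (shorter sets
    first, then alphabetical); ties carry no order semantics.
    """
    if table.mode == "activity":
        validate_activity(activity)
    if activity not in table.values.columns:
        raise KeyError(f"activity {activity!r} not a column of the table")
    if tie_tol < 0:
        raise ValidationError("tie_tol must be >= 0")
    members = tuple(sensor_set(s) for s in (pool if pool is not None else MULTI_SENSOR_SETS))
    if not members:
        raise ValidationError("pool must be non-empty")
    vals = {}
    for s in members:
        if s not in table.values.index:
            raise KeyError(f"pool member {s!r} missing from table")
        vals[s] = float(table.values.at[s, activity])

    def canon_key(s: str) -> tuple[int, str]:
        return (len(s), s)

    ordered = sorted(members, key=lambda s: (-vals[s], canon_key(s)))
    groups: list[list[str]] = []
    gvals: list[float] = []
    for s in ordered:
        if groups and gvals[-1] - vals[s] <= tie_tol:
            groups[-1].append(s)
        else:
            groups.append([s])
            gvals.append(vals[s])
    return SensorHierarchy(
        activity=activity,
        groups=tuple(tuple(sorted(g, key=canon_key)) for g in groups),
        values=tuple(gvals),
    )


# ---------------------------------------------------------------------------
# Recognition evaluation statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationReport:
    """Per-activity, per-subject and overall recognition correctness.

    ``R_s_a[a]`` is the percent of correct recognitions of activity ``a``
    pooled over subjects; ``U_s_a[a]`` the weighted standard deviation of the
    per-subject correctness values (weights proportional to repetition
    counts), a measure of inter-subject dispersion.  ``R_s_V``/``U_s_V`` are
    the transposed statistics per subject, and ``R_s_ALL``/``U_s_ALL`` the
    pooled total with the dispersion over subjects.
    """

    R_s_a: dict[str, float]
    U_s_a: dict[str, float]
    R_s_ALL: float
    U_s_ALL: float
    R_s_V: dict[str, float]
    U_s_V: dict[str, float]
    repetition_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "R_s_a": self.R_s_a,
            "U_s_a": self.U_s_a,
            "R_s_ALL": self.R_s_ALL,
            "U_s_ALL": self.U_s_ALL,
            "R_s_V": self.R_s_V,
            "U_s_V": self.U_s_V,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _weighted_std(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted population standard deviation; 0 for a single group."""
    w = weights / weights.sum()
    mean = float(np.dot(w, values))
    return float(np.sqrt(np.dot(w, (values - mean) ** 2)))


def evaluate_recognition(
    predictions: Sequence[tuple[str, str, str]],
) -> EvaluationReport:
    """Score a list of ``(subject, true activity, predicted activity)``.

    Correctness is the percentage of exact label matches.  The dispersion
    statistics use repetition counts as weights, so subjects (or activities)
    with more repetitions influence the spread proportionally.
    """
    if not predictions:
        raise ValidationError("prediction list must be non-empty")
    rows = []
    for subject, truth, pred in predictions:
        rows.append((str(subject), validate_activity(truth), validate_activity(pred)))
    df = pd.DataFrame(rows, columns=["subject", "truth", "pred"])
    df["correct"] = (df["truth"] == df["pred"]).astype(float)

    cell = df.groupby(["subject", "truth"], sort=True)["correct"].agg(["mean", "count"])
    cell["pct"] = 100.0 * cell["mean"]

    R_s_a: dict[str, float] = {}
    U_s_a: dict[str, float] = {}
    for act, sub in cell.groupby(level="truth", sort=True):
        w = sub["count"].to_numpy(dtype=float)
        x = sub["pct"].to_numpy(dtype=float)
        R_s_a[act] = float(np.dot(w, x) / w.sum())
        U_s_a[act] = _weighted_std(x, w)

    R_s_V: dict[str, float] = {}
    U_s_V: dict[str, float] = {}
    for subj, sub in cell.groupby(level="subject", sort=True):
        w = sub["count"].to_numpy(dtype=float)
        x = sub["pct"].to_numpy(dtype=float)
        R_s_V[subj] = float(np.dot(w, x) / w.sum())
        U_s_V[subj] = _weighted_std(x, w)

    R_s_ALL = 100.0 * float(df["correct"].mean())
    subj_tot = df.groupby("subject")["correct"].agg(["mean", "count"])
    U_s_ALL = _weighted_std(
        100.0 * subj_tot["mean"].to_numpy(dtype=float),
        subj_tot["count"].to_numpy(dtype=float),
    )
    counts = {
        (subj, act): int(n)
        for (subj, act), n in cell["count"].items()
    }
    return EvaluationReport(
        R_s_a=R_s_a, U_s_a=U_s_a, R_s_ALL=R_s_ALL, U_s_ALL=U_s_ALL,
        R_s_V=R_s_V, U_s_V=U_s_V, repetition_counts=counts,
    )


def table_summary(
    table: ReliabilityTable, pool: Iterable[str] | None = None
) -> tuple[float, float]:
    """Minimum and maximum correctness over ``pool`` rows × data columns.

    The aggregate ``ALL`` column is excluded; by default the pool is every
    multi-sensor combination present in the table.
    """
    if pool is None:
        members = [s for s in table.sets if len(s) >= 2]
    else:
        members = [sensor_set(s) for s in pool]
    if not members:
        raise ValidationError("pool must be non-empty")
    sub = table.values.loc[members, list(table.columns)].to_numpy(dtype=float)
    return float(sub.min()), float(sub.max())
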