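"""Readers, writers and core record types shared across the pipeline.

Recordings follow the ActiGraph 1 Hz CSV export layout: a header row with
the eight columns ``Date, Time, Axis 1, Axis 2, Axis 3, Steps, Inclinometer,
Vector Magnitude`` followed by one row per second.  The last six columns are
the six activity-count time series of one sensor location; with sensors worn
at the hip and the ankle a participant contributes twelve series in total.

Label tracks store minute-accurate "intended jogging" intervals, either as
reported in the activity diary (``diary``) or after visual correction against
the raw signals (``golden``).  All interval arithmetic in the package uses
half-open ``[start, end)`` minutes so adjacent intervals never double-count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ContinuityError",
    "CHANNELS",
    "RECORDING_COLUMNS",
    "JOGGING",
    "NONJOGGING",
    "LABEL_NAMES",
    "Recording",
    "LabelTrack",
    "Participant",
    "FeatureMatrix",
    "read_recording",
    "write_recording",
    "read_labels",
    "write_labels",
    "read_feature_matrix",
    "write_feature_matrix",
]


class FormatError(ValueError):
    """A file does not have the expected structure (columns, header)."""


class ValidationError(ValueError):
    """File contents violate a domain invariant (sign, order, overlap)."""


class ContinuityError(ValidationError):
    """The 1 Hz timestamp sequence has a gap or a duplicate."""


#: in-memory channel attribute names, in file column order
CHANNELS: Tuple[str, ...] = (
    "axis1",
    "axis2",
    "axis3",
    "steps",
    "inclinometer",
    "vector_magnitude",
)

#: the eight columns of an ActiGraph-style 1 Hz export
RECORDING_COLUMNS: Tuple[str, ...] = (
    "Date",
    "Time",
    "Axis 1",
    "Axis 2",
    "Axis 3",
    "Steps",
    "Inclinometer",
    "Vector Magnitude",
)

_CHANNEL_BY_COLUMN = dict(zip(RECORDING_COLUMNS[2:], CHANNELS))

# class encoding used throughout: jogging is the positive class
JOGGING: int = 1
NONJOGGING: int = 0
LABEL_NAMES: Dict[int, str] = {JOGGING: "jogging", NONJOGGING: "nonjogging"}
_LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}

LOCATIONS: Tuple[str, ...] = ("hip", "ankle")
GENDERS: Tuple[str, ...] = ("male", "female")
SPLITS: Tuple[str, ...] = ("train", "validation", "test")


@dataclass
class Recording:
    """Six equal-length 1 Hz activity-count series from one sensor location.

    Sample ``i`` of every channel corresponds to wall-clock time
    ``start + i`` seconds.
    """

    participant_id: str
    location: str
    start: pd.Timestamp
    axis1: np.ndarray
    axis2: np.ndarray
    axis3: np.ndarray
    steps: np.ndarray
    inclinometer: np.ndarray
    vector_magnitude: np.ndarray

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValidationError(f"unknown sensor location {self.location!r}")
        self.start = pd.Timestamp(self.start)
        lengths = set()
        for name in CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or arr.size < 1:
                raise ValidationError(f"channel {name} must be a non-empty 1-d sequence")
            if np.any(arr < 0):
                row = int(np.argmax(arr < 0))
                raise ValidationError(f"negative value in channel {name} at row {row}")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite value in channel {name}")
            setattr(self, name, arr)
            lengths.add(arr.size)
        if len(lengths) != 1:
            raise ValidationError(f"channel lengths differ: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return self.axis1.size

    @property
    def end(self) -> pd.Timestamp:
        """One second past the last sample (half-open span)."""
        return self.start + pd.Timedelta(seconds=self.n_samples)

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(name)
        return getattr(self, name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.location == other.location
            and self.start == other.start
            and all(np.array_equal(self.channel(c), other.channel(c)) for c in CHANNELS)
        )


def _check_minute(ts: pd.Timestamp, what: str) -> pd.Timestamp:
    ts = pd.Timestamp(ts)
    if ts != ts.floor("min"):
        raise ValidationError(f"{what} {ts} is not aligned to a whole minute")
    return ts


@dataclass
class LabelTrack:
    """Minute-resolution intended-jogging intervals for one participant.

    ``intervals`` are half-open ``[start, end)`` timestamp pairs, sorted and
    non-overlapping.  Touching intervals are merged on construction.
    """

    participant_id: str
    source: str  # "diary" | "golden"
    intervals: List[Tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.source not in ("diary", "golden"):
            raise ValidationError(f"unknown label source {self.source!r}")
        cleaned = []
        for s, e in self.intervals:
            s = _check_minute(s, "interval start")
            e = _check_minute(e, "interval end")
            if e <= s:
                raise ValidationError(f"interval end {e} not after start {s}")
            cleaned.append((s, e))
        cleaned.sort()
        merged: List[Tuple[pd.Timestamp, pd.Timestamp]] = []
        for s, e in cleaned:
            if merged and s < merged[-1][1]:
                raise ValidationError(
                    f"overlapping intervals for participant {self.participant_id}"
                )
            if merged and s == merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        self.intervals = merged

    @property
    def total_minutes(self) -> int:
        return int(
            sum((e - s) / pd.Timedelta(minutes=1) for s, e in self.intervals)
        )

    def covers(self, start: pd.Timestamp, end: pd.Timestamp) -> bool:
        """True if ``[start, end)`` lies fully inside one labeled interval."""
        return any(s <= start and end <= e for s, e in self.intervals)

    def disjoint(self, start: pd.Timestamp, end: pd.Timestamp) -> bool:
        """True if ``[start, end)`` intersects no labeled interval."""
        return all(e <= start or end <= s for s, e in self.intervals)


@dataclass(frozen=True)
class Participant:
    participant_id: str
    gender: str
    split: str

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValidationError(f"unknown gender {self.gender!r}")
        if self.split not in SPLITS:
            raise ValidationError(f"unknown split {self.split!r}")


class FeatureMatrix:
    """Instances x named numeric features with a binary class label.

    The instance index is ``(participant_id, window start)``.  Excluded
    (border) windows never enter a matrix, so every label is jogging or
    non-jogging and every value is finite.
    """

    def __init__(self, features: pd.DataFrame, labels: Sequence[int]):
        if features.columns.duplicated().any():
            dupes = features.columns[features.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate feature names: {dupes[:5]}")
        labels = np.asarray(labels)
        if labels.shape != (len(features),):
            raise ValidationError("labels must align one-to-one with instances")
        if not np.all(np.isin(labels, (JOGGING, NONJOGGING))):
            raise ValidationError("labels must be jogging/nonjogging")
        values = features.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = features.columns[~np.isfinite(values).all(axis=0)].tolist()
            raise ValidationError(f"non-finite feature values in columns {bad[:5]}")
        self.features = features
        self.labels = labels.astype(np.int8)

    @property
    def feature_names(self) -> List[str]:
        return list(self.features.columns)

    @property
    def n_instances(self) -> int:
        return len(self.features)

    @property
    def jogging_ratio(self) -> float:
        return float(np.mean(self.labels == JOGGING))

    def X(self, feature_names: Sequence[str] | None = None) -> np.ndarray:
        if feature_names is None:
            return self.features.to_numpy(dtype=float)
        return self.features.loc[:, list(feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def select(self, feature_names: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.features.loc[:, list(feature_names)].copy(), self.labels)

    def take(self, row_idx: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(row_idx)
        return FeatureMatrix(self.features.iloc[idx].copy(), self.labels[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.features.equals(other.features)
            and np.array_equal(self.labels, other.labels)
        )


# ---------------------------------------------------------------------------
# recordings


def read_recording(path: str | Path, participant_id: str, location: str) -> Recording:
    """Parse an 8-column ActiGraph-style 1 Hz CSV into a :class:`Recording`.

    Timestamps must advance in strict 1 s steps; a gap or duplicate raises
    :class:`ContinuityError` rather than silently resampling.
    """
    df = pd.read_csv(path)
    for col in RECORDING_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    if len(df) == 0:
        raise FormatError(f"empty recording file {path}")
    times = pd.to_datetime(
        df["Date"].astype(str) + " " + df["Time"].astype(str), format="mixed"
    )
    deltas = times.diff().dropna()
    if (deltas != pd.Timedelta(seconds=1)).any():
        row = int(np.argmax((deltas != pd.Timedelta(seconds=1)).to_numpy())) + 1
        raise ContinuityError(f"timestamp step != 1s at row {row} of {path}")
    channels = {}
    for col, name in _CHANNEL_BY_COLUMN.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValidationError(f"non-numeric value in {col!r} at row {row}")
        if (vals < 0).any():
            row = int((vals < 0).idxmax())
            raise ValidationError(f"negative value in {col!r} at row {row}")
        channels[name] = vals.to_numpy(dtype=float)
    return Recording(
        participant_id=participant_id,
        location=location,
        start=times.iloc[0],
        **channels,
    )


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` back to the 8-column CSV layout."""
    times = recording.start + pd.to_timedelta(np.arange(recording.n_samples), unit="s")
    df = pd.DataFrame(
        {
            "Date": times.strftime("%Y-%m-%d"),
            "Time": times.strftime("%H:%M:%S"),
            **{
                col: recording.channel(name)
                for col, name in _CHANNEL_BY_COLUMN.items()
            },
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# label tracks

_LABEL_COLUMNS = ("participant_id", "start", "end")


def read_labels(path: str | Path, source: str) -> Dict[str, LabelTrack]:
    """Read a label CSV (participant_id, start, end) into per-participant tracks.

    Timestamps are ``YYYY-MM-DD HH:MM``; intervals are minute-aligned,
    half-open, and touching intervals are merged.  Returns a mapping from
    participant id to that participant's :class:`LabelTrack`.
    """
    df = pd.read_csv(path)
    for col in _LABEL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    tracks: Dict[str, LabelTrack] = {}
    for pid, group in df.groupby("participant_id", sort=True):
        intervals = [
            (pd.Timestamp(s), pd.Timestamp(e))
            for s, e in zip(group["start"], group["end"])
        ]
        tracks[str(pid)] = LabelTrack(str(pid), source, intervals)
    return tracks


def write_labels(tracks: Iterable[LabelTrack], path: str | Path) -> None:
    rows = [
        {
            "participant_id": t.participant_id,
            "start": s.strftime("%Y-%m-%d %H:%M"),
            "end": e.strftime("%Y-%m-%d %H:%M"),
        }
        for t in tracks
        for s, e in t.intervals
    ]
    pd.DataFrame(rows, columns=list(_LABEL_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature matrices

_INDEX_COLUMNS = ("participant_id", "window_start")


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    df = matrix.features.copy()
    df.insert(0, "label", [LABEL_NAMES[v] for v in matrix.labels])
    df.to_csv(path, index=True, index_label=list(_INDEX_COLUMNS))


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    if df.columns.duplicated().any():
        raise FormatError(f"duplicate feature names in {path}")
    for col in (*_INDEX_COLUMNS, "label"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    df["window_start"] = pd.to_datetime(df["window_start"])
    df = df.set_index(list(_INDEX_COLUMNS))
    try:
        labels = np.array([_LABEL_CODES[v] for v in df.pop("label")])
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValidationError(f"unknown class label {exc}") from exc
    return FeatureMatrix(df, labels)
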