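"""Sliding-window segmentation and window labeling.

Two strategies are supported out of the box: 60 s windows without overlap
and 180 s windows with 120 s overlap (60 s shift).  Windows are aligned to
whole minutes starting from the recording start, never span midnight, and a
window is labeled jogging only if it lies fully inside a labeled interval,
non-jogging only if it is fully outside all intervals; windows straddling a
boundary are *excluded* (they never enter a feature matrix).

Only participant-days that contain at least one labeled jogging interval are
used when building datasets, which bounds the class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .io import JOGGING, NONJOGGING, LabelTrack, Recording, ValidationError
from .names import series_name
from .synthetic import SynthCohort

__all__ = [
    "WindowSpec",
    "Window",
    "SegmentedDataset",
    "segment",
    "assign_label",
    "build_dataset",
    "window_count",
]

EXCLUDED = -1
_MINUTE = pd.Timedelta(minutes=1)
_SECOND = pd.Timedelta(seconds=1)


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-length sliding window: length and overlap in seconds."""

    length_s: int = 60
    overlap_s: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_s < self.length_s:
            raise ValidationError("overlap must satisfy 0 <= overlap < length")
        if self.length_s % 60 or self.shift_s % 60:
            raise ValidationError("window length and shift must be whole minutes")

    @property
    def shift_s(self) -> int:
        return self.length_s - self.overlap_s


@dataclass
class Window:
    participant_id: str
    start: pd.Timestamp
    series: Dict[str, np.ndarray]
    label: Optional[int] = None  # JOGGING / NONJOGGING / EXCLUDED / None

    @property
    def length_s(self) -> int:
        return next(iter(self.series.values())).size

    @property
    def end(self) -> pd.Timestamp:
        return self.start + self.length_s * _SECOND


def window_count(span_s: int, spec: WindowSpec) -> int:
    """Number of full windows in a span: floor((L - n) / shift) + 1, or 0."""
    if span_s < spec.length_s:
        return 0
    return (span_s - spec.length_s) // spec.shift_s + 1


def _day_offsets(recording: Recording, spec: WindowSpec) -> np.ndarray:
    """Window start offsets (seconds from recording start), not crossing midnight."""
    offsets: List[int] = []
    start, end = recording.start, recording.end
    day = start.normalize()
    while day < end:
        seg_start = max(start, day)
        seg_end = min(end, day + pd.Timedelta(days=1))
        first = seg_start.ceil("min")
        span = int((seg_end - first) / _SECOND)
        k = window_count(span, spec)
        base = int((first - start) / _SECOND)
        offsets.extend(base + i * spec.shift_s for i in range(k))
        day += pd.Timedelta(days=1)
    return np.asarray(offsets, dtype=np.int64)


def segment(hip: Recording, ankle: Recording, spec: WindowSpec) -> List[Window]:
    """Slice a time-aligned hip/ankle recording pair into unlabeled windows."""
    if hip.start != ankle.start or hip.n_samples != ankle.n_samples:
        raise ValidationError("hip and ankle recordings are not time-aligned")
    if hip.participant_id != ankle.participant_id:
        raise ValidationError("recordings belong to different participants")
    offsets = _day_offsets(hip, spec)
    windows = []
    for off in offsets:
        sl = slice(off, off + spec.length_s)
        series = {}
        for rec in (hip, ankle):
            for ch in ("axis1", "axis2", "axis3", "steps", "inclinometer", "vector_magnitude"):
                series[series_name(rec.location, ch)] = rec.channel(ch)[sl]
        windows.append(Window(hip.participant_id, hip.start + int(off) * _SECOND, series))
    return windows


def assign_label(window: Window, labels: LabelTrack) -> int:
    """JOGGING if fully inside an interval, NONJOGGING if fully outside, else EXCLUDED."""
    if labels.covers(window.start, window.end):
        return JOGGING
    if labels.disjoint(window.start, window.end):
        return NONJOGGING
    return EXCLUDED


@dataclass
class SegmentedDataset:
    """Labeled windows of one split as dense per-series arrays.

    ``series[name]`` has shape ``(n_windows, length_s)``; rows align with
    ``index`` (participant id, window start), ``labels`` and ``gender``.
    Excluded border windows are already dropped.
    """

    spec: WindowSpec
    index: pd.MultiIndex
    labels: np.ndarray
    gender: np.ndarray
    series: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.labels)

    @property
    def n_jogging(self) -> int:
        return int(np.sum(self.labels == JOGGING))

    @property
    def n_nonjogging(self) -> int:
        return int(np.sum(self.labels == NONJOGGING))

    @property
    def jogging_ratio(self) -> float:
        return self.n_jogging / self.n_windows


def _label_offsets(
    recording: Recording, offsets: np.ndarray, spec: WindowSpec, track: LabelTrack
) -> np.ndarray:
    """Vectorized label assignment over all window offsets (seconds)."""
    starts = offsets
    ends = offsets + spec.length_s
    inside = np.zeros(offsets.size, dtype=bool)
    touches = np.zeros(offsets.size, dtype=bool)
    for s, e in track.intervals:
        s_off = (s - recording.start) / _SECOND
        e_off = (e - recording.start) / _SECOND
        inside |= (starts >= s_off) & (ends <= e_off)
        touches |= (starts < e_off) & (ends > s_off)
    labels = np.full(offsets.size, NONJOGGING, dtype=np.int8)
    labels[touches] = EXCLUDED
    labels[inside] = JOGGING
    return labels


def build_dataset(
    cohort: SynthCohort,
    spec: WindowSpec,
    label_source: str = "golden",
    materialize: bool = True,
    drop_excluded: bool = True,
) -> Dict[str, SegmentedDataset]:
    """Segment and label a cohort into per-split datasets.

    Only participant-days with at least one labeled jogging interval are
    kept, excluded (border) windows are dropped unless ``drop_excluded`` is
    False (prediction timelines need them), and per-series value arrays
    are materialized unless ``materialize`` is False (labels/index only).
    """
    if label_source not in ("golden", "diary"):
        raise ValidationError(f"unknown label source {label_source!r}")
    datasets: Dict[str, SegmentedDataset] = {}
    for split in ("train", "validation", "test"):
        entries = cohort.split(split)
        if not entries:
            raise ValidationError(f"split {split!r} is empty")
        idx_participant: List[str] = []
        idx_start: List[pd.Timestamp] = []
        labels_parts: List[np.ndarray] = []
        gender_parts: List[np.ndarray] = []
        series_parts: Dict[str, List[np.ndarray]] = {}
        for entry in entries:
            hip, ankle = entry.hip, entry.ankle
            if hip.start != ankle.start or hip.n_samples != ankle.n_samples:
                raise ValidationError(
                    f"misaligned recordings for {entry.participant.participant_id}"
                )
            track: LabelTrack = getattr(entry, label_source)
            offsets = _day_offsets(hip, spec)
            labels = _label_offsets(hip, offsets, spec, track)
            # restrict to days containing at least one labeled interval
            days_with_activity = {s.normalize() for s, _ in track.intervals}
            window_days = pd.DatetimeIndex(hip.start + offsets * _SECOND).normalize()
            on_active_day = np.asarray(window_days.isin(list(days_with_activity)))
            keep = on_active_day
            if drop_excluded:
                keep = keep & (labels != EXCLUDED)
            offsets, labels = offsets[keep], labels[keep]
            if offsets.size == 0:
                continue
            idx_participant.extend([entry.participant.participant_id] * offsets.size)
            idx_start.extend(hip.start + offsets * _SECOND)
            labels_parts.append(labels)
            gender_parts.append(np.repeat(entry.participant.gender, offsets.size))
            if materialize:
                cols = offsets[:, None] + np.arange(spec.length_s)
                for rec in (hip, ankle):
                    for ch in (
                        "axis1",
                        "axis2",
                        "axis3",
                        "steps",
                        "inclinometer",
                        "vector_magnitude",
                    ):
                        name = series_name(rec.location, ch)
                        series_parts.setdefault(name, []).append(rec.channel(ch)[cols])
        if not labels_parts:
            raise ValidationError(f"no usable windows in split {split!r}")
        datasets[split] = SegmentedDataset(
            spec=spec,
            index=pd.MultiIndex.from_arrays(
                [idx_participant, idx_start], names=["participant_id", "window_start"]
            ),
            labels=np.concatenate(labels_parts),
            gender=np.concatenate(gender_parts),
            series={k: np.vstack(v) for k, v in series_parts.items()},
        )
    return datasets
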