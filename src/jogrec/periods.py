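"""From window predictions to activity bouts and the matching-ratio metric.

With overlapping windows (180 s length, 60 s shift) every interior 60 s
block is covered by three windows; its final label is the majority vote of
those predictions (ties and uncovered blocks fall to non-jogging).  Maximal
runs of jogging blocks become activity periods, which the three
post-classification rules then filter and merge:

* **Rule 1** removes periods shorter than or equal to 3 minutes;
* **Rule 2** applies Rule 1, then merges adjacent periods whose pause is
  at most 5 minutes (the pause becomes part of the merged period);
* **Rule 3** applies Rule 2, then merges adjacent periods whose pause is at
  most the sum of their durations, re-evaluating durations after every
  merge until a fixed point.

The matching ratio compares two period lists at minute resolution:
``matched / (matched + missed + other)`` where matched is the overlap,
missed the reference-only minutes and other the predicted-only minutes — the
bout-level analogue of true positives, false negatives and false positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .io import JOGGING, NONJOGGING, LabelTrack, ValidationError
from .segmentation import WindowSpec

__all__ = [
    "ActivityPeriod",
    "PredictionTimeline",
    "MatchingReport",
    "vote_merge",
    "timeline_to_periods",
    "periods_from_track",
    "rule1",
    "rule2",
    "rule3",
    "apply_rule",
    "matching_ratio",
    "evaluate_periods",
]

_MINUTE = pd.Timedelta(minutes=1)


@dataclass(frozen=True)
class ActivityPeriod:
    """A minute-aligned, half-open [start, end) jogging bout."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("period end must be after start")

    @property
    def minutes(self) -> int:
        return int((self.end - self.start) / _MINUTE)


def _check_sorted(periods: Sequence[ActivityPeriod]) -> List[ActivityPeriod]:
    periods = sorted(periods, key=lambda p: p.start)
    for a, b in zip(periods, periods[1:]):
        if b.start < a.end:
            raise ValidationError("periods overlap")
    return periods


@dataclass
class PredictionTimeline:
    """Contiguous minute-aligned 60 s blocks with a binary label each."""

    participant_id: str
    start: pd.Timestamp
    labels: np.ndarray  # int8 per minute block

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        if self.start != self.start.floor("min"):
            raise ValidationError("timeline must start on a whole minute")
        self.labels = np.asarray(self.labels, dtype=np.int8)


def vote_merge(
    window_starts: Sequence[pd.Timestamp],
    predictions: Sequence[int],
    spec: WindowSpec,
    participant_id: str = "",
) -> PredictionTimeline:
    """Majority vote of the windows covering each 60 s block.

    A tie (possible at day edges where a block is covered by two windows)
    or an uncovered block yields non-jogging.
    """
    if spec.shift_s != 60:
        raise ValidationError("vote merge expects a 60 s window shift")
    starts = pd.DatetimeIndex(window_starts)
    preds = np.asarray(predictions)
    if len(starts) == 0:
        raise ValidationError("no windows to merge")
    t0 = starts.min()
    t1 = starts.max() + pd.Timedelta(seconds=spec.length_s)
    n_blocks = int((t1 - t0) / _MINUTE)
    votes_j = np.zeros(n_blocks, dtype=int)
    votes_n = np.zeros(n_blocks, dtype=int)
    blocks_per_window = spec.length_s // 60
    offsets = ((starts - t0) / _MINUTE).astype(int)
    for off, p in zip(offsets, preds):
        sl = slice(off, off + blocks_per_window)
        if p == JOGGING:
            votes_j[sl] += 1
        else:
            votes_n[sl] += 1
    labels = np.where(votes_j > votes_n, JOGGING, NONJOGGING).astype(np.int8)
    return PredictionTimeline(participant_id, t0, labels)


def timeline_to_periods(timeline: PredictionTimeline) -> List[ActivityPeriod]:
    """Run-length encode maximal jogging runs into periods."""
    jog = (timeline.labels == JOGGING).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], jog, [0]))))
    return [
        ActivityPeriod(timeline.start + int(s) * _MINUTE, timeline.start + int(e) * _MINUTE)
        for s, e in edges.reshape(-1, 2)
    ]


def periods_from_track(track: LabelTrack) -> List[ActivityPeriod]:
    return [ActivityPeriod(s, e) for s, e in track.intervals]


def rule1(periods: Sequence[ActivityPeriod]) -> List[ActivityPeriod]:
    """Remove periods shorter than or equal to 3 minutes."""
    return [p for p in _check_sorted(periods) if p.minutes > 3]


def _merge_if(
    periods: List[ActivityPeriod], gap_allowed
) -> List[ActivityPeriod]:
    """Left-to-right merging to a fixed point; ``gap_allowed(a, b, gap)``
    decides whether to merge, with durations re-evaluated after each merge."""
    changed = True
    while changed:
        changed = False
        out: List[ActivityPeriod] = []
        for p in periods:
            if out:
                gap = int((p.start - out[-1].end) / _MINUTE)
                if gap_allowed(out[-1], p, gap):
                    out[-1] = ActivityPeriod(out[-1].start, p.end)
                    changed = True
                    continue
            out.append(p)
        periods = out
    return periods


def rule2(periods: Sequence[ActivityPeriod]) -> List[ActivityPeriod]:
    """Rule 1, then merge adjacent periods with a pause of at most 5 minutes."""
    return _merge_if(rule1(periods), lambda a, b, gap: gap <= 5)


def rule3(periods: Sequence[ActivityPeriod]) -> List[ActivityPeriod]:
    """Rule 2, then merge adjacent periods whose pause is at most the sum of
    their (current) durations, cascading to a fixed point."""
    return _merge_if(rule2(periods), lambda a, b, gap: gap <= a.minutes + b.minutes)


_RULES = {"none": lambda p: _check_sorted(p), "rule1": rule1, "rule2": rule2, "rule3": rule3}


def apply_rule(periods: Sequence[ActivityPeriod], rule: str) -> List[ActivityPeriod]:
    try:
        return _RULES[rule](periods)
    except KeyError:
        raise ValidationError(f"unknown rule {rule!r}") from None


@dataclass
class MatchingReport:
    matched: int
    missed: int
    other: int

    @property
    def matching_ratio(self) -> Optional[float]:
        total = self.matched + self.missed + self.other
        if total == 0:
            return None
        return self.matched / total

    def __add__(self, other: "MatchingReport") -> "MatchingReport":
        return MatchingReport(
            self.matched + other.matched,
            self.missed + other.missed,
            self.other + other.other,
        )


def matching_ratio(
    predicted: Sequence[ActivityPeriod], golden: Sequence[ActivityPeriod]
) -> MatchingReport:
    """Minute-level overlap report of predicted vs reference periods."""
    predicted = _check_sorted(predicted)
    golden = _check_sorted(golden)
    matched = 0
    for p in predicted:
        for g in golden:
            lo = max(p.start, g.start)
            hi = min(p.end, g.end)
            if hi > lo:
                matched += int((hi - lo) / _MINUTE)
    pred_total = sum(p.minutes for p in predicted)
    gold_total = sum(g.minutes for g in golden)
    return MatchingReport(matched, gold_total - matched, pred_total - matched)


def evaluate_periods(
    predicted: Sequence[ActivityPeriod],
    golden: Sequence[ActivityPeriod],
    rule: str = "none",
) -> MatchingReport:
    """Apply the chosen rule to BOTH period lists, then match them."""
    return matching_ratio(apply_rule(predicted, rule), apply_rule(golden, rule))
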