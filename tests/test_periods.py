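"""Vote merging, run-length encoding, the three rules and the matching ratio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from jogrec.io import JOGGING, NONJOGGING, LabelTrack, ValidationError
from jogrec.periods import (
    ActivityPeriod,
    PredictionTimeline,
    apply_rule,
    evaluate_periods,
    matching_ratio,
    periods_from_track,
    rule1,
    rule2,
    rule3,
    timeline_to_periods,
    vote_merge,
)
from jogrec.segmentation import WindowSpec

T0 = pd.Timestamp("2016-05-02 08:00")
MIN = pd.Timedelta(minutes=1)


def periods(*pairs):
    """Build a period list from (start_minute, end_minute) offsets."""
    return [ActivityPeriod(T0 + s * MIN, T0 + e * MIN) for s, e in pairs]


def spans(ps):
    return [(int((p.start - T0) / MIN), int((p.end - T0) / MIN)) for p in ps]


@st.composite
def period_lists(draw):
    """Sorted, non-overlapping period lists with varied durations and gaps."""
    n = draw(st.integers(0, 8))
    pos = 0
    out = []
    for _ in range(n):
        pos += draw(st.integers(1, 40))  # gap
        dur = draw(st.integers(1, 45))
        out.append((pos, pos + dur))
        pos += dur
    return periods(*out)


class TestVoteMerge:
    def test_60s_windows_identity(self):
        starts = [T0 + i * MIN for i in range(6)]
        preds = [1, 0, 1, 1, 0, 0]
        tl = vote_merge(starts, preds, WindowSpec(60, 0), "P1")
        np.testing.assert_array_equal(tl.labels, preds)
        assert tl.start == T0

    def test_overlapping_windows_majority(self):
        # 180 s windows, 60 s shift: interior block i is covered by windows
        # i-2, i-1, i; block 3 gets votes from windows 1 (J), 2 (N), 3 (J)
        starts = [T0 + i * MIN for i in range(5)]
        preds = [0, 1, 0, 1, 0]
        tl = vote_merge(starts, preds, WindowSpec(180, 120), "P1")
        assert tl.labels.size == 7
        oracle = []
        for block in range(7):
            votes = [p for i, p in enumerate(preds) if i <= block <= i + 2]
            jog = sum(v == JOGGING for v in votes)
            oracle.append(JOGGING if jog > len(votes) - jog else NONJOGGING)
        np.testing.assert_array_equal(tl.labels, oracle)

    def test_tie_and_uncovered_fall_to_nonjogging(self):
        # two windows cover block 1 with a 1-1 tie
        starts = [T0, T0 + MIN]
        tl = vote_merge(starts, [1, 0], WindowSpec(180, 120), "P1")
        assert tl.labels[1] == NONJOGGING
        # a gap between windows leaves blocks uncovered
        starts = [T0, T0 + 5 * MIN]
        tl = vote_merge(starts, [1, 1], WindowSpec(60, 0), "P1")
        np.testing.assert_array_equal(tl.labels, [1, 0, 0, 0, 0, 1])

    def test_requires_60s_shift(self):
        with pytest.raises(ValidationError):
            vote_merge([T0], [1], WindowSpec(180, 60))


class TestRunLengthEncoding:
    def test_oracle(self):
        tl = PredictionTimeline("P1", T0, [0, 1, 1, 0, 1, 0, 0, 1])
        assert spans(timeline_to_periods(tl)) == [(1, 3), (4, 5), (7, 8)]

    def test_all_nonjogging(self):
        assert timeline_to_periods(PredictionTimeline("P1", T0, [0, 0, 0])) == []

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=120))
    def test_round_trip(self, labels):
        tl = PredictionTimeline("P1", T0, labels)
        ps = timeline_to_periods(tl)
        rebuilt = np.zeros(len(labels), dtype=int)
        for s, e in spans(ps):
            rebuilt[s:e] = 1
        np.testing.assert_array_equal(rebuilt, labels)

    def test_periods_from_track(self):
        track = LabelTrack("P1", "golden", [(T0, T0 + 10 * MIN)])
        assert spans(periods_from_track(track)) == [(0, 10)]


class TestRules:
    def test_rule1_inclusive_boundary(self):
        ps = periods((0, 3), (10, 14), (20, 23))
        assert spans(rule1(ps)) == [(10, 14)]

    def test_rule2_worked_example_5_7_gap3(self):
        # 5 min + 3 min pause + 7 min -> one 15-minute period
        ps = periods((0, 5), (8, 15))
        out = rule2(ps)
        assert spans(out) == [(0, 15)]
        assert out[0].minutes == 15

    def test_rule2_gap_boundary(self):
        assert len(rule2(periods((0, 5), (10, 15)))) == 1  # gap 5: merged
        assert len(rule2(periods((0, 5), (11, 16)))) == 2  # gap 6: kept apart

    def test_rule3_worked_example_4_10_gap6(self):
        # 4 min + 6 min pause + 10 min: rule 2 keeps them apart, rule 3
        # merges (6 <= 4 + 10) into one 20-minute period
        ps = periods((0, 4), (10, 20))
        assert spans(rule2(ps)) == [(0, 4), (10, 20)]
        out = rule3(ps)
        assert spans(out) == [(0, 20)]
        assert out[0].minutes == 20

    def test_rule3_worked_example_15_gap30_20(self):
        # 15 min + 30 min pause + 20 min: 30 <= 15 + 20, one 65-minute period
        ps = periods((0, 15), (45, 65))
        out = rule3(ps)
        assert spans(out) == [(0, 65)]
        assert out[0].minutes == 65

    def test_rule3_cascades_to_fixed_point(self):
        # first merge creates a long period that then absorbs the next one
        ps = periods((0, 10), (15, 25), (45, 55))
        # 10+5gap+10 -> (0,25) of 25 min; gap to (45,55) is 20 <= 25 + 10
        assert spans(rule3(ps)) == [(0, 55)]

    def test_unknown_rule_raises(self):
        with pytest.raises(ValidationError):
            apply_rule(periods((0, 5)), "rule4")

    @given(period_lists(), st.sampled_from(["none", "rule1", "rule2", "rule3"]))
    def test_idempotence(self, ps, rule):
        once = apply_rule(ps, rule)
        assert apply_rule(once, rule) == once

    @given(period_lists())
    def test_rule_postconditions(self, ps):
        r1, r2, r3 = rule1(ps), rule2(ps), rule3(ps)
        assert all(p.minutes > 3 for p in r1)
        for a, b in zip(r2, r2[1:]):
            assert (b.start - a.end) / MIN > 5
        for a, b in zip(r3, r3[1:]):
            assert (b.start - a.end) / MIN > a.minutes + b.minutes
        # total covered minutes only grows along the rule chain after rule 1
        assert sum(p.minutes for p in r2) >= sum(p.minutes for p in r1)
        assert sum(p.minutes for p in r3) >= sum(p.minutes for p in r2)
        # rule outputs cover every minute their inputs (post rule 1) covered
        assert len(r3) <= len(r2) <= len(r1)


class TestMatching:
    def test_worked_example_one_third(self):
        report = matching_ratio(periods((5, 15)), periods((0, 10)))
        assert (report.matched, report.missed, report.other) == (5, 5, 5)
        assert report.matching_ratio == pytest.approx(1 / 3)

    def test_perfect_and_empty(self):
        assert matching_ratio(periods((0, 10)), periods((0, 10))).matching_ratio == 1.0
        assert matching_ratio([], []).matching_ratio is None
        r = matching_ratio([], periods((0, 10)))
        assert r.matching_ratio == 0.0 and r.missed == 10

    def test_overlapping_input_raises(self):
        with pytest.raises(ValidationError):
            matching_ratio(periods((0, 10), (5, 15)), [])

    @given(period_lists(), period_lists())
    def test_bruteforce_minute_grid_oracle(self, pred, gold):
        horizon = max([e for _, e in spans(pred) + spans(gold)] or [1])
        p = np.zeros(horizon, dtype=bool)
        g = np.zeros(horizon, dtype=bool)
        for s, e in spans(pred):
            p[s:e] = True
        for s, e in spans(gold):
            g[s:e] = True
        report = matching_ratio(pred, gold)
        assert report.matched == int(np.sum(p & g))
        assert report.missed == int(np.sum(~p & g))
        assert report.other == int(np.sum(p & ~g))

    def test_rules_applied_to_both_sides(self):
        # a short golden burst is removed by rule 1 on both sides, so a
        # predictor that ignores it is no longer penalized
        pred = periods((10, 20))
        gold = periods((0, 2), (10, 20))
        assert evaluate_periods(pred, gold, "none").matching_ratio == pytest.approx(10 / 12)
        assert evaluate_periods(pred, gold, "rule1").matching_ratio == 1.0
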