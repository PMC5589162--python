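"""Synthetic labeled cohorts of 1 Hz activity-count recordings.

The generator emulates the statistical structure the recognition pipeline
relies on, without modelling raw 30 Hz gait mechanics:

* non-negative per-second activity counts on six channels per sensor
  location (hip and ankle), with the vector magnitude recomputed from the
  three axes;
* quasi-periodic high-intensity jogging bouts (counts follow
  ``gain * (base + amplitude * |sin(2*pi*f*t)|) + noise`` truncated at zero,
  so short-lag autocorrelation within bouts is high);
* heavy class imbalance: one to two ~20-minute bouts inside a long
  recording day;
* short intra-bout pauses (1-4 min of light activity inside a labeled
  bout) and occasional short running bursts (<= 3 min) outside bouts;
* participant-level multiplicative intensity gains whose distribution
  differs between dataset splits, emulating concept drift;
* diary label tracks that are minute-offset corruptions of the golden
  standard tracks.

All randomness derives from one master seed; each participant gets an
independent stream keyed by a stable hash of the participant id, so a cohort
does not depend on generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .io import LabelTrack, Participant, Recording, ValidationError

__all__ = ["SynthConfig", "SynthCohort", "CohortEntry", "generate_participant", "generate_cohort"]

# regime codes on the per-minute schedule
_SED, _LIGHT, _JOG, _PAUSE, _BURST = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class ChannelIntensity:
    """Per-second count model of one axis while jogging / at light activity."""

    jog_base: float
    jog_amplitude: float
    jog_noise_sd: float
    light_mean: float
    light_sd: float


#: default per-axis intensities; the ankle sees larger vertical counts
_DEFAULT_INTENSITIES: Dict[Tuple[str, str], ChannelIntensity] = {
    ("hip", "axis1"): ChannelIntensity(2500, 800, 300, 200, 120),
    ("hip", "axis2"): ChannelIntensity(1200, 400, 200, 120, 80),
    ("hip", "axis3"): ChannelIntensity(1000, 300, 200, 100, 70),
    ("ankle", "axis1"): ChannelIntensity(3500, 1000, 300, 250, 140),
    ("ankle", "axis2"): ChannelIntensity(1500, 500, 250, 140, 90),
    ("ankle", "axis3"): ChannelIntensity(1300, 400, 250, 120, 80),
}


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort.

    Defaults follow the field-study design: 14/13/12 participants per split
    with near-balanced genders in training/validation, ~20-minute lognormal
    bout durations clipped to [1, 90] minutes, and one or two bouts inside a
    12-hour waking-day recording, which yields a windowed jogging ratio of a
    few percent.
    """

    seed: int = 0
    n_train: int = 14
    n_validation: int = 13
    n_test: int = 12
    #: (male, female) counts per split; balanced in train/validation,
    #: imbalanced in test
    gender_counts: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {"train": (7, 7), "validation": (7, 6), "test": (4, 8)}
    )
    days_per_participant: int = 1
    day_minutes: int = 720
    day_start: str = "2016-05-02 08:00"
    #: bouts per day drawn uniformly from these choices
    bouts_per_day: Tuple[int, ...] = (1, 2)
    #: lognormal bout duration (minutes): mean ~ exp(mu + sigma^2/2) = 20
    bout_duration_mu: float = 2.816
    bout_duration_sigma: float = 0.6
    bout_duration_min: int = 1
    bout_duration_max: int = 90
    intra_bout_pause_prob: float = 0.3
    intra_bout_pause_minutes: Tuple[int, int] = (1, 4)
    #: expected short running bursts (<= 3 min) per day outside bouts
    burst_prob_per_day: float = 0.7
    burst_minutes: Tuple[int, int] = (1, 3)
    #: step cadence while jogging, steps per second
    steps_per_second: float = 2.8
    #: quasi-periodic modulation frequency (Hz); roughly step frequency / 2
    jog_modulation_hz: float = 1.4
    #: participant gain ~ LogNormal(ln(split multiplier), gain_sigma)
    gain_sigma: float = 0.15
    drift_emulation: bool = True
    split_gain: Dict[str, float] = field(
        default_factory=lambda: {"train": 1.0, "validation": 1.25, "test": 1.15}
    )
    #: diary boundary offsets: rounded Normal(0, sd) minutes
    diary_offset_sd: float = 2.0
    intensities: Dict[Tuple[str, str], ChannelIntensity] = field(
        default_factory=lambda: dict(_DEFAULT_INTENSITIES)
    )
    max_schedule_retries: int = 200

    def __post_init__(self) -> None:
        if self.day_minutes <= 0 or self.days_per_participant <= 0:
            raise ValidationError("durations must be positive")
        if not 0 <= self.intra_bout_pause_prob <= 1:
            raise ValidationError("pause probability must be in [0, 1]")
        if not 0 <= self.burst_prob_per_day <= 1:
            raise ValidationError("burst probability must be in [0, 1]")
        if self.bout_duration_min < 1 or self.bout_duration_max < self.bout_duration_min:
            raise ValidationError("invalid bout duration range")
        for split, counts in self.gender_counts.items():
            expected = {"train": self.n_train, "validation": self.n_validation, "test": self.n_test}[split]
            if sum(counts) != expected:
                raise ValidationError(
                    f"gender counts {counts} do not sum to split size {expected} for {split}"
                )


@dataclass
class CohortEntry:
    participant: Participant
    hip: Recording
    ankle: Recording
    golden: LabelTrack
    diary: LabelTrack


@dataclass
class SynthCohort:
    config: SynthConfig
    entries: List[CohortEntry]

    def split(self, name: str) -> List[CohortEntry]:
        return [e for e in self.entries if e.participant.split == name]

    def labels(self, source: str) -> Dict[str, LabelTrack]:
        return {e.participant.participant_id: getattr(e, source) for e in self.entries}


def _participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    """Stable per-participant stream: keyed by master seed and a CRC of the id."""
    key = zlib.crc32(participant_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _sample_bout_minutes(config: SynthConfig, rng: np.random.Generator) -> int:
    d = rng.lognormal(config.bout_duration_mu, config.bout_duration_sigma)
    return int(np.clip(round(d), config.bout_duration_min, config.bout_duration_max))


def _schedule_day(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-minute regime codes for one day; raises after bounded retries."""
    m = config.day_minutes
    n_bouts = int(rng.choice(config.bouts_per_day))
    for _ in range(config.max_schedule_retries):
        durations = [_sample_bout_minutes(config, rng) for _ in range(n_bouts)]
        # background: alternating sedentary / light segments of 5-30 minutes
        schedule = np.empty(m, dtype=np.int8)
        pos = 0
        while pos < m:
            seg = int(rng.integers(5, 31))
            schedule[pos : pos + seg] = _SED if rng.random() < 0.6 else _LIGHT
            pos += seg
        # place bouts without overlap, away from the day edges
        placed: List[Tuple[int, int]] = []
        ok = True
        for dur in durations:
            if dur + 2 >= m:
                ok = False
                break
            for _ in range(50):
                start = int(rng.integers(1, m - dur))
                if all(start >= e + 5 or start + dur + 5 <= s for s, e in placed):
                    placed.append((start, start + dur))
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        for s, e in placed:
            schedule[s:e] = _JOG
            dur = e - s
            lo, hi = config.intra_bout_pause_minutes
            if dur >= hi + 4 and rng.random() < config.intra_bout_pause_prob:
                plen = int(rng.integers(lo, hi + 1))
                pstart = int(rng.integers(s + 2, e - plen - 1))
                schedule[pstart : pstart + plen] = _PAUSE
        # short running bursts in non-jogging time (Rule 1 has work to do)
        if rng.random() < config.burst_prob_per_day:
            blen = int(rng.integers(config.burst_minutes[0], config.burst_minutes[1] + 1))
            for _ in range(50):
                bstart = int(rng.integers(0, m - blen))
                window = schedule[max(0, bstart - 5) : bstart + blen + 5]
                if not np.any((window == _JOG) | (window == _PAUSE)):
                    schedule[bstart : bstart + blen] = _BURST
                    break
        return schedule
    raise ValidationError(
        f"could not fit {n_bouts} bouts into a {m}-minute day "
        f"after {config.max_schedule_retries} retries"
    )


def _axis_counts(
    schedule_s: np.ndarray,
    intensity: ChannelIntensity,
    gain: float,
    config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-second counts of one axis given the per-second regime codes."""
    n = schedule_s.size
    t = np.arange(n)
    counts = np.zeros(n)
    jogging = (schedule_s == _JOG) | (schedule_s == _BURST)
    light = (schedule_s == _LIGHT) | (schedule_s == _PAUSE)
    sedentary = schedule_s == _SED
    modulation = np.abs(np.sin(2 * np.pi * config.jog_modulation_hz * t))
    counts[jogging] = gain * (
        intensity.jog_base + intensity.jog_amplitude * modulation[jogging]
    ) + rng.normal(0, intensity.jog_noise_sd, jogging.sum())
    counts[light] = rng.normal(intensity.light_mean, intensity.light_sd, light.sum())
    # sedentary: mostly zeros with sparse small counts
    sed_vals = rng.exponential(15.0, sedentary.sum()) * (rng.random(sedentary.sum()) < 0.3)
    counts[sedentary] = sed_vals
    return np.maximum(counts, 0.0).round()


def _location_recording(
    participant_id: str,
    location: str,
    start: pd.Timestamp,
    schedule_s: np.ndarray,
    gain: float,
    config: SynthConfig,
    rng: np.random.Generator,
) -> Recording:
    n = schedule_s.size
    axes = {
        axis: _axis_counts(schedule_s, config.intensities[(location, axis)], gain, config, rng)
        for axis in ("axis1", "axis2", "axis3")
    }
    active = (schedule_s == _JOG) | (schedule_s == _BURST)
    steps = np.zeros(n)
    steps[active] = rng.poisson(config.steps_per_second, active.sum())
    light = (schedule_s == _LIGHT) | (schedule_s == _PAUSE)
    steps[light] = rng.poisson(0.8, light.sum())
    # inclinometer: low-information small integers, weakly tied to activity
    inclinometer = rng.integers(0, 4, n).astype(float)
    vector_magnitude = np.sqrt(axes["axis1"] ** 2 + axes["axis2"] ** 2 + axes["axis3"] ** 2)
    return Recording(
        participant_id=participant_id,
        location=location,
        start=start,
        axis1=axes["axis1"],
        axis2=axes["axis2"],
        axis3=axes["axis3"],
        steps=steps,
        inclinometer=inclinometer,
        vector_magnitude=vector_magnitude,
    )


def _diary_from_golden(
    golden: LabelTrack,
    recording_start: pd.Timestamp,
    recording_end: pd.Timestamp,
    config: SynthConfig,
    rng: np.random.Generator,
) -> LabelTrack:
    """Corrupt golden boundaries with rounded Gaussian minute offsets."""
    minute = pd.Timedelta(minutes=1)
    intervals = []
    last_end = recording_start
    for s, e in golden.intervals:
        if config.diary_offset_sd > 0:
            ds = int(round(rng.normal(0, config.diary_offset_sd)))
            de = int(round(rng.normal(0, config.diary_offset_sd)))
        else:
            ds = de = 0
        ns = max(s + ds * minute, last_end)
        ne = min(e + de * minute, recording_end)
        if ne <= ns:  # degenerate corruption: keep a 1-minute stub at the start
            ns = max(s, last_end)
            ne = ns + minute
        intervals.append((ns, ne))
        last_end = ne
    return LabelTrack(golden.participant_id, "diary", intervals)


def generate_participant(
    config: SynthConfig,
    participant_id: str,
    gender: str,
    seed: int | None = None,
    gain_multiplier: float = 1.0,
) -> Tuple[Recording, Recording, LabelTrack, LabelTrack]:
    """Generate one participant's hip/ankle recordings and label tracks.

    ``seed`` defaults to the config master seed; the participant's stream is
    derived from it and from a stable hash of ``participant_id``.
    """
    rng = _participant_rng(config.seed if seed is None else seed, participant_id)
    gain = gain_multiplier * float(rng.lognormal(0.0, config.gain_sigma))
    day0 = pd.Timestamp(config.day_start)
    minute = pd.Timedelta(minutes=1)

    schedules = []
    golden_intervals = []
    for day in range(config.days_per_participant):
        day_start = day0 + pd.Timedelta(days=day)
        schedule = _schedule_day(config, rng)
        schedules.append(schedule)
        in_bout = (schedule == _JOG) | (schedule == _PAUSE)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], in_bout.view(np.int8), [0]))))
        for s, e in edges.reshape(-1, 2):
            golden_intervals.append((day_start + int(s) * minute, day_start + int(e) * minute))

    # one contiguous recording per day would also be valid; we emit one
    # recording spanning all days back-to-back for simplicity, day by day
    if config.days_per_participant == 1:
        schedule_s = np.repeat(schedules[0], 60)
        start = day0
    else:
        # concatenate full 24 h days so wall-clock alignment is preserved
        full = []
        for day, schedule in enumerate(schedules):
            padded = np.full(24 * 60, _SED, dtype=np.int8)
            h0 = day0.hour * 60 + day0.minute
            padded[h0 : h0 + schedule.size] = schedule
            full.append(padded)
        schedule_s = np.repeat(np.concatenate(full), 60)
        start = day0.normalize()

    hip = _location_recording(participant_id, "hip", start, schedule_s, gain, config, rng)
    ankle = _location_recording(participant_id, "ankle", start, schedule_s, gain, config, rng)
    golden = LabelTrack(participant_id, "golden", golden_intervals)
    diary = _diary_from_golden(golden, hip.start, hip.end, config, rng)
    return hip, ankle, golden, diary


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Generate the full train/validation/test cohort deterministically."""
    entries: List[CohortEntry] = []
    counter = 0
    for split in ("train", "validation", "test"):
        males, females = config.gender_counts[split]
        genders = ["male"] * males + ["female"] * females
        mult = config.split_gain[split] if config.drift_emulation else 1.0
        for gender in genders:
            counter += 1
            pid = f"P{counter:03d}"
            hip, ankle, golden, diary = generate_participant(
                config, pid, gender, gain_multiplier=mult
            )
            entries.append(
                CohortEntry(Participant(pid, gender, split), hip, ankle, golden, diary)
            )
    return SynthCohort(config, entries)
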