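"""Sleep scoring from per-minute activity counts.

A fly is scored asleep during any maximal run of >= 5 consecutive minutes
with zero activity counts; immobile runs of 1-4 minutes are transient
pauses (awake).  Traits are scored per 12h:12h photoperiod phase.

Conventions (documented, not asserted as anyone's ground truth):

* minute 0 of each recording day is lights-on; the day phase covers
  ``[0, day_length)`` and the night phase ``[day_length, period)``;
* a sleep bout crossing a phase boundary is one bout attributed to the
  phase in which it began, while its minutes count toward each phase's
  sleep-duration total;
* sleep latency is the time from lights-off to the onset of the first
  bout starting in the night phase, 720 if no such bout exists;
* runs truncated by the start/end of the recording are classified by
  their observed length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WAKE, SLEEP, PAUSE = 0, 1, 2
STATE_NAMES = {WAKE: "wake", SLEEP: "sleep", PAUSE: "transient_pause"}

SLEEP_RUN_MIN = 5  # minutes of immobility that define sleep


@dataclass(frozen=True)
class LightsSchedule:
    """12h:12h photoperiod by default; minute 0 of each day = lights-on."""

    day_length: int = 720
    period: int = 1440

    def __post_init__(self) -> None:
        if not 0 < self.day_length < self.period:
            raise ValueError("day_length must lie strictly inside the period")

    @property
    def night_length(self) -> int:
        return self.period - self.day_length

    def is_night(self, minutes: np.ndarray) -> np.ndarray:
        return (np.asarray(minutes) % self.period) >= self.day_length


@dataclass
class ActivityTrace:
    """Per-minute activity counts for one fly plus its photoperiod."""

    counts: np.ndarray
    schedule: LightsSchedule = field(default_factory=LightsSchedule)
    fly_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D minute series")
        if (self.counts < 0).any():
            raise ValueError("activity counts cannot be negative")

    @property
    def n_minutes(self) -> int:
        return self.counts.size

    @property
    def n_days(self) -> int:
        return self.counts.size // self.schedule.period

    def drop_first_day(self) -> "ActivityTrace":
        p = self.schedule.period
        if self.n_minutes <= p:
            raise ValueError("trace has no data beyond the first day")
        return ActivityTrace(self.counts[p:], self.schedule, self.fly_id)


@dataclass
class SleepTraits:
    """The eight scored sleep phenotypes (per day, or averaged across days)."""

    night_sleep: float
    day_sleep: float
    night_bout_number: float
    day_bout_number: float
    night_avg_bout_length: float
    day_avg_bout_length: float
    sleep_latency: float
    waking_activity: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


TRAIT_NAMES = [
    "night_sleep", "day_sleep", "night_bout_number", "day_bout_number",
    "night_avg_bout_length", "day_avg_bout_length", "sleep_latency",
    "waking_activity",
]


def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zero-count minutes as (start, length) pairs."""
    zero = counts == 0
    if not zero.any():
        return []
    padded = np.diff(np.concatenate(([0], zero.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def classify_states(trace: ActivityTrace) -> np.ndarray:
    """Label every minute as wake, sleep, or transient pause.

    Returns an int array (codes ``WAKE``/``SLEEP``/``PAUSE``) the same
    length as the trace.
    """
    states = np.full(trace.n_minutes, WAKE, dtype=np.int8)
    for start, length in _zero_runs(trace.counts):
        states[start:start + length] = SLEEP if length >= SLEEP_RUN_MIN else PAUSE
    return states


def sleep_bouts(trace: ActivityTrace) -> list[tuple[int, int]]:
    """(start, length) of every sleep bout (immobile runs >= 5 min)."""
    return [(s, ln) for s, ln in _zero_runs(trace.counts) if ln >= SLEEP_RUN_MIN]


def is_dead(trace: ActivityTrace, terminal_immobility: int = 1440) -> bool:
    """Heuristic death flag: trailing immobile span >= ``terminal_immobility``."""
    counts = trace.counts
    nz = np.flatnonzero(counts)
    trailing = counts.size if nz.size == 0 else counts.size - 1 - int(nz[-1])
    return trailing >= terminal_immobility


def _score_one_day(counts: np.ndarray, states: np.ndarray,
                   bouts: list[tuple[int, int]], day: int,
                   schedule: LightsSchedule) -> SleepTraits:
    p, dl = schedule.period, schedule.day_length
    lo, hi = day * p, (day + 1) * p
    day_slice = slice(lo, lo + dl)
    night_slice = slice(lo + dl, hi)

    day_sleep = int((states[day_slice] == SLEEP).sum())
    night_sleep = int((states[night_slice] == SLEEP).sum())

    # bout attribution: onset phase of the bout, onset day
    n_bouts = {"day": 0, "night": 0}
    bout_minutes = {"day": 0, "night": 0}
    latency = float(schedule.night_length)
    first_night_onset = None
    for start, length in bouts:
        if not lo <= start < hi:
            continue
        phase = "night" if (start - lo) >= dl else "day"
        n_bouts[phase] += 1
        bout_minutes[phase] += length
        if phase == "night" and first_night_onset is None:
            first_night_onset = start
    if first_night_onset is not None:
        latency = float(first_night_onset - (lo + dl))

    def avg(ph: str) -> float:
        return bout_minutes[ph] / n_bouts[ph] if n_bouts[ph] else 0.0

    awake = (states[lo:hi] != SLEEP)
    n_awake = int(awake.sum())
    total_counts = int(counts[lo:hi].sum())
    waking = total_counts / n_awake if n_awake else np.nan

    return SleepTraits(
        night_sleep=float(night_sleep),
        day_sleep=float(day_sleep),
        night_bout_number=float(n_bouts["night"]),
        day_bout_number=float(n_bouts["day"]),
        night_avg_bout_length=avg("night"),
        day_avg_bout_length=avg("day"),
        sleep_latency=latency,
        waking_activity=waking,
    )


def score_traits_by_day(trace: ActivityTrace,
                        discard_first_day: bool = False) -> list[SleepTraits]:
    """Score each complete recorded day separately."""
    if discard_first_day:
        trace = trace.drop_first_day()
    if trace.n_days < 1:
        raise ValueError("trace must cover at least one full day")
    states = classify_states(trace)
    bouts = sleep_bouts(trace)
    return [
        _score_one_day(trace.counts, states, bouts, d, trace.schedule)
        for d in range(trace.n_days)
    ]


def score_traits(trace: ActivityTrace, discard_first_day: bool = False) -> SleepTraits:
    """Score a trace, averaging per-day traits across complete days."""
    per_day = score_traits_by_day(trace, discard_first_day=discard_first_day)
    vals = {
        name: float(np.nanmean([getattr(t, name) for t in per_day]))
        for name in TRAIT_NAMES
    }
    return SleepTraits(**vals)


def population_state_fractions(state_series: list[np.ndarray]) -> pd.DataFrame:
    """Fraction of flies in each state at every aligned minute.

    All series must have equal length.  Returns a DataFrame with columns
    ``sleep``, ``wake``, ``pause`` summing to 1 at every minute.
    """
    if not state_series:
        raise ValueError("need at least one state series")
    mat = np.vstack(state_series)
    n = mat.shape[0]
    return pd.DataFrame({
        "sleep": (mat == SLEEP).sum(axis=0) / n,
        "wake": (mat == WAKE).sum(axis=0) / n,
        "pause": (mat == PAUSE).sum(axis=0) / n,
    })


@dataclass
class DeprivationDeltas:
    """Sleep change of the deprivation and recovery days vs. baseline."""

    baseline_night: float
    baseline_day: float
    baseline_total: float
    event_night_delta: float
    event_day_delta: float
    event_total_delta: float
    event_night_pct: float
    recovery_night_delta: float
    recovery_day_delta: float
    recovery_total_delta: float
    recovery_total_pct: float


def _day_totals(t: SleepTraits) -> tuple[float, float, float]:
    return t.night_sleep, t.day_sleep, t.night_sleep + t.day_sleep


def deprivation_deltas(day_series: list[SleepTraits], baseline_days: list[int],
                       event_day: int, recovery_day: int) -> DeprivationDeltas:
    """Compare deprivation-night and recovery-day sleep against baseline.

    ``day_series`` is indexed by recording day; ``baseline_days`` must be
    non-empty and precede ``event_day``.  Percent changes are relative to
    the baseline mean (positive = loss).
    """
    if not baseline_days:
        raise ValueError("baseline_days must be non-empty")
    if max(baseline_days) >= event_day:
        raise ValueError("baseline days must precede the deprivation day")
    for d in [*baseline_days, event_day, recovery_day]:
        if not 0 <= d < len(day_series):
            raise ValueError(f"day {d} missing from the series")

    base = np.array([_day_totals(day_series[d]) for d in baseline_days]).mean(axis=0)
    event = np.array(_day_totals(day_series[event_day]))
    rec = np.array(_day_totals(day_series[recovery_day]))

    def pct(baseline: float, delta: float) -> float:
        return 100.0 * (-delta) / baseline if baseline else np.nan

    return DeprivationDeltas(
        baseline_night=base[0], baseline_day=base[1], baseline_total=base[2],
        event_night_delta=event[0] - base[0],
        event_day_delta=event[1] - base[1],
        event_total_delta=event[2] - base[2],
        event_night_pct=pct(base[0], event[0] - base[0]),
        recovery_night_delta=rec[0] - base[0],
        recovery_day_delta=rec[1] - base[1],
        recovery_total_delta=rec[2] - base[2],
        recovery_total_pct=pct(base[2], rec[2] - base[2]),
    )


def percent_night_sleep_decrease(baseline_night: float, deprived_night: float) -> float:
    """Percent decrease in night sleep from baseline to the deprived night."""
    if baseline_night <= 0:
        raise ValueError("baseline night sleep must be positive")
    return 100.0 * (baseline_night - deprived_night) / baseline_night


def traits_frame(traits: list[SleepTraits], **metadata) -> pd.DataFrame:
    """Tidy one-row-per-fly table of scored traits plus metadata columns."""
    df = pd.DataFrame([t.as_dict() for t in traits])
    for key, vals in metadata.items():
        df[key] = vals
    return df
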