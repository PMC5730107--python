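"""Activity-trace generator with configurable sleep-bout structure.

Each simulated day draws a phase sleep total binomially around the
requested mean (so population means are recovered exactly in
expectation), splits it into immobile bouts of >= 5 minutes, and fills
the waking remainder with nonzero activity counts, optionally punctuated
by transient pauses (immobile runs of 1-4 minutes, scored awake).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..sleep import ActivityTrace, LightsSchedule


@dataclass(frozen=True)
class ActivitySpec:
    """Bout structure of the generated trace."""

    mean_bout_length: float = 60.0   # target average sleep-bout length, minutes
    activity_rate: float = 2.0       # mean counts per waking minute (>= 1 enforced)
    n_pauses_per_phase: int = 0      # transient pauses (1-4 min) inserted per phase
    deterministic_totals: bool = False  # use the requested means exactly


def _compose(total: int, parts: int, minimum: int,
             rng: np.random.Generator) -> np.ndarray:
    """Random composition of ``total`` into ``parts`` pieces, each >= minimum."""
    extra = total - parts * minimum
    if extra < 0:
        raise ValueError("infeasible composition")
    if parts == 0:
        return np.zeros(0, dtype=int)
    return minimum + rng.multinomial(extra, np.full(parts, 1.0 / parts))


def _build_phase(length: int, sleep_total: int, spec: ActivitySpec,
                 rng: np.random.Generator) -> np.ndarray:
    if sleep_total > length:
        raise ValueError(f"requested {sleep_total} sleep minutes in a "
                         f"{length}-minute phase")
    if sleep_total < 5:
        sleep_total = 0  # too short to form a bout

    counts = np.empty(length, dtype=np.int64)
    rate = max(spec.activity_rate, 1.0)
    counts[:] = 1 + rng.poisson(rate - 1.0, size=length)

    if sleep_total > 0:
        n_bouts = int(np.clip(round(sleep_total / spec.mean_bout_length),
                              1, sleep_total // 5))
        wake_total = length - sleep_total
        while n_bouts > 1 and wake_total < n_bouts - 1:
            n_bouts -= 1
        bouts = _compose(sleep_total, n_bouts, 5, rng)
        # distribute wake minutes into n_bouts+1 gaps; internal gaps >= 1
        internal = n_bouts - 1
        gaps = _compose(wake_total - internal, n_bouts + 1, 0, rng)
        gaps[1:-1] += 1 if internal else 0
        pos = 0
        for k in range(n_bouts):
            pos += gaps[k]
            counts[pos:pos + bouts[k]] = 0
            pos += bouts[k]

    # transient pauses: zero runs of 1-4 minutes inside wake stretches
    for _ in range(spec.n_pauses_per_phase):
        pause_len = int(rng.integers(1, 5))
        active = np.flatnonzero(counts > 0)
        # candidate starts whose window is active and not flush against a
        # zero run (which would merge into a sleep bout)
        ok = []
        for start in active:
            stop = start + pause_len
            if stop > length:
                continue
            if (counts[start:stop] > 0).all() \
                    and (start == 0 or counts[start - 1] > 0) \
                    and (stop == length or counts[stop] > 0):
                ok.append(start)
        if not ok:
            continue
        start = int(rng.choice(ok))
        counts[start:start + pause_len] = 0
    return counts


def simulate_activity(mean_night_sleep: float, mean_day_sleep: float,
                      bout_structure: ActivitySpec | dict | None = None,
                      n_minutes: int = 1440,
                      lights_schedule: LightsSchedule | None = None,
                      seed: int | np.random.Generator = 0,
                      fly_id: str = "") -> ActivityTrace:
    """Generate a per-minute activity trace hitting the requested sleep means.

    ``n_minutes`` must be a whole number of schedule periods.  Totals per
    phase are binomial draws with the requested mean (exact with
    ``deterministic_totals``); infeasible targets raise.
    """
    schedule = lights_schedule or LightsSchedule()
    if isinstance(bout_structure, dict):
        spec = ActivitySpec(**bout_structure)
    else:
        spec = bout_structure or ActivitySpec()
    if n_minutes % schedule.period:
        raise ValueError("n_minutes must be a whole number of days")
    day_len, night_len = schedule.day_length, schedule.night_length
    if not 0 <= mean_night_sleep <= night_len:
        raise ValueError("mean_night_sleep outside the night phase length")
    if not 0 <= mean_day_sleep <= day_len:
        raise ValueError("mean_day_sleep outside the day phase length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    chunks = []
    for _ in range(n_minutes // schedule.period):
        if spec.deterministic_totals:
            day_total = int(round(mean_day_sleep))
            night_total = int(round(mean_night_sleep))
        else:
            day_total = int(rng.binomial(day_len, mean_day_sleep / day_len))
            night_total = int(rng.binomial(night_len, mean_night_sleep / night_len))
        chunks.append(_build_phase(day_len, day_total, spec, rng))
        chunks.append(_build_phase(night_len, night_total, spec, rng))
    return ActivityTrace(np.concatenate(chunks), schedule, fly_id=fly_id)
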