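"""Simulated multi-day smart-home logs with known ground truth.

Each day is drawn from one of a few *routine profiles* — ordered schedules
of activity blocks with jittered start times and durations, optional
concurrent overlays (e.g. a toilet visit during the night's sleep) and a
sensor emission map that fires mapped sensors with a per-second Bernoulli
probability while an activity runs.  Gaps between blocks are idle.  The
generated logs are serialised in the interval dialect so they exercise the
whole parsing/preprocessing path, and every day carries its ground-truth
profile label for evaluating whether clustering recovers the day types.

The default fixture mimics a single-resident apartment with seven
activities and three day types: a *full-home* routine, an *evening-away*
routine (the resident leaves around 18:00 and returns late) and a
*night-away* routine (the resident is out from the evening until the next
morning).  The away windows of the three types are hours apart, so the day
types are well separated by construction; start/duration jitter defaults
to a 10-minute standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .io_preprocess import (IDLE, SECONDS_PER_DAY, ActivityInterval, SensorEvent,
                            DEFAULT_RESIDENT)

__all__ = ["ScheduleBlock", "OverlayRule", "RoutineProfile", "SimulationConfig",
           "SimulatedDataset", "generate_day", "generate_dataset",
           "write_logs", "default_profiles", "default_config"]

#: calendar anchor for simulated logs; day d starts at this date + d days, 04:00
EPOCH = datetime(2009, 6, 1, 4, 0, 0)

HOUR = 3600
MIN = 60


@dataclass(frozen=True)
class ScheduleBlock:
    """One routine activity block, timed in seconds from the 04:00 day start."""

    activity: str
    start_mean: int
    duration_mean: int
    start_sd: int = 10 * MIN
    duration_sd: int = 10 * MIN


@dataclass(frozen=True)
class OverlayRule:
    """A second, concurrent activity dropped on top of a base block.

    With probability *probability* per day, one interval of *activity*
    (jittered around *duration_mean*) is placed uniformly inside the
    ``window`` (seconds of day), restricted to stretches where exactly one
    activity is already running so concurrency never exceeds two.
    """

    activity: str
    probability: float
    window: tuple[int, int]
    duration_mean: int = 5 * MIN
    duration_sd: int = MIN


@dataclass(frozen=True)
class RoutineProfile:
    """A day type: ordered schedule blocks, overlays and sensor emissions."""

    profile_id: str
    blocks: tuple[ScheduleBlock, ...]
    overlays: tuple[OverlayRule, ...] = ()
    emissions: dict = field(default_factory=dict)  # activity -> {sensor: p/sec}

    def __post_init__(self) -> None:
        starts = [b.start_mean for b in self.blocks]
        if starts != sorted(starts):
            raise ValueError(f"profile {self.profile_id}: blocks must be ordered by mean start")


@dataclass(frozen=True)
class SimulationConfig:
    """Mixture of routine profiles plus global simulation knobs."""

    profiles: tuple[RoutineProfile, ...]
    weights: tuple[float, ...]
    n_days: int = 30
    seed: int = 0
    noise_rate: float = 0.0   # spurious sensor activations per second
    resident: str = DEFAULT_RESIDENT

    def __post_init__(self) -> None:
        if len(self.profiles) != len(self.weights):
            raise ValueError("one weight per profile is required")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {sum(self.weights)}")


@dataclass
class SimulatedDataset:
    """Generated raw logs plus the ground-truth day-type labels."""

    activity_intervals: list
    sensor_events: list
    labels: list            # day index -> profile_id
    config: SimulationConfig


def _jitter(rng: np.random.Generator, mean: int, sd: int, lo: int, hi: int) -> int:
    """Truncated-normal integer draw clipped into [lo, hi]."""
    if sd == 0:
        return int(np.clip(mean, lo, hi))
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


def generate_day(profile: RoutineProfile, rng: np.random.Generator,
                 day_index: int = 0, resident: str = DEFAULT_RESIDENT,
                 noise_rate: float = 0.0,
                 sensor_alphabet: tuple[str, ...] | None = None,
                 ) -> tuple[list[ActivityInterval], list[SensorEvent]]:
    """Sample one experiment day of activity intervals and sensor events.

    Blocks are jittered then forced into order (a block cannot start before
    the previous one ends) and truncated at the day end; gaps stay idle.
    """
    day_start = EPOCH + timedelta(days=day_index)

    def ts(sec: int) -> datetime:
        return day_start + timedelta(seconds=int(sec))

    intervals: list[ActivityInterval] = []
    segs: list[tuple[int, int, str]] = []
    cursor = 0
    for blk in profile.blocks:
        start = max(_jitter(rng, blk.start_mean, blk.start_sd, 0, SECONDS_PER_DAY), cursor)
        dur = _jitter(rng, blk.duration_mean, blk.duration_sd, 1, SECONDS_PER_DAY)
        end = min(start + dur, SECONDS_PER_DAY)
        if start >= SECONDS_PER_DAY or end <= start:
            continue  # schedule overflow: block truncated away
        segs.append((start, end, blk.activity))
        intervals.append(ActivityInterval(blk.activity, ts(start), ts(end), resident))
        cursor = end

    for rule in profile.overlays:
        if rng.random() >= rule.probability:
            continue
        dur = _jitter(rng, rule.duration_mean, rule.duration_sd, 1, SECONDS_PER_DAY)
        lo, hi = rule.window
        # candidate stretches inside the window covered by exactly one base block
        hosts = [(max(s, lo), min(e, hi)) for s, e, _a in segs
                 if min(e, hi) - max(s, lo) >= dur]
        if not hosts:
            continue
        s, e = hosts[int(rng.integers(len(hosts)))]
        start = int(rng.integers(s, e - dur + 1))
        intervals.append(ActivityInterval(rule.activity, ts(start), ts(start + dur), resident))

    events: list[SensorEvent] = []
    for s, e, activity in segs:
        for sensor, p in profile.emissions.get(activity, {}).items():
            if p <= 0:
                continue
            active = rng.random(e - s) < p
            edges = np.flatnonzero(np.diff(np.concatenate(([0], active.astype(np.int8), [0]))))
            for lo_i, hi_i in zip(edges[::2], edges[1::2]):
                events.append(SensorEvent(sensor, ts(s + lo_i), ts(s + hi_i)))

    if noise_rate > 0 and sensor_alphabet:
        n_noise = rng.poisson(noise_rate * SECONDS_PER_DAY)
        for _ in range(n_noise):
            sensor = sensor_alphabet[int(rng.integers(len(sensor_alphabet)))]
            start = int(rng.integers(SECONDS_PER_DAY - 10))
            events.append(SensorEvent(sensor, ts(start), ts(start + int(rng.integers(1, 10)))))

    intervals.sort(key=lambda a: a.start)
    events.sort(key=lambda e: e.start)
    return intervals, events


def generate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw day types from the mixture and generate all days' logs."""
    rng = np.random.default_rng(cfg.seed)
    sensors = tuple(sorted({s for p in cfg.profiles
                            for em in p.emissions.values() for s in em}))
    type_idx = rng.choice(len(cfg.profiles), size=cfg.n_days, p=cfg.weights)
    intervals: list[ActivityInterval] = []
    events: list[SensorEvent] = []
    labels: list[str] = []
    for day in range(cfg.n_days):
        profile = cfg.profiles[int(type_idx[day])]
        labels.append(profile.profile_id)
        ivs, evs = generate_day(profile, rng, day, cfg.resident,
                                cfg.noise_rate, sensors)
        intervals.extend(ivs)
        events.extend(evs)
    return SimulatedDataset(intervals, events, labels, cfg)


def write_logs(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Serialise a simulated dataset in the interval log dialect.

    Writes ``sensors.tsv`` and ``activities.tsv`` (tab-separated interval
    records) plus ``labels.tsv`` mapping day index to ground-truth type.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%Y-%m-%d %H:%M:%S"
    paths = {"sensors": out / "sensors.tsv",
             "activities": out / "activities.tsv",
             "labels": out / "labels.tsv"}
    with open(paths["sensors"], "w", encoding="utf-8") as fh:
        for e in ds.sensor_events:
            fh.write(f"{e.start.strftime(fmt)}\t{e.end.strftime(fmt)}\t{e.sensor_id}\n")
    with open(paths["activities"], "w", encoding="utf-8") as fh:
        for a in ds.activity_intervals:
            fh.write(f"{a.start.strftime(fmt)}\t{a.end.strftime(fmt)}\t"
                     f"{a.activity}\t{a.resident_id}\n")
    with open(paths["labels"], "w", encoding="utf-8") as fh:
        fh.write("day\tprofile\n")
        for day, lab in enumerate(ds.labels):
            fh.write(f"{day}\t{lab}\n")
    return paths


# ---------------------------------------------------------------------------
# default fixture: three single-resident day types
# ---------------------------------------------------------------------------

_EMISSIONS = {
    "go to bed": {"bed_pressure": 0.9},
    "use toilet": {"toilet_flush": 0.3, "bathroom_door": 0.4},
    "prepare breakfast": {"fridge_door": 0.2, "cupboard": 0.2},
    "prepare dinner": {"fridge_door": 0.3, "stove": 0.4},
    "take shower": {"bathroom_door": 0.5},
    "get drink": {"fridge_door": 0.5},
    "leave house": {"front_door": 0.02},
}


def default_profiles(start_sd: int = 10 * MIN, duration_sd: int = 10 * MIN,
                     overlay_probability: float = 0.6) -> tuple[RoutineProfile, ...]:
    """Three well-separated Kasteren-like day types.

    The away windows (none / 14:00–04:00 / 16:00–next morning) of the
    three types are disjoint for more than six hours of the day, so the
    types are distinguishable by any reasonable whole-day metric.
    """
    def blk(activity, start, dur):
        return ScheduleBlock(activity, start, dur, start_sd, duration_sd)

    toilet_overlay = OverlayRule("use toilet", overlay_probability,
                                 (19 * HOUR, 23 * HOUR), 5 * MIN, MIN)

    full_home = RoutineProfile(
        "full_home",
        blocks=(
            blk("prepare breakfast", 4 * HOUR, 30 * MIN),        # 08:00
            blk("take shower", int(4.6 * HOUR), 20 * MIN),
            blk("leave house", 6 * HOUR, 3 * HOUR),              # short errand
            blk("get drink", int(9.5 * HOUR), 10 * MIN),
            blk("prepare dinner", 14 * HOUR, 1 * HOUR),          # 18:00
            blk("use toilet", int(15.2 * HOUR), 5 * MIN),
            blk("go to bed", 19 * HOUR, int(8.5 * HOUR)),        # 23:00-07:30
        ),
        overlays=(toilet_overlay,),
        emissions=_EMISSIONS,
    )
    evening_away = RoutineProfile(
        "evening_away",
        blocks=(
            blk("prepare breakfast", 4 * HOUR, 30 * MIN),
            blk("take shower", int(4.6 * HOUR), 20 * MIN),
            blk("get drink", 8 * HOUR, 10 * MIN),
            blk("leave house", 10 * HOUR, 14 * HOUR),            # 14:00-04:00 away
        ),
        emissions=_EMISSIONS,
    )
    night_away = RoutineProfile(
        "night_away",
        blocks=(
            blk("go to bed", 0, int(3.5 * HOUR)),                # sleeps until 07:30
            blk("prepare breakfast", 4 * HOUR, 30 * MIN),
            blk("use toilet", int(4.8 * HOUR), 5 * MIN),
            blk("prepare dinner", 10 * HOUR, 45 * MIN),          # early dinner 14:00
            blk("leave house", 12 * HOUR, 12 * HOUR),            # 16:00 to next morning
        ),
        emissions=_EMISSIONS,
    )
    return full_home, evening_away, night_away


def default_config(n_days: int = 30, seed: int = 0,
                   noise_rate: float = 0.0) -> SimulationConfig:
    """Default study conditions: 30 days over the three default day types."""
    profiles = default_profiles()
    w = 1.0 / len(profiles)
    return SimulationConfig(profiles, (w,) * len(profiles), n_days=n_days,
                            seed=seed, noise_rate=noise_rate)
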