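"""Parsing and preprocessing of smart-home event logs.

Two raw log dialects are supported:

* **interval logs** (Kasteren style) — one record per line holding a start
  time, an end time and a sensor or activity identifier;
* **point-event logs** (CASAS style) — one record per line holding a date,
  a time, a sensor id, a binary value and, optionally, an activity label
  tagged ``begin`` or ``end``.

Both are reduced to the same in-memory representation: per-second *daily
vectors*.  An experiment day runs from 04:00 on one calendar day to 04:00
on the next (sleep brackets both ends), so each day has 86,400 one-second
slots.  A slot of a :class:`DailySensorVector` holds the set of sensors
active during that second; a slot of a :class:`DailyActivityVector` holds
the set of annotated activities in effect (at most two concurrent ones),
or the reserved ``"no activity"`` label when nothing is annotated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86_400
IDLE = "no activity"
DEFAULT_DAY_START = timedelta(hours=4)
DEFAULT_RESIDENT = "R1"

#: sensor value tokens accepted as binary (after cleanup normalisation)
_BINARY_ON = {"ON", "OPEN", "PRESENT", "1", "TRUE"}
_BINARY_OFF = {"OFF", "CLOSE", "CLOSED", "ABSENT", "0", "FALSE"}
#: default CASAS token cleanups ("OF" is a known typo for "OFF")
DEFAULT_VALUE_CLEANUP = {"OF": "OFF", "ONN": "ON"}


class ParseError(ValueError):
    """A raw log line could not be interpreted; carries the line number."""


class ValidationError(ValueError):
    """Parsed data violate a structural constraint (e.g. end < start)."""


# ---------------------------------------------------------------------------
# timestamps
# ---------------------------------------------------------------------------

def round_to_second(ts: datetime) -> datetime:
    """Round a timestamp to the nearest whole second, halves up."""
    if ts.microsecond == 0:
        return ts
    base = ts.replace(microsecond=0)
    if ts.microsecond >= 500_000:
        base += timedelta(seconds=1)
    return base


def _parse_timestamp(text: str, year_cleanup: dict[int, int] | None = None) -> datetime:
    """Parse a timestamp string leniently; optionally fix impossible years."""
    if year_cleanup:
        head = text.split("-", 1)[0]
        if head.isdigit() and int(head) in year_cleanup:
            text = f"{year_cleanup[int(head)]}-{text.split('-', 1)[1]}"
    try:
        ts = pd.Timestamp(text)
    except (ValueError, pd.errors.OutOfBoundsDatetime) as exc:
        raise ParseError(f"unparseable timestamp {text!r}") from exc
    return round_to_second(ts.to_pydatetime())


# ---------------------------------------------------------------------------
# event records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorEvent:
    """An interval during which one binary sensor was active.

    Timestamps are whole seconds; the interval is half-open ``[start, end)``.
    """

    sensor_id: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"sensor {self.sensor_id}: end {self.end} before start {self.start}"
            )


@dataclass(frozen=True)
class ActivityInterval:
    """An annotated activity of one resident over a half-open time interval."""

    activity: str
    start: datetime
    end: datetime
    resident_id: str = DEFAULT_RESIDENT

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"activity {self.activity!r}: end {self.end} before start {self.start}"
            )


# ---------------------------------------------------------------------------
# daily vectors
# ---------------------------------------------------------------------------

def _as_slot_array(slots: Iterable[frozenset]) -> np.ndarray:
    if isinstance(slots, np.ndarray) and slots.dtype == object:
        return slots
    arr = np.empty(len(list(slots)) if not hasattr(slots, "__len__") else len(slots), dtype=object)
    for i, s in enumerate(slots):
        arr[i] = s if isinstance(s, frozenset) else frozenset(s)
    return arr


@dataclass
class DailySensorVector:
    """Per-slot sets of active sensors for one experiment day."""

    day_index: int
    slots: np.ndarray  # object array of frozenset[str]

    def __post_init__(self) -> None:
        self.slots = _as_slot_array(self.slots)

    def __len__(self) -> int:
        return len(self.slots)


@dataclass
class DailyActivityVector:
    """Per-slot activity sets (size 1 or 2) for one experiment day.

    Slots with no annotation hold exactly ``{"no activity"}``.
    """

    day_index: int
    slots: np.ndarray  # object array of frozenset[str]

    def __post_init__(self) -> None:
        self.slots = _as_slot_array(self.slots)

    def __len__(self) -> int:
        return len(self.slots)

    def validate(self) -> None:
        for i, s in enumerate(self.slots):
            if not 1 <= len(s) <= 2:
                raise ValidationError(
                    f"day {self.day_index}, slot {i}: activity set size {len(s)}"
                )


def vector_from_runs(day_index: int, runs: Sequence[tuple[Iterable[str], int]],
                     kind: str = "activity") -> DailyActivityVector | DailySensorVector:
    """Build a daily vector from ``(labels, length)`` run-length pairs.

    Convenience for tests and the synthetic generator; the run lengths must
    sum to the desired day length.  Identical runs share one frozenset
    object, keeping memory proportional to the number of runs.
    """
    n = sum(length for _, length in runs)
    slots = np.empty(n, dtype=object)
    pos = 0
    for labels, length in runs:
        fs = frozenset(labels)
        slots[pos:pos + length] = fs
        pos += length
    cls = DailyActivityVector if kind == "activity" else DailySensorVector
    return cls(day_index, slots)


@dataclass
class PreprocessedDataset:
    """All daily vectors for one home, plus the alphabets they draw from."""

    sensor_alphabet: tuple[str, ...]
    activity_alphabet: tuple[str, ...]
    sensor_days: list[DailySensorVector]
    activity_days: dict[str, list[DailyActivityVector]]  # resident -> days
    day_start_offset: timedelta = DEFAULT_DAY_START
    slot_seconds: int = 1
    first_day_start: datetime | None = None

    @property
    def n_days(self) -> int:
        return len(self.sensor_days)

    @property
    def residents(self) -> tuple[str, ...]:
        return tuple(sorted(self.activity_days))

    def validate(self) -> None:
        n = SECONDS_PER_DAY // self.slot_seconds
        for day in self.sensor_days:
            if len(day) != n:
                raise ValidationError(f"sensor day {day.day_index} has {len(day)} slots, want {n}")
        for res, days in self.activity_days.items():
            for day in days:
                if len(day) != n:
                    raise ValidationError(
                        f"{res} day {day.day_index} has {len(day)} slots, want {n}")
                day.validate()


# ---------------------------------------------------------------------------
# interval-log (Kasteren) dialect
# ---------------------------------------------------------------------------

def parse_interval_log(path: str | Path, kind: str) -> list:
    """Parse a tab-separated interval log.

    Each non-comment line holds ``start<TAB>end<TAB>id`` and, for activity
    logs, an optional fourth resident-id field.  Timestamps are rounded to
    the nearest second (halves up).  Records come back sorted by start time.

    Parameters
    ----------
    path
        Log file to read.
    kind
        ``"sensor"`` or ``"activity"``; selects the record type.
    """
    if kind not in ("sensor", "activity"):
        raise ValueError(f"kind must be 'sensor' or 'activity', got {kind!r}")
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected at least 3 tab-separated "
                                 f"fields, got {len(fields)}: {line!r}")
            try:
                start = _parse_timestamp(fields[0])
                end = _parse_timestamp(fields[1])
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            ident = fields[2].strip()
            if not ident:
                raise ParseError(f"{path}:{lineno}: empty identifier")
            if end < start:
                raise ValidationError(f"{path}:{lineno}: end {end} before start {start}")
            if kind == "sensor":
                records.append(SensorEvent(ident, start, end))
            else:
                resident = fields[3].strip() if len(fields) > 3 else DEFAULT_RESIDENT
                records.append(ActivityInterval(ident, start, end, resident))
    records.sort(key=lambda r: r.start)
    return records


# ---------------------------------------------------------------------------
# point-event (CASAS) dialect
# ---------------------------------------------------------------------------

def _split_resident(label: str) -> tuple[str, str]:
    """Split an ``R1_eating`` style label into resident and activity."""
    if len(label) > 3 and label[0] == "R" and label[1].isdigit() and label[2] == "_":
        return label[:2], label[3:]
    return DEFAULT_RESIDENT, label


def parse_casas_log(path: str | Path,
                    value_cleanup: dict[str, str] | None = None,
                    year_cleanup: dict[int, int] | None = None,
                    unclosed_policy: str = "close",
                    ) -> tuple[list[SensorEvent], list[ActivityInterval]]:
    """Parse a CASAS point-event log into sensor intervals and activities.

    Lines are whitespace separated: ``date time sensor value [activity
    begin|end]``.  Known token typos are normalised through *value_cleanup*
    (default maps ``OF`` to ``OFF``); impossible years are corrected through
    *year_cleanup* (e.g. ``{22009: 2009}``).  Numeric, non-binary sensor
    readings (temperature, power, ...) are dropped.  ``begin``/``end``
    activity tags are paired into :class:`ActivityInterval` records per
    resident.

    Parameters
    ----------
    unclosed_policy
        What to do with a ``begin`` that never sees its ``end``:
        ``"close"`` ends it at the last timestamp in the log and warns,
        ``"error"`` raises.
    """
    if unclosed_policy not in ("close", "error"):
        raise ValueError(f"unknown unclosed_policy {unclosed_policy!r}")
    cleanup = dict(DEFAULT_VALUE_CLEANUP)
    if value_cleanup:
        cleanup.update(value_cleanup)

    sensor_on: dict[str, datetime] = {}
    open_acts: dict[tuple[str, str], datetime] = {}
    events: list[SensorEvent] = []
    intervals: list[ActivityInterval] = []
    last_ts: datetime | None = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected at least 4 fields: {line!r}")
            try:
                ts = _parse_timestamp(f"{fields[0]} {fields[1]}", year_cleanup)
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            last_ts = ts if last_ts is None else max(last_ts, ts)
            sensor, value = fields[2], fields[3]
            value = cleanup.get(value, cleanup.get(value.upper(), value))
            upper = value.upper()
            if upper in _BINARY_ON:
                sensor_on.setdefault(sensor, ts)
            elif upper in _BINARY_OFF:
                start = sensor_on.pop(sensor, None)
                if start is not None:
                    events.append(SensorEvent(sensor, start, max(ts, start)))
            else:
                try:
                    float(value)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: unknown sensor value token {value!r}") from None
                # numeric reading: non-binary sensor, excluded
                continue
            if len(fields) >= 6:
                label, tag = fields[4], fields[5].lower()
                resident, activity = _split_resident(label)
                key = (resident, activity)
                if tag == "begin":
                    open_acts[key] = ts
                elif tag == "end":
                    start = open_acts.pop(key, None)
                    if start is None:
                        raise ParseError(
                            f"{path}:{lineno}: 'end' for {label!r} without matching 'begin'")
                    intervals.append(ActivityInterval(activity, start, max(ts, start), resident))
                else:
                    raise ParseError(f"{path}:{lineno}: expected begin/end tag, got {tag!r}")

    # sensors still on / activities still open at log end
    for sensor, start in sensor_on.items():
        events.append(SensorEvent(sensor, start, last_ts))
    if open_acts:
        if unclosed_policy == "error":
            names = ", ".join(f"{r}:{a}" for r, a in open_acts)
            raise ValidationError(f"unclosed activity annotations: {names}")
        for (resident, activity), start in open_acts.items():
            warnings.warn(f"activity {activity!r} ({resident}) never closed; "
                          f"closing at log end {last_ts}", stacklevel=2)
            intervals.append(ActivityInterval(activity, start, last_ts, resident))

    events.sort(key=lambda e: e.start)
    intervals.sort(key=lambda a: a.start)
    return events, intervals


# ---------------------------------------------------------------------------
# daily vector construction
# ---------------------------------------------------------------------------

def _day_origin(first: datetime, offset: timedelta) -> datetime:
    """First experiment-day boundary at or after the earliest timestamp."""
    boundary = first.replace(hour=0, minute=0, second=0, microsecond=0) + offset
    if boundary < first:
        boundary += timedelta(days=1)
    return boundary


def _sweep_day(intervals: list[tuple[int, int, str]], n: int, default: frozenset,
               day_index: int, concurrency_limit: int | None,
               concurrency_policy: str) -> np.ndarray:
    """Fill one day's slots from clipped ``(start, end, label)`` intervals.

    Runs a boundary sweep so every constant stretch shares one frozenset.
    """
    marks: dict[int, list[tuple[bool, int]]] = {}
    for idx, (s, e, _lab) in enumerate(intervals):
        if s < e:
            marks.setdefault(s, []).append((True, idx))
            marks.setdefault(e, []).append((False, idx))
    slots = np.empty(n, dtype=object)
    if not marks:
        slots[:] = default
        return slots
    points = sorted(marks)
    active: set[int] = set()
    pos = 0
    for pt in points:
        if pt > pos:
            slots[pos:pt] = _slot_set(active, intervals, default, day_index, pos,
                                      concurrency_limit, concurrency_policy)
            pos = pt
        for starting, idx in marks[pt]:
            (active.add if starting else active.discard)(idx)
    if pos < n:
        slots[pos:n] = _slot_set(active, intervals, default, day_index, pos,
                                 concurrency_limit, concurrency_policy)
    return slots


def _slot_set(active: set[int], intervals, default: frozenset, day_index: int,
              slot: int, limit: int | None, policy: str) -> frozenset:
    if not active:
        return default
    labels = {intervals[i][2] for i in active}
    if limit is not None and len(labels) > limit:
        if policy == "keep_two_longest":
            by_len = sorted(active, key=lambda i: (intervals[i][1] - intervals[i][0], -i),
                            reverse=True)
            labels = set()
            for i in by_len:
                labels.add(intervals[i][2])
                if len(labels) == limit:
                    break
        else:
            raise ValidationError(
                f"day {day_index}, slot {slot}: {len(labels)} concurrent activities "
                f"{sorted(labels)} exceed the limit of {limit}")
    return frozenset(labels)


def build_daily_vectors(events: Sequence[SensorEvent],
                        intervals: Sequence[ActivityInterval],
                        day_start_offset: timedelta = DEFAULT_DAY_START,
                        slot_seconds: int = 1,
                        edge_policy: str = "extend",
                        concurrency_policy: str = "error",
                        sensor_alphabet: Sequence[str] | None = None,
                        activity_alphabet: Sequence[str] | None = None,
                        origin: datetime | None = None,
                        ) -> PreprocessedDataset:
    """Slice parsed logs into per-second daily sensor and activity vectors.

    Experiment days are half-open windows ``[origin + d·24 h, origin +
    (d+1)·24 h)`` where *origin* is the first 04:00 boundary (for the
    default offset) at or after the earliest timestamp; data before it are
    disregarded.  An interval covers a slot iff it covers the slot's start
    second (intervals half-open).  Activity annotations of different
    residents are kept separate; sensors are shared.

    Parameters
    ----------
    edge_policy
        ``"extend"`` completes a trailing partial day by holding the last
        observed state; ``"drop"`` discards it.
    concurrency_policy
        ``"error"`` rejects slots with more than two concurrent activities;
        ``"keep_two_longest"`` keeps the two longest-running ones.
    origin
        Explicit start of experiment day 0.  By default the first day
        boundary at or after the earliest timestamp is used (data before
        it are disregarded); pass a known recording start to pin the day
        grid, e.g. when ground-truth day labels must stay aligned.
    """
    if day_start_offset >= timedelta(hours=24):
        raise ValueError("day_start_offset must be below 24 h")
    if edge_policy not in ("extend", "drop"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    if concurrency_policy not in ("error", "keep_two_longest"):
        raise ValueError(f"unknown concurrency_policy {concurrency_policy!r}")
    if SECONDS_PER_DAY % slot_seconds:
        raise ValueError("slot_seconds must divide 86,400")
    if not events and not intervals:
        raise ValueError("no events or activity intervals given")

    all_starts = [e.start for e in events] + [a.start for a in intervals]
    all_ends = [e.end for e in events] + [a.end for a in intervals]
    if origin is None:
        origin = _day_origin(min(all_starts), day_start_offset)
    data_end = max(max(all_ends), origin)

    span = (data_end - origin).total_seconds()
    n_days = math.ceil(span / SECONDS_PER_DAY) if edge_policy == "extend" \
        else math.floor(span / SECONDS_PER_DAY)
    if n_days < 1:
        raise ValueError("logs do not span a single full experiment day")
    extend_from = None
    if edge_policy == "extend" and span < n_days * SECONDS_PER_DAY:
        # second within the last day where data stop
        extend_from = int(span) - (n_days - 1) * SECONDS_PER_DAY

    sensors = tuple(sorted(sensor_alphabet)) if sensor_alphabet is not None \
        else tuple(sorted({e.sensor_id for e in events}))
    residents = sorted({a.resident_id for a in intervals}) or [DEFAULT_RESIDENT]
    observed_acts = {a.activity for a in intervals}
    if activity_alphabet is not None:
        missing = observed_acts - set(activity_alphabet)
        if missing:
            raise ValidationError(f"activities outside declared alphabet: {sorted(missing)}")
        activities = tuple(sorted(set(activity_alphabet) | {IDLE}))
    else:
        activities = tuple(sorted(observed_acts | {IDLE}))

    def clipped(day: int, recs, label_of) -> list[tuple[int, int, str]]:
        lo = origin + timedelta(seconds=day * SECONDS_PER_DAY)
        out = []
        for r in recs:
            s = int((r.start - lo).total_seconds())
            e = int((r.end - lo).total_seconds())
            s, e = max(s, 0), min(e, SECONDS_PER_DAY)
            if s < e:
                out.append((s, e, label_of(r)))
        return out

    empty = frozenset()
    idle = frozenset({IDLE})
    sensor_days: list[DailySensorVector] = []
    activity_days: dict[str, list[DailyActivityVector]] = {r: [] for r in residents}
    per_res = {r: [a for a in intervals if a.resident_id == r] for r in residents}

    for day in range(n_days):
        slots = _sweep_day(clipped(day, events, lambda e: e.sensor_id),
                           SECONDS_PER_DAY, empty, day, None, concurrency_policy)
        if day == n_days - 1 and extend_from is not None and extend_from > 0:
            slots[extend_from:] = slots[extend_from - 1]
        sensor_days.append(DailySensorVector(day, slots))
        for res in residents:
            slots = _sweep_day(clipped(day, per_res[res], lambda a: a.activity),
                               SECONDS_PER_DAY, idle, day, 2, concurrency_policy)
            if day == n_days - 1 and extend_from is not None and extend_from > 0:
                slots[extend_from:] = slots[extend_from - 1]
            activity_days[res].append(DailyActivityVector(day, slots))

    ds = PreprocessedDataset(sensors, activities, sensor_days, activity_days,
                             day_start_offset, slot_seconds, first_day_start=origin)
    if slot_seconds > 1:
        from .entropy import resize  # late import; resize lives with entropy tooling
        ds.sensor_days = [resize(d, slot_seconds, idle_label=None) for d in ds.sensor_days]
        ds.activity_days = {r: [resize(d, slot_seconds) for d in days]
                            for r, days in ds.activity_days.items()}
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# wide per-second matrix format
# ---------------------------------------------------------------------------

def _wide_columns(ds: PreprocessedDataset) -> list[str]:
    cols = ["day"]
    cols += [f"s:{s}" for s in ds.sensor_alphabet]
    for res in ds.residents:
        cols += [f"a:{res}:{a}" for a in ds.activity_alphabet]
    return cols


def write_wide_matrix(ds: PreprocessedDataset, path: str | Path) -> None:
    """Write the dataset as a tab-separated 0/1 matrix, one line per slot.

    Columns: day index, one column per sensor, then one column per
    (resident, activity).  Value 1 marks an active sensor or a present
    activity.  The format round-trips losslessly through
    :func:`read_wide_matrix`.
    """
    cols = _wide_columns(ds)
    sensor_pos = {s: i for i, s in enumerate(ds.sensor_alphabet)}
    act_pos: dict[tuple[str, str], int] = {}
    off = 1 + len(ds.sensor_alphabet)
    for res in ds.residents:
        for a in ds.activity_alphabet:
            act_pos[(res, a)] = off
            off += 1
    ncol = off

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for d in range(ds.n_days):
            n = len(ds.sensor_days[d])
            mat = np.zeros((n, ncol), dtype=np.int64)
            mat[:, 0] = ds.sensor_days[d].day_index
            for i, s in enumerate(ds.sensor_days[d].slots):
                for sensor in s:
                    mat[i, 1 + sensor_pos[sensor]] = 1
            for res in ds.residents:
                for i, s in enumerate(ds.activity_days[res][d].slots):
                    for a in s:
                        mat[i, act_pos[(res, a)]] = 1
            pd.DataFrame(mat).to_csv(fh, sep="\t", header=False, index=False)


def read_wide_matrix(path: str | Path) -> PreprocessedDataset:
    """Read a wide per-second matrix back into a :class:`PreprocessedDataset`."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if not cols or cols[0] != "day":
        raise ValidationError(f"{path}: first column must be 'day', got {cols[:1]}")
    sensors = [c[2:] for c in cols if c.startswith("s:")]
    act_cols = [c for c in cols if c.startswith("a:")]
    if len(cols) != 1 + len(sensors) + len(act_cols):
        bad = [c for c in cols[1:] if not c.startswith(("s:", "a:"))]
        raise ValidationError(f"{path}: unrecognised columns {bad}")
    residents = sorted({c.split(":", 2)[1] for c in act_cols})
    activities = sorted({c.split(":", 2)[2] for c in act_cols})

    day_col = df["day"].to_numpy()
    day_ids = sorted(set(day_col.tolist()))
    n = int((day_col == day_ids[0]).sum())

    def decode(block: np.ndarray, labels: list[str], default: frozenset) -> np.ndarray:
        """Run-length decode a 0/1 block into shared frozenset slots."""
        slots = np.empty(len(block), dtype=object)
        change = np.flatnonzero((np.diff(block, axis=0) != 0).any(axis=1))
        bounds = np.concatenate(([0], change + 1, [len(block)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            on = np.flatnonzero(block[lo])
            fs = frozenset(labels[j] for j in on) if on.size else default
            slots[lo:hi] = fs
        return slots

    sensor_days, activity_days = [], {r: [] for r in residents}
    for d in day_ids:
        sub = df[day_col == d]
        if len(sub) != n:
            raise ValidationError(f"{path}: day {d} has {len(sub)} lines, expected {n}")
        sblock = sub[[f"s:{s}" for s in sensors]].to_numpy() if sensors \
            else np.zeros((n, 0), dtype=int)
        sensor_days.append(DailySensorVector(int(d), decode(sblock, sensors, frozenset())))
        for res in residents:
            ablock = sub[[f"a:{res}:{a}" for a in activities]].to_numpy()
            activity_days[res].append(
                DailyActivityVector(int(d), decode(ablock, activities, frozenset({IDLE}))))

    slot_seconds = SECONDS_PER_DAY // n
    ds = PreprocessedDataset(tuple(sensors), tuple(activities), sensor_days,
                             activity_days, slot_seconds=slot_seconds)
    ds.validate()
    return ds
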