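"""Core data types for sensor events and ground-truth activities.

A :class:`SensorEvent` is one timestamped firing of one sensor with a
type-specific payload.  An :class:`EventLog` is a canonically sorted,
duplicate-free sequence of events plus session metadata.  Ground truth
arrives as :class:`ActivityRecord` intervals (half-open ``[start, end)``).

Serialization: JSON Lines (one object per line, optional leading metadata
object) and RFC-4180 CSV with flattened payload columns.  Timestamps are
ISO-8601 UTC with millisecond resolution; all duration arithmetic is done
in seconds as floats.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ParseError, SchemaError

__all__ = [
    "SensorType",
    "SensorEvent",
    "ActivityRecord",
    "EventLog",
    "ACTIVITY_TYPES",
    "QUESTION_IDS",
    "parse_timestamp",
    "format_timestamp",
    "quantize_ms",
    "read_event_log",
    "write_event_log",
    "read_activity_log",
    "write_activity_log",
]


class SensorType(str, Enum):
    MOTION = "motion"
    MAT = "mat"
    DISTANCE = "distance"
    DOOR = "door"
    WEIGHT_SCALE = "weight_scale"
    SPEAKER = "speaker"


DISTANCE_POSITIONS = frozenset({"first_step", "last_step"})
DOOR_STATES = frozenset({"opened", "closed"})
QUESTION_IDS = ("availability", "exhaustion", "frequency")

ACTIVITY_TYPES = frozenset(
    {
        "room_presence",
        "sitting",
        "weight_measuring",
        "stair_climbing",
        "exhaustion_report",
        "entry_exit",
    }
)

_UTC = timezone.utc


# ---------------------------------------------------------------------------
# timestamps
# ---------------------------------------------------------------------------

def parse_timestamp(text: str) -> datetime:
    """Parse an ISO-8601 timestamp into an aware UTC datetime.

    Accepts a trailing ``Z`` or an explicit offset; naive timestamps are
    rejected.
    """
    raw = text.strip()
    if raw.endswith(("Z", "z")):
        raw = raw[:-1] + "+00:00"
    try:
        dt = datetime.fromisoformat(raw)
    except ValueError as exc:
        raise ParseError(f"malformed timestamp {text!r}: {exc}") from None
    if dt.tzinfo is None:
        raise ParseError(f"timestamp {text!r} lacks a UTC offset")
    return dt.astimezone(_UTC)


def format_timestamp(dt: datetime) -> str:
    """Serialize to ISO-8601 UTC with exactly millisecond precision."""
    dt = dt.astimezone(_UTC)
    return f"{dt:%Y-%m-%dT%H:%M:%S}.{dt.microsecond // 1000:03d}Z"


def quantize_ms(dt: datetime) -> datetime:
    """Round a datetime down to whole milliseconds (serialization grain)."""
    return dt.replace(microsecond=(dt.microsecond // 1000) * 1000)


def _ensure_utc(dt: datetime, what: str) -> datetime:
    if not isinstance(dt, datetime):
        raise SchemaError(f"{what} must be a datetime, got {type(dt).__name__}")
    if dt.tzinfo is None:
        raise SchemaError(f"{what} must be timezone-aware (UTC)")
    return dt.astimezone(_UTC)


# ---------------------------------------------------------------------------
# payload schema
# ---------------------------------------------------------------------------

def validate_payload(sensor_type: SensorType, payload: Mapping) -> dict:
    """Validate and normalize a payload against its sensor type.

    Returns a fresh plain dict; raises :class:`SchemaError` on any
    cross-type or malformed payload.
    """
    if not isinstance(payload, Mapping):
        raise SchemaError(f"payload must be a mapping, got {type(payload).__name__}")
    keys = set(payload)
    st = SensorType(sensor_type)

    def expect(expected: set[str]) -> None:
        if keys != expected:
            raise SchemaError(
                f"payload keys {sorted(keys)} do not match sensor type "
                f"{st.value!r} (expected {sorted(expected)})"
            )

    if st is SensorType.MOTION:
        expect({"room"})
        room = payload["room"]
        if not isinstance(room, str) or not room:
            raise SchemaError("motion payload 'room' must be a non-empty string")
        return {"room": room}
    if st is SensorType.MAT:
        expect({"occupied"})
        occ = payload["occupied"]
        if not isinstance(occ, bool):
            raise SchemaError("mat payload 'occupied' must be a boolean")
        return {"occupied": occ}
    if st is SensorType.DISTANCE:
        expect({"position"})
        pos = payload["position"]
        if pos not in DISTANCE_POSITIONS:
            raise SchemaError(
                f"distance payload 'position' must be one of {sorted(DISTANCE_POSITIONS)}"
            )
        return {"position": pos}
    if st is SensorType.DOOR:
        expect({"state"})
        state = payload["state"]
        if state not in DOOR_STATES:
            raise SchemaError(f"door payload 'state' must be one of {sorted(DOOR_STATES)}")
        return {"state": state}
    if st is SensorType.WEIGHT_SCALE:
        expect({"mass"})
        mass = payload["mass"]
        if isinstance(mass, bool) or not isinstance(mass, (int, float)):
            raise SchemaError("weight_scale payload 'mass' must be a number")
        mass = float(mass)
        if not math.isfinite(mass) or mass <= 0:
            raise SchemaError("weight_scale payload 'mass' must be finite and > 0")
        return {"mass": mass}
    if st is SensorType.SPEAKER:
        expect({"question_id", "answer"})
        qid = payload["question_id"]
        if qid not in QUESTION_IDS:
            raise SchemaError(f"speaker 'question_id' must be one of {QUESTION_IDS}")
        answer = payload["answer"]
        if not isinstance(answer, str):
            raise SchemaError("speaker payload 'answer' must be a string token")
        return {"question_id": qid, "answer": answer}
    raise SchemaError(f"unknown sensor type {sensor_type!r}")  # pragma: no cover


def _payload_key(payload: Mapping) -> tuple:
    return tuple(sorted(payload.items()))


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorEvent:
    """One timestamped firing of one sensor.

    ``payload`` is a tagged variant whose shape is determined by
    ``sensor_type`` (see :func:`validate_payload`).
    """

    sensor_id: str
    sensor_type: SensorType
    timestamp: datetime
    payload: Mapping

    def __post_init__(self) -> None:
        if not isinstance(self.sensor_id, str) or not self.sensor_id:
            raise SchemaError("sensor_id must be a non-empty string")
        try:
            st = SensorType(self.sensor_type)
        except ValueError:
            raise SchemaError(f"unknown sensor type {self.sensor_type!r}") from None
        object.__setattr__(self, "sensor_type", st)
        object.__setattr__(
            self, "timestamp", _ensure_utc(self.timestamp, "event timestamp")
        )
        object.__setattr__(self, "payload", validate_payload(st, self.payload))

    def sort_key(self) -> tuple:
        return (self.timestamp, self.sensor_id, _payload_key(self.payload))

    def dedupe_key(self) -> tuple:
        return (self.timestamp, self.sensor_id, _payload_key(self.payload))


@dataclass(frozen=True)
class ActivityRecord:
    """Ground-truth activity interval ``[start, end)`` with type and location."""

    participant_id: str
    run_id: int
    activity_type: str
    location: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.activity_type not in ACTIVITY_TYPES:
            raise SchemaError(f"unknown activity type {self.activity_type!r}")
        if self.run_id not in (1, 2, 3):
            raise SchemaError(f"run_id must be 1, 2 or 3, got {self.run_id!r}")
        object.__setattr__(self, "start", _ensure_utc(self.start, "activity start"))
        object.__setattr__(self, "end", _ensure_utc(self.end, "activity end"))
        if self.start > self.end:
            raise SchemaError(
                f"activity end {format_timestamp(self.end)} precedes start "
                f"{format_timestamp(self.start)}"
            )

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()

    @property
    def midpoint(self) -> datetime:
        return self.start + timedelta(seconds=self.duration_s / 2.0)


@dataclass(frozen=True)
class EventLog:
    """Canonically sorted, duplicate-free sequence of sensor events."""

    events: tuple[SensorEvent, ...] = ()
    metadata: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=SensorEvent.sort_key))
        seen: set[tuple] = set()
        for ev in events:
            key = ev.dedupe_key()
            if key in seen:
                raise SchemaError(
                    f"duplicate event (timestamp={format_timestamp(ev.timestamp)}, "
                    f"sensor_id={ev.sensor_id!r}, payload={dict(ev.payload)!r})"
                )
            seen.add(key)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "metadata", dict(self.metadata))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[SensorEvent]:
        return iter(self.events)

    def of_type(self, sensor_type: SensorType) -> tuple[SensorEvent, ...]:
        st = SensorType(sensor_type)
        return tuple(ev for ev in self.events if ev.sensor_type is st)


# ---------------------------------------------------------------------------
# event log I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "sensor_id",
    "sensor_type",
    "timestamp",
    "room",
    "occupied",
    "position",
    "state",
    "mass",
    "question_id",
    "answer",
]

_META_PREFIX = "# metadata="


def _event_to_obj(ev: SensorEvent) -> dict:
    return {
        "sensor_id": ev.sensor_id,
        "sensor_type": ev.sensor_type.value,
        "timestamp": format_timestamp(ev.timestamp),
        "payload": dict(ev.payload),
    }


def _event_from_obj(obj: Mapping, where: str) -> SensorEvent:
    for key in ("sensor_id", "sensor_type", "timestamp", "payload"):
        if key not in obj:
            raise ParseError(f"{where}: missing field {key!r}")
    try:
        ts = parse_timestamp(obj["timestamp"])
    except ParseError as exc:
        raise ParseError(f"{where}: {exc}") from None
    try:
        return SensorEvent(
            sensor_id=obj["sensor_id"],
            sensor_type=obj["sensor_type"],
            timestamp=ts,
            payload=obj["payload"],
        )
    except SchemaError as exc:
        raise SchemaError(f"{where}: {exc}") from None


def write_event_log(log: EventLog, path: str | Path, dialect: str = "jsonl") -> None:
    """Write an event log; re-readable to an equal :class:`EventLog`."""
    path = Path(path)
    if dialect == "jsonl":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(json.dumps({"__meta__": dict(log.metadata)}, sort_keys=True) + "\n")
            for ev in log:
                fh.write(json.dumps(_event_to_obj(ev), sort_keys=True) + "\n")
    elif dialect == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            fh.write(_META_PREFIX + json.dumps(dict(log.metadata), sort_keys=True) + "\r\n")
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for ev in log:
                row = {col: "" for col in _CSV_COLUMNS}
                row["sensor_id"] = ev.sensor_id
                row["sensor_type"] = ev.sensor_type.value
                row["timestamp"] = format_timestamp(ev.timestamp)
                for key, value in ev.payload.items():
                    if isinstance(value, bool):
                        row[key] = "true" if value else "false"
                    else:
                        row[key] = str(value)
                writer.writerow(row)
    else:
        raise ParseError(f"unknown dialect {dialect!r} (expected 'jsonl' or 'csv')")


def _csv_row_to_event(row: Mapping, where: str) -> SensorEvent:
    st_raw = row.get("sensor_type", "")
    payload_cols = {
        k: v for k, v in row.items() if k not in ("sensor_id", "sensor_type", "timestamp")
        and v not in ("", None)
    }
    payload: dict = {}
    for key, value in payload_cols.items():
        if key == "occupied":
            if value not in ("true", "false"):
                raise ParseError(f"{where}: 'occupied' must be 'true' or 'false'")
            payload[key] = value == "true"
        elif key == "mass":
            try:
                payload[key] = float(value)
            except ValueError:
                raise ParseError(f"{where}: bad mass {value!r}") from None
        else:
            payload[key] = value
    return _event_from_obj(
        {
            "sensor_id": row.get("sensor_id", ""),
            "sensor_type": st_raw,
            "timestamp": row.get("timestamp", ""),
            "payload": payload,
        },
        where,
    )


def read_event_log(path: str | Path, dialect: str = "jsonl") -> EventLog:
    """Read and validate an event log; returns a canonically sorted log.

    An empty file yields an empty log.  Malformed timestamps raise
    :class:`ParseError` naming the line; payload/type mismatches raise
    :class:`SchemaError`.
    """
    path = Path(path)
    if dialect == "jsonl":
        events: list[SensorEvent] = []
        metadata: dict = {}
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                where = f"{path.name}:{lineno}"
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"{where}: invalid JSON: {exc}") from None
                if "__meta__" in obj:
                    metadata = obj["__meta__"]
                    continue
                events.append(_event_from_obj(obj, where))
        return EventLog(events=tuple(events), metadata=metadata)
    if dialect == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            first = fh.readline()
            metadata = {}
            if first.startswith(_META_PREFIX):
                try:
                    metadata = json.loads(first[len(_META_PREFIX):])
                except json.JSONDecodeError as exc:
                    raise ParseError(f"{path.name}:1: bad metadata line: {exc}") from None
            elif first.strip():
                fh.seek(0)
            elif not first:
                return EventLog()
            reader = csv.DictReader(fh)
            events = []
            for lineno, row in enumerate(reader, start=1):
                events.append(_csv_row_to_event(row, f"{path.name}:row {lineno}"))
        return EventLog(events=tuple(events), metadata=metadata)
    raise ParseError(f"unknown dialect {dialect!r} (expected 'jsonl' or 'csv')")


# ---------------------------------------------------------------------------
# activity log I/O
# ---------------------------------------------------------------------------

_ACTIVITY_COLUMNS = ["participant_id", "run_id", "activity_type", "location", "start", "end"]


def write_activity_log(records: Iterable[ActivityRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ACTIVITY_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.participant_id,
                    rec.run_id,
                    rec.activity_type,
                    rec.location,
                    format_timestamp(rec.start),
                    format_timestamp(rec.end),
                ]
            )


def read_activity_log(path: str | Path) -> tuple[ActivityRecord, ...]:
    path = Path(path)
    records: list[ActivityRecord] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return ()
        missing = set(_ACTIVITY_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path.name}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=1):
            where = f"{path.name}:row {lineno}"
            try:
                run_id = int(row["run_id"])
            except ValueError:
                raise ParseError(f"{where}: run_id {row['run_id']!r} is not an integer") from None
            try:
                start = parse_timestamp(row["start"])
                end = parse_timestamp(row["end"])
            except ParseError as exc:
                raise ParseError(f"{where}: {exc}") from None
            try:
                records.append(
                    ActivityRecord(
                        participant_id=row["participant_id"],
                        run_id=run_id,
                        activity_type=row["activity_type"],
                        location=row["location"],
                        start=start,
                        end=end,
                    )
                )
            except SchemaError as exc:
                raise SchemaError(f"{where}: {exc}") from None
    return tuple(records)


def sort_activities(records: Sequence[ActivityRecord]) -> tuple[ActivityRecord, ...]:
    return tuple(sorted(records, key=lambda r: (r.start, r.end, r.participant_id)))
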