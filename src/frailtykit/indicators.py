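"""Derive frailty indicators from an event log.

Four detectors, one per ambient sensor stream, each built around a single
duration subtraction on a selected pair of event timestamps:

- sedentary bouts: mat vacated minus mat occupied
- stair climbs: absolute gap between the two stair distance sensors,
  with an up/down direction flag
- room presence: first confirmed trigger of the next room's motion sensor
  minus first confirmed trigger of the previous room's
- outings: gap between consecutive entrance-door events, confirmed only
  when longer than 5 minutes with no interior sensor activity in between

``derive_indicators`` dispatches a full log to all four and passes weight
and speaker records through.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Optional, Sequence

from .errors import ContractError, SchemaError, UnknownRoomError
from .event_model import EventLog, SensorEvent, SensorType
from .frailty_scoring import WeightReading

__all__ = [
    "SedentaryBout",
    "StairClimb",
    "RoomPresence",
    "Outing",
    "IndicatorConfig",
    "IndicatorSet",
    "detect_sedentary_bouts",
    "detect_stair_climbs",
    "compute_room_presence",
    "detect_outings",
    "derive_indicators",
]


@dataclass(frozen=True)
class SedentaryBout:
    """One seated interval on the pressure mat; ``s`` in seconds."""

    t_pre_occupied: datetime
    t_unoccupied: Optional[datetime]
    s: Optional[float]
    complete: bool


@dataclass(frozen=True)
class StairClimb:
    """One stair traversal between the two distance sensors."""

    t_distance_sensor1: datetime
    t_distance_sensor2: Optional[datetime]
    sc: Optional[float]
    direction: Optional[str]  # "up" | "down"
    complete: bool


@dataclass(frozen=True)
class RoomPresence:
    """Stay in one room between consecutive confirmed motion transitions."""

    room: str
    t_pre_motion: datetime
    t_next_motion: Optional[datetime]
    r: Optional[float]
    complete: bool


@dataclass(frozen=True)
class Outing:
    """Candidate absence between two consecutive entrance-door events.

    ``o`` is 1 only when the span exceeds the outing threshold and no
    interior (non-door) sensor fired strictly inside it.
    """

    t_pre_door_event: datetime
    t_door_event: datetime
    od: float
    interior_event_count: int
    o: int


def _seconds(later: datetime, earlier: datetime) -> float:
    return (later - earlier).total_seconds()


def _check_stream(events: Sequence[SensorEvent], sensor_type: SensorType, op: str) -> None:
    prev: Optional[datetime] = None
    for ev in events:
        if ev.sensor_type is not sensor_type:
            raise SchemaError(
                f"{op} expects only {sensor_type.value!r} events, got {ev.sensor_type.value!r}"
            )
        if prev is not None and ev.timestamp < prev:
            raise ContractError(f"{op} requires events sorted by timestamp")
        prev = ev.timestamp


def detect_sedentary_bouts(
    mat_events: Sequence[SensorEvent],
    debounce_s: float = 2.0,
    min_bout_s: float = 0.0,
) -> tuple[SedentaryBout, ...]:
    """Pair mat occupied/vacated transitions into sedentary bouts.

    Vacancy flickers shorter than ``debounce_s`` are merged into the
    surrounding bout; completed bouts shorter than ``min_bout_s`` are
    dropped.  A trailing occupancy with no vacate is reported as an open
    bout flagged incomplete.
    """
    _check_stream(mat_events, SensorType.MAT, "detect_sedentary_bouts")
    # state transitions only; repeated same-state firings collapse
    transitions: list[tuple[datetime, bool]] = []
    state: Optional[bool] = None
    for ev in mat_events:
        occupied = ev.payload["occupied"]
        if occupied != state:
            transitions.append((ev.timestamp, occupied))
            state = occupied

    raw: list[tuple[datetime, Optional[datetime]]] = []
    start: Optional[datetime] = None
    for ts, occupied in transitions:
        if occupied and start is None:
            start = ts
        elif not occupied and start is not None:
            raw.append((start, ts))
            start = None
    if start is not None:
        raw.append((start, None))

    merged: list[tuple[datetime, Optional[datetime]]] = []
    for begin, end in raw:
        if merged and merged[-1][1] is not None and _seconds(begin, merged[-1][1]) < debounce_s:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((begin, end))

    bouts: list[SedentaryBout] = []
    for begin, end in merged:
        if end is None:
            bouts.append(SedentaryBout(begin, None, None, complete=False))
            continue
        s = _seconds(end, begin)
        if s < min_bout_s:
            continue
        bouts.append(SedentaryBout(begin, end, s, complete=True))
    return tuple(bouts)


def detect_stair_climbs(
    distance_events: Sequence[SensorEvent],
    pairing_window_s: float = 120.0,
) -> tuple[StairClimb, ...]:
    """Greedily pair stair distance triggers into climbs.

    Each trigger pairs with the earliest opposite-position trigger within
    ``pairing_window_s``; the climb direction is up when the first-step
    sensor fired first.  Unpaired triggers are emitted incomplete.
    """
    _check_stream(distance_events, SensorType.DISTANCE, "detect_stair_climbs")
    climbs: list[StairClimb] = []
    pending: Optional[SensorEvent] = None

    def emit_incomplete(ev: SensorEvent) -> None:
        climbs.append(StairClimb(ev.timestamp, None, None, None, complete=False))

    for ev in distance_events:
        if pending is None:
            pending = ev
            continue
        gap = _seconds(ev.timestamp, pending.timestamp)
        if ev.payload["position"] != pending.payload["position"] and gap <= pairing_window_s:
            direction = "up" if pending.payload["position"] == "first_step" else "down"
            climbs.append(
                StairClimb(pending.timestamp, ev.timestamp, abs(gap), direction, complete=True)
            )
            pending = None
        else:
            emit_incomplete(pending)
            pending = ev
    if pending is not None:
        emit_incomplete(pending)
    return tuple(climbs)


def compute_room_presence(
    motion_events: Sequence[SensorEvent],
    confirm_quiet_s: float = 0.0,
    known_rooms: Optional[Iterable[str]] = None,
) -> tuple[RoomPresence, ...]:
    """Collapse motion triggers into non-overlapping room-presence intervals.

    A trigger in a new room is confirmed as a transition when it is the
    first trigger of a maximal same-room run; with ``confirm_quiet_s > 0``
    a new-room trigger arriving within the quiet period of the previous
    accepted trigger is discarded as PIR re-trigger noise.  Consecutive
    presences tile the span between the first and last confirmed
    transition; the final room yields an open interval flagged incomplete.
    """
    _check_stream(motion_events, SensorType.MOTION, "compute_room_presence")
    rooms = set(known_rooms) if known_rooms is not None else None
    confirmed: list[tuple[datetime, str]] = []
    current_room: Optional[str] = None
    last_accepted: Optional[datetime] = None
    for ev in motion_events:
        room = ev.payload["room"]
        if rooms is not None and room not in rooms:
            raise UnknownRoomError(f"motion event labels unknown room {room!r}")
        if room != current_room:
            if (
                confirm_quiet_s > 0
                and last_accepted is not None
                and _seconds(ev.timestamp, last_accepted) < confirm_quiet_s
            ):
                continue  # unconfirmed re-trigger
            confirmed.append((ev.timestamp, room))
            current_room = room
        last_accepted = ev.timestamp

    presences: list[RoomPresence] = []
    for (t0, room), (t1, _next_room) in zip(confirmed, confirmed[1:]):
        presences.append(RoomPresence(room, t0, t1, _seconds(t1, t0), complete=True))
    if confirmed:
        t_last, room = confirmed[-1]
        presences.append(RoomPresence(room, t_last, None, None, complete=False))
    return tuple(presences)


def detect_outings(
    door_events: Sequence[SensorEvent],
    other_events: Sequence[SensorEvent],
    min_outing_s: float = 300.0,
    coalesce_window_s: float = 0.0,
) -> tuple[Outing, ...]:
    """Score the spans between consecutive door events as outings.

    Interior events are non-door events with timestamps strictly inside the
    open interval between the two door events; the span is a confirmed
    outing (``o = 1``) only if it strictly exceeds ``min_outing_s`` and has
    no interior events.  ``coalesce_window_s > 0`` collapses door-event
    clusters (e.g. an open/close pair) into their first event.
    """
    _check_stream(door_events, SensorType.DOOR, "detect_outings")
    prev_other: Optional[datetime] = None
    for ev in other_events:
        if ev.sensor_type is SensorType.DOOR:
            raise SchemaError("detect_outings: other_events must not contain door events")
        if prev_other is not None and ev.timestamp < prev_other:
            raise ContractError("detect_outings requires sorted other_events")
        prev_other = ev.timestamp

    door_times: list[datetime] = []
    for ev in door_events:
        if (
            coalesce_window_s > 0
            and door_times
            and _seconds(ev.timestamp, door_times[-1]) <= coalesce_window_s
        ):
            continue
        door_times.append(ev.timestamp)

    other_times = [ev.timestamp for ev in other_events]
    outings: list[Outing] = []
    for t0, t1 in zip(door_times, door_times[1:]):
        od = _seconds(t1, t0)
        interior = bisect_left(other_times, t1) - bisect_right(other_times, t0)
        o = 1 if (od > min_outing_s and interior == 0) else 0
        outings.append(Outing(t0, t1, od, interior, o))
    return tuple(outings)


@dataclass(frozen=True)
class IndicatorConfig:
    """Tunable parameters for all four detectors.

    Defaults are inert on clean data: no debouncing side effects, no
    minimum bout length, a generous stair pairing window, and the 5-minute
    outing threshold.
    """

    debounce_s: float = 2.0
    min_bout_s: float = 0.0
    pairing_window_s: float = 120.0
    confirm_quiet_s: float = 0.0
    min_outing_s: float = 300.0
    door_coalesce_s: float = 0.0
    rooms: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class IndicatorSet:
    """All indicators derived from one session's event log."""

    sedentary_bouts: tuple[SedentaryBout, ...] = ()
    stair_climbs: tuple[StairClimb, ...] = ()
    room_presences: tuple[RoomPresence, ...] = ()
    outings: tuple[Outing, ...] = ()
    weights: tuple[WeightReading, ...] = ()
    dialogue_answers: tuple[SensorEvent, ...] = ()
    door_event_times: tuple[datetime, ...] = ()

    def is_empty(self) -> bool:
        return not any(
            (
                self.sedentary_bouts,
                self.stair_climbs,
                self.room_presences,
                self.outings,
                self.weights,
                self.dialogue_answers,
                self.door_event_times,
            )
        )


def derive_indicators(log: EventLog, config: IndicatorConfig = IndicatorConfig()) -> IndicatorSet:
    """Run all detectors over a log; deterministic for fixed input and config."""
    mat = log.of_type(SensorType.MAT)
    distance = log.of_type(SensorType.DISTANCE)
    motion = log.of_type(SensorType.MOTION)
    door = log.of_type(SensorType.DOOR)
    non_door = tuple(ev for ev in log if ev.sensor_type is not SensorType.DOOR)

    weights = tuple(
        WeightReading(ev.timestamp, ev.payload["mass"])
        for ev in log.of_type(SensorType.WEIGHT_SCALE)
    )
    return IndicatorSet(
        sedentary_bouts=detect_sedentary_bouts(
            mat, debounce_s=config.debounce_s, min_bout_s=config.min_bout_s
        ),
        stair_climbs=detect_stair_climbs(distance, pairing_window_s=config.pairing_window_s),
        room_presences=compute_room_presence(
            motion, confirm_quiet_s=config.confirm_quiet_s, known_rooms=config.rooms
        ),
        outings=detect_outings(
            door,
            non_door,
            min_outing_s=config.min_outing_s,
            coalesce_window_s=config.door_coalesce_s,
        ),
        weights=weights,
        dialogue_answers=log.of_type(SensorType.SPEAKER),
        door_event_times=tuple(ev.timestamp for ev in door),
    )
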