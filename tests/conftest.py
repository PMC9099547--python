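"""Shared fixtures and event-construction helpers."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from frailtykit.event_model import SensorEvent, SensorType

BASE = datetime(2022, 3, 1, 10, 0, 0, tzinfo=timezone.utc)


def ts(seconds: float) -> datetime:
    """Timestamp ``seconds`` after the shared base instant (ms-quantized)."""
    dt = BASE + timedelta(seconds=seconds)
    return dt.replace(microsecond=(dt.microsecond // 1000) * 1000)


def mat(seconds: float, occupied: bool, sensor_id: str = "mat_chair") -> SensorEvent:
    return SensorEvent(sensor_id, SensorType.MAT, ts(seconds), {"occupied": occupied})


def motion(seconds: float, room: str) -> SensorEvent:
    return SensorEvent(f"motion_{room}", SensorType.MOTION, ts(seconds), {"room": room})


def distance(seconds: float, position: str) -> SensorEvent:
    sensor_id = "distance_first_step" if position == "first_step" else "distance_last_step"
    return SensorEvent(sensor_id, SensorType.DISTANCE, ts(seconds), {"position": position})


def door(seconds: float, state: str = "opened") -> SensorEvent:
    return SensorEvent("door_entrance", SensorType.DOOR, ts(seconds), {"state": state})


def scale(seconds: float, mass: float) -> SensorEvent:
    return SensorEvent("scale_bathroom", SensorType.WEIGHT_SCALE, ts(seconds), {"mass": mass})


def speaker(seconds: float, question_id: str, answer: str) -> SensorEvent:
    return SensorEvent(
        "speaker_living_room",
        SensorType.SPEAKER,
        ts(seconds),
        {"question_id": question_id, "answer": answer},
    )


@pytest.fixture
def zero_model():
    from frailtykit.homesim import SensorModel

    return SensorModel.zero_noise()


@pytest.fixture
def default_plan():
    from frailtykit.homesim import FloorPlan

    return FloorPlan()


@pytest.fixture
def default_script():
    from frailtykit.homesim import ProtocolScript

    return ProtocolScript()
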