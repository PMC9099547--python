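"""Synthetic single-occupant home sessions and their sensor observations.

``generate_session`` plays out a three-run activity protocol (guided
normal pace, self-paced normal, self-paced slow) producing ground-truth
:class:`~frailtykit.event_model.ActivityRecord` intervals.  ``observe``
corrupts those activities into a :class:`~frailtykit.event_model.EventLog`
through per-sensor observation models (missed detections, latency jitter,
occupancy flicker, token misrecognition), so the full
derivation-plus-validation pipeline runs without any external data.

Randomness is organized as one pseudo-random stream per
(sensor type, participant), keyed from the master seed, so changing one
sensor's noise leaves the other streams untouched.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np

from .agreement import (
    align_for_agreement,
    bland_altman,
    cohens_kappa,
    detection_rate,
    pearson_correlation,
)
from .errors import ConfigError, DataError
from .event_model import (
    ActivityRecord,
    EventLog,
    SensorEvent,
    SensorType,
    quantize_ms,
)
from .exhaustion_dialogue import percent_recognition_agreement
from .indicators import IndicatorConfig, derive_indicators

__all__ = [
    "FloorPlan",
    "SensorModel",
    "RunSpec",
    "ProtocolScript",
    "ObservationTrace",
    "generate_session",
    "observe",
    "observe_detailed",
    "run_validation_study",
]

_SESSION_EPOCH = datetime(2022, 1, 10, 9, 0, 0, tzinfo=timezone.utc)

# run type names
GUIDED_NORMAL = "guided_normal"
SELF_PACED_NORMAL = "self_paced_normal"
SELF_PACED_SLOW = "self_paced_slow"


@dataclass(frozen=True)
class FloorPlan:
    """Room labels and sensor placement for a single-occupant dwelling."""

    rooms: tuple[str, ...] = ("living_room", "dining_room", "kitchen", "bedroom", "bathroom")
    entrance: str = "entrance"
    stairs: str = "stairs"
    mat_sensor_id: str = "mat_chair"
    door_sensor_id: str = "door_entrance"
    scale_sensor_id: str = "scale_bathroom"
    speaker_sensor_id: str = "speaker_living_room"
    distance_first_id: str = "distance_first_step"
    distance_last_id: str = "distance_last_step"

    def __post_init__(self) -> None:
        if len(self.rooms) < 2:
            raise ConfigError("floor plan needs at least two rooms")
        if len(set(self.rooms)) != len(self.rooms):
            raise ConfigError("duplicate room labels in floor plan")

    def motion_sensor_id(self, room: str) -> str:
        if room not in self.rooms:
            raise ConfigError(f"no motion sensor for unknown room {room!r}")
        return f"motion_{room}"


@dataclass(frozen=True)
class SensorModel:
    """Per-sensor observation noise.  All defaults are zero (ideal sensors).

    ``distance_miss_p`` drops a whole climb (both triggers), modeling the
    out-of-range failure mode where a person passes beyond the ultrasonic
    threshold; the other miss probabilities drop individual firings.
    """

    motion_miss_p: float = 0.0
    mat_miss_p: float = 0.0
    distance_miss_p: float = 0.0
    door_miss_p: float = 0.0
    scale_miss_p: float = 0.0
    speaker_miss_p: float = 0.0

    motion_jitter_sd_s: float = 0.0
    mat_jitter_sd_s: float = 0.0
    distance_jitter_sd_s: float = 0.0
    door_jitter_sd_s: float = 0.0

    mat_flicker_per_min: float = 0.0
    motion_flicker_per_min: float = 0.0

    speaker_misrecognize_p: float = 0.0
    weight_noise_sd_kg: float = 0.0
    weight_trend_kg_per_reading: float = 0.0

    # behavioral answer distribution for the simulated dialogue
    availability_yes_p: float = 1.0
    exhaustion_yes_p: float = 0.5
    frequency_weights: tuple[float, float, float] = (0.25, 0.25, 0.5)  # always, sometimes, rare

    def __post_init__(self) -> None:
        for name in (
            "motion_miss_p",
            "mat_miss_p",
            "distance_miss_p",
            "door_miss_p",
            "scale_miss_p",
            "speaker_miss_p",
            "speaker_misrecognize_p",
            "availability_yes_p",
            "exhaustion_yes_p",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value!r}")
        for name in (
            "motion_jitter_sd_s",
            "mat_jitter_sd_s",
            "distance_jitter_sd_s",
            "door_jitter_sd_s",
            "mat_flicker_per_min",
            "motion_flicker_per_min",
            "weight_noise_sd_kg",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if len(self.frequency_weights) != 3 or any(w < 0 for w in self.frequency_weights):
            raise ConfigError("frequency_weights must be three non-negative weights")
        if sum(self.frequency_weights) <= 0:
            raise ConfigError("frequency_weights must not all be zero")

    @classmethod
    def zero_noise(cls) -> "SensorModel":
        return cls()


@dataclass(frozen=True)
class RunSpec:
    """One protocol run: pacing style plus duration multipliers."""

    run_type: str = GUIDED_NORMAL
    sitting_multiplier: float = 1.0
    stair_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.run_type not in (GUIDED_NORMAL, SELF_PACED_NORMAL, SELF_PACED_SLOW):
            raise ConfigError(f"unknown run type {self.run_type!r}")


@dataclass(frozen=True)
class ProtocolScript:
    """Three-run session script; every activity type occurs >= once per run."""

    runs: tuple[RunSpec, ...] = (
        RunSpec(GUIDED_NORMAL),
        RunSpec(SELF_PACED_NORMAL),
        RunSpec(SELF_PACED_SLOW, sitting_multiplier=2.0, stair_multiplier=2.0),
    )
    room_visits_per_run: int = 3
    mean_gap_s: float = 15.0
    break_between_runs_s: float = 120.0

    def __post_init__(self) -> None:
        if len(self.runs) != 3:
            raise ConfigError("a protocol script has exactly three runs")
        if self.room_visits_per_run < 1:
            raise ConfigError("room_visits_per_run must be >= 1")
        if self.mean_gap_s < 0 or self.break_between_runs_s < 0:
            raise ConfigError("gaps must be non-negative")


def _participant_key(participant_id: str) -> int:
    return zlib.crc32(participant_id.encode("utf-8"))


def _rng(seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0xFFFFFFFF, *streams])


def _q(dt: datetime) -> datetime:
    return quantize_ms(dt)


def generate_session(
    plan: FloorPlan,
    script: ProtocolScript,
    seed: int,
    participant_id: str = "p1",
) -> tuple[ActivityRecord, ...]:
    """Simulate one participant's three-run session of ground-truth activities.

    Activities are chronologically ordered and non-overlapping, cover all
    six protocol activity types in every run, and are deterministic for a
    fixed seed.  Guided-run room stays are drawn around two minutes.
    """
    rng = _rng(seed, 0xA11, _participant_key(participant_id))
    t = _SESSION_EPOCH
    records: list[ActivityRecord] = []
    prev_room: Optional[str] = None

    def gap() -> timedelta:
        return timedelta(seconds=2.0 + rng.exponential(script.mean_gap_s))

    for run_index, run in enumerate(script.runs, start=1):
        rooms: list[str] = []
        for _ in range(script.room_visits_per_run):
            choices = [r for r in plan.rooms if r != prev_room]
            room = str(rng.choice(choices))
            rooms.append(room)
            prev_room = room

        def room_duration() -> float:
            if run.run_type == GUIDED_NORMAL:
                return max(30.0, rng.normal(120.0, 10.0))
            return rng.uniform(60.0, 180.0)

        slots: list[tuple[str, str, float]] = []  # (activity_type, location, duration)
        slots.append(("room_presence", rooms[0], room_duration()))
        slots.append(
            ("sitting", plan.rooms[0], max(10.0, rng.normal(60.0, 15.0)) * run.sitting_multiplier)
        )
        if len(rooms) > 1:
            slots.append(("room_presence", rooms[1], room_duration()))
        slots.append(("weight_measuring", "bathroom", rng.uniform(15.0, 40.0)))
        slots.append(
            ("stair_climbing", plan.stairs, max(5.0, rng.normal(14.0, 3.0)) * run.stair_multiplier)
        )
        for room in rooms[2:]:
            slots.append(("room_presence", room, room_duration()))
        slots.append(("exhaustion_report", plan.rooms[0], rng.uniform(20.0, 45.0)))
        slots.append(("entry_exit", plan.entrance, rng.uniform(240.0, 600.0)))

        for activity_type, location, duration in slots:
            start = _q(t)
            end = _q(start + timedelta(seconds=duration))
            records.append(
                ActivityRecord(
                    participant_id=participant_id,
                    run_id=run_index,
                    activity_type=activity_type,
                    location=location,
                    start=start,
                    end=end,
                )
            )
            t = end + gap()
        t += timedelta(seconds=script.break_between_runs_s)

    return tuple(records)


@dataclass(frozen=True)
class ObservationTrace:
    """Pre-noise truth for emitted events; used for recognition/weight scoring."""

    speaker_reference_tokens: tuple[str, ...] = ()
    speaker_recognized_tokens: tuple[str, ...] = ()
    true_masses_kg: tuple[float, ...] = ()
    observed_masses_kg: tuple[float, ...] = ()


def observe_detailed(
    activities: Sequence[ActivityRecord],
    model: SensorModel,
    plan: FloorPlan,
    seed: int,
) -> tuple[EventLog, ObservationTrace]:
    """Corrupt ground-truth activities into sensor events, keeping the trace."""
    if not activities:
        return EventLog(metadata={"seed": int(seed)}), ObservationTrace()
    participant = activities[0].participant_id
    pkey = _participant_key(participant)
    rng_by_type = {
        st: _rng(seed, i + 1, pkey) for i, st in enumerate(SensorType)
    }
    events: list[SensorEvent] = []
    speaker_ref: list[str] = []
    speaker_rec: list[str] = []
    true_masses: list[float] = []
    observed_masses: list[float] = []

    base_mass = float(_rng(seed, 0xB0D4, pkey).normal(70.0, 8.0))
    n_weight_readings = 0
    climb_goes_up = True

    def jittered(ts: datetime, sd: float, rng: np.random.Generator) -> datetime:
        if sd > 0:
            ts = ts + timedelta(seconds=float(rng.normal(0.0, sd)))
        return _q(ts)

    for rec in sorted(activities, key=lambda r: r.start):
        if rec.activity_type == "room_presence":
            rng = rng_by_type[SensorType.MOTION]
            fired = rng.random() >= model.motion_miss_p
            if fired:
                events.append(
                    SensorEvent(
                        plan.motion_sensor_id(rec.location),
                        SensorType.MOTION,
                        jittered(rec.start, model.motion_jitter_sd_s, rng),
                        {"room": rec.location},
                    )
                )
            if model.motion_flicker_per_min > 0 and rec.duration_s > 2:
                k = rng.poisson(model.motion_flicker_per_min * rec.duration_s / 60.0)
                for offset in sorted(rng.uniform(1.0, rec.duration_s - 1.0, size=k)):
                    events.append(
                        SensorEvent(
                            plan.motion_sensor_id(rec.location),
                            SensorType.MOTION,
                            _q(rec.start + timedelta(seconds=float(offset))),
                            {"room": rec.location},
                        )
                    )
        elif rec.activity_type == "sitting":
            rng = rng_by_type[SensorType.MAT]
            for ts, occupied in ((rec.start, True), (rec.end, False)):
                if rng.random() >= model.mat_miss_p:
                    events.append(
                        SensorEvent(
                            plan.mat_sensor_id,
                            SensorType.MAT,
                            jittered(ts, model.mat_jitter_sd_s, rng),
                            {"occupied": occupied},
                        )
                    )
            if model.mat_flicker_per_min > 0 and rec.duration_s > 4:
                k = rng.poisson(model.mat_flicker_per_min * rec.duration_s / 60.0)
                for offset in sorted(rng.uniform(1.0, rec.duration_s - 2.0, size=k)):
                    t0 = rec.start + timedelta(seconds=float(offset))
                    events.append(
                        SensorEvent(plan.mat_sensor_id, SensorType.MAT, _q(t0), {"occupied": False})
                    )
                    events.append(
                        SensorEvent(
                            plan.mat_sensor_id,
                            SensorType.MAT,
                            _q(t0 + timedelta(seconds=0.4)),
                            {"occupied": True},
                        )
                    )
        elif rec.activity_type == "stair_climbing":
            rng = rng_by_type[SensorType.DISTANCE]
            up = climb_goes_up
            climb_goes_up = not climb_goes_up
            if rng.random() >= model.distance_miss_p:  # whole climb in/out of range
                first = (plan.distance_first_id, "first_step")
                last = (plan.distance_last_id, "last_step")
                start_sensor, end_sensor = (first, last) if up else (last, first)
                events.append(
                    SensorEvent(
                        start_sensor[0],
                        SensorType.DISTANCE,
                        jittered(rec.start, model.distance_jitter_sd_s, rng),
                        {"position": start_sensor[1]},
                    )
                )
                events.append(
                    SensorEvent(
                        end_sensor[0],
                        SensorType.DISTANCE,
                        jittered(rec.end, model.distance_jitter_sd_s, rng),
                        {"position": end_sensor[1]},
                    )
                )
        elif rec.activity_type == "entry_exit":
            rng = rng_by_type[SensorType.DOOR]
            for ts, state in ((rec.start, "opened"), (rec.end, "opened")):
                if rng.random() >= model.door_miss_p:
                    events.append(
                        SensorEvent(
                            plan.door_sensor_id,
                            SensorType.DOOR,
                            jittered(ts, model.door_jitter_sd_s, rng),
                            {"state": state},
                        )
                    )
        elif rec.activity_type == "weight_measuring":
            rng = rng_by_type[SensorType.WEIGHT_SCALE]
            true_mass = base_mass + model.weight_trend_kg_per_reading * n_weight_readings
            n_weight_readings += 1
            if rng.random() >= model.scale_miss_p:
                observed = true_mass + (
                    float(rng.normal(0.0, model.weight_noise_sd_kg))
                    if model.weight_noise_sd_kg > 0
                    else 0.0
                )
                observed = max(observed, 1.0)
                events.append(
                    SensorEvent(
                        plan.scale_sensor_id,
                        SensorType.WEIGHT_SCALE,
                        _q(rec.start),
                        {"mass": observed},
                    )
                )
                true_masses.append(true_mass)
                observed_masses.append(observed)
        elif rec.activity_type == "exhaustion_report":
            rng = rng_by_type[SensorType.SPEAKER]
            availability = "yes" if rng.random() < model.availability_yes_p else "no"
            exhaustion = "yes" if rng.random() < model.exhaustion_yes_p else "no"
            weights = np.asarray(model.frequency_weights, dtype=float)
            frequency = str(
                rng.choice(["always", "sometimes", "rare"], p=weights / weights.sum())
            )
            intended = [("availability", availability)]
            if availability == "yes":
                intended += [("exhaustion", exhaustion), ("frequency", frequency)]
            for i, (qid, token) in enumerate(intended):
                if rng.random() < model.speaker_miss_p:
                    continue
                recognized = token
                if rng.random() < model.speaker_misrecognize_p:
                    recognized = "garble"
                offset = rec.duration_s * (0.25 + 0.25 * i)
                events.append(
                    SensorEvent(
                        plan.speaker_sensor_id,
                        SensorType.SPEAKER,
                        _q(rec.start + timedelta(seconds=offset)),
                        {"question_id": qid, "answer": recognized},
                    )
                )
                speaker_ref.append(token)
                speaker_rec.append(recognized)

    log = EventLog(
        events=tuple(events),
        metadata={"session_id": participant, "seed": int(seed)},
    )
    trace = ObservationTrace(
        speaker_reference_tokens=tuple(speaker_ref),
        speaker_recognized_tokens=tuple(speaker_rec),
        true_masses_kg=tuple(true_masses),
        observed_masses_kg=tuple(observed_masses),
    )
    return log, trace


def observe(
    activities: Sequence[ActivityRecord],
    model: SensorModel,
    plan: FloorPlan,
    seed: int,
) -> EventLog:
    """Corrupt ground-truth activities into an :class:`EventLog`."""
    log, _ = observe_detailed(activities, model, plan, seed)
    return log


# ---------------------------------------------------------------------------
# end-to-end validation study
# ---------------------------------------------------------------------------

def _kappa_block(pairs: list[tuple[str, str]]) -> Optional[dict]:
    if not pairs:
        return None
    try:
        res = cohens_kappa(pairs)
    except DataError:
        return None
    return {
        "n_pairs": res.n,
        "p_o": res.p_o,
        "p_e": res.p_e,
        "kappa": res.k,
        "z": res.z,
        "p_value": res.p_value,
    }


def _nan_to_none(value: float) -> Optional[float]:
    return None if value != value else value


def _ba_block(pairs: list[tuple[float, float]]) -> Optional[dict]:
    if len(pairs) < 2:
        return None
    res = bland_altman(pairs)
    return {
        "n": res.n,
        "bias": res.bias,
        "sd": res.sd,
        "lower_loa": res.lower_loa,
        "upper_loa": res.upper_loa,
        "n_outside": res.n_outside,
        "pct_outside": res.pct_outside,
        "agreement": res.agreement,
        "prop_bias_t": _nan_to_none(res.prop_bias_t),
        "prop_bias_p": _nan_to_none(res.prop_bias_p),
    }


def _detection_block(detected: int, undetected: int) -> Optional[dict]:
    if detected + undetected == 0:
        return None
    rate = detection_rate(detected, undetected)
    return {"detected": rate.detected, "undetected": rate.undetected, "pct": rate.pct}


def run_validation_study(
    n_participants: int = 9,
    plan: FloorPlan = FloorPlan(),
    script: ProtocolScript = ProtocolScript(),
    model: SensorModel = SensorModel(),
    seed: int = 0,
    indicator_config: Optional[IndicatorConfig] = None,
    match_tolerance_s: float = 30.0,
    grid_s: float = 1.0,
) -> dict:
    """Simulate a cohort, derive indicators, and score concurrent validity.

    Returns one JSON-serializable report with per-sensor blocks (kappa for
    motion, Bland-Altman plus detection for mat and distance, detection for
    door, percent recognition agreement for the speaker, and correlation
    for the weight scale).  Deterministic for a fixed seed.
    """
    if n_participants < 1:
        raise ConfigError("n_participants must be >= 1")
    if indicator_config is None:
        indicator_config = IndicatorConfig(rooms=plan.rooms)

    room_pairs: list[tuple[str, str]] = []
    sedentary_pairs: list[tuple[float, float]] = []
    climb_pairs: list[tuple[float, float]] = []
    sed_det = sed_undet = 0
    climb_det = climb_undet = 0
    door_det = door_undet = 0
    speaker_rec: list[str] = []
    speaker_ref: list[str] = []
    weight_pairs: list[tuple[float, float]] = []
    n_activities = 0

    for i in range(n_participants):
        participant = f"p{i + 1}"
        activities = generate_session(plan, script, seed=seed, participant_id=participant)
        n_activities += len(activities)
        log, trace = observe_detailed(activities, model, plan, seed=seed)
        derived = derive_indicators(log, indicator_config)
        aligned = align_for_agreement(
            activities, derived, match_tolerance_s=match_tolerance_s, grid_s=grid_s
        )
        room_pairs.extend(aligned.room_pairs)
        sedentary_pairs.extend(aligned.sedentary_pairs)
        climb_pairs.extend(aligned.climb_pairs)
        sed_det += aligned.sedentary_detected
        sed_undet += aligned.sedentary_undetected
        climb_det += aligned.climb_detected
        climb_undet += aligned.climb_undetected
        door_det += aligned.door_detected
        door_undet += aligned.door_undetected
        speaker_rec.extend(trace.speaker_recognized_tokens)
        speaker_ref.extend(trace.speaker_reference_tokens)
        weight_pairs.extend(zip(trace.observed_masses_kg, trace.true_masses_kg))

    speaker_block: Optional[dict] = None
    if speaker_rec:
        speaker_block = {
            "n": len(speaker_rec),
            "percent_agreement": percent_recognition_agreement(speaker_rec, speaker_ref),
        }
    weight_block: Optional[dict] = None
    if len(weight_pairs) >= 3:
        arr = np.asarray(weight_pairs)
        if np.ptp(arr[:, 0]) > 0 and np.ptp(arr[:, 1]) > 0:
            r, p = pearson_correlation(weight_pairs)
            weight_block = {"n": len(weight_pairs), "r": r, "p_value": p}

    return {
        "n_participants": n_participants,
        "n_activities": n_activities,
        "seed": int(seed),
        "motion": {"kappa": _kappa_block(room_pairs)},
        "mat": {
            "bland_altman": _ba_block(sedentary_pairs),
            "detection": _detection_block(sed_det, sed_undet),
        },
        "distance": {
            "bland_altman": _ba_block(climb_pairs),
            "detection": _detection_block(climb_det, climb_undet),
        },
        "door": {"detection": _detection_block(door_det, door_undet)},
        "speaker": speaker_block,
        "weight": weight_block,
    }


def report_to_json(report: dict) -> str:
    """Stable serialization; fixed inputs yield byte-identical output."""
    return json.dumps(report, indent=2, sort_keys=True)
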