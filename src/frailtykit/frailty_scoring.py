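"""Fried-style frailty state from per-criterion flags, plus weight tracking.

Criterion cut-offs for sensor-derived quantities are deliberately
configuration-only: this package validates measurement plumbing, not
clinical thresholds.  The one enabled default is a weight-loss flag at 5%,
consistent with the phenotype model's "shrinking" criterion; every other
threshold defaults to disabled and the criterion reports ``missing``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from datetime import datetime
from typing import TYPE_CHECKING, Optional, Sequence

from .errors import ConfigError, ContractError, SchemaError
from .exhaustion_dialogue import FRAIL_FREQUENCY_TOKENS

if TYPE_CHECKING:  # pragma: no cover
    from .indicators import IndicatorSet

__all__ = [
    "CRITERIA",
    "CriterionFlags",
    "FrailtyState",
    "WeightReading",
    "WeightChange",
    "CriterionThresholds",
    "DEFAULT_STUDY_THRESHOLDS",
    "classify_state",
    "weight_change",
    "flag_criteria",
]

CRITERIA = (
    "sedentary_strength",
    "stair_performance",
    "exhaustion",
    "low_activity",
    "weight_loss",
    "constricted_life_space",
)

_FLAGS = frozenset({"positive", "negative", "missing"})


@dataclass(frozen=True)
class WeightReading:
    """A single smart-scale measurement."""

    timestamp: datetime
    mass_kg: float

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise SchemaError(f"mass must be > 0, got {self.mass_kg!r}")


@dataclass(frozen=True)
class WeightChange:
    """Weight change over one consecutive tracking window."""

    window_index: int
    start: datetime
    end: datetime
    delta_kg: float
    delta_percent: float


@dataclass(frozen=True)
class CriterionFlags:
    """Per-criterion flags; each is ``positive``, ``negative`` or ``missing``."""

    sedentary_strength: str = "missing"
    stair_performance: str = "missing"
    exhaustion: str = "missing"
    low_activity: str = "missing"
    weight_loss: str = "missing"
    constricted_life_space: str = "missing"

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value not in _FLAGS:
                raise SchemaError(
                    f"criterion {f.name!r} flag must be one of {sorted(_FLAGS)}, got {value!r}"
                )

    def as_dict(self) -> dict[str, str]:
        return {name: getattr(self, name) for name in CRITERIA}

    def positive_count(self) -> int:
        return sum(1 for name in CRITERIA if getattr(self, name) == "positive")


@dataclass(frozen=True)
class FrailtyState:
    positive_count: int
    state: str  # non_frail | pre_frail | frail


def classify_state(flags: CriterionFlags) -> FrailtyState:
    """Count positive flags and map to a frailty state.

    0 positives -> non_frail, 1-2 -> pre_frail, 3 or more -> frail.
    ``missing`` never counts as positive.
    """
    count = flags.positive_count()
    if count > len(CRITERIA):
        raise ContractError(f"positive count {count} exceeds criterion count {len(CRITERIA)}")
    if count == 0:
        state = "non_frail"
    elif count <= 2:
        state = "pre_frail"
    else:
        state = "frail"
    return FrailtyState(positive_count=count, state=state)


def weight_change(
    readings: Sequence[WeightReading], window_s: float
) -> tuple[WeightChange, ...]:
    """Earliest-to-latest weight change per consecutive window.

    Readings are partitioned into consecutive windows of ``window_s``
    seconds starting at the first reading; each window holding at least two
    readings yields one change record (delta and percent relative to the
    window's earliest reading).  Fewer than two readings overall -> empty.
    """
    if window_s <= 0:
        raise ConfigError(f"window_s must be > 0, got {window_s!r}")
    ordered = sorted(readings, key=lambda r: r.timestamp)
    if len(ordered) < 2:
        return ()
    t0 = ordered[0].timestamp
    buckets: dict[int, list[WeightReading]] = {}
    for reading in ordered:
        idx = int((reading.timestamp - t0).total_seconds() // window_s)
        buckets.setdefault(idx, []).append(reading)
    changes: list[WeightChange] = []
    for idx in sorted(buckets):
        group = buckets[idx]
        if len(group) < 2:
            continue
        first, last = group[0], group[-1]
        delta = last.mass_kg - first.mass_kg
        changes.append(
            WeightChange(
                window_index=idx,
                start=first.timestamp,
                end=last.timestamp,
                delta_kg=delta,
                delta_percent=100.0 * delta / first.mass_kg,
            )
        )
    return tuple(changes)


@dataclass(frozen=True)
class CriterionThresholds:
    """Cut-offs for turning indicators into criterion flags.

    ``None`` disables a criterion (it reports ``missing``).  The exhaustion
    criterion needs no threshold; it is read from the dialogue answers.

    - ``weight_loss_pct``: positive if weight dropped by at least this
      percentage from the earliest to the latest reading.
    - ``sedentary_total_s``: positive if total completed sedentary time
      exceeds this many seconds.
    - ``stair_mean_s``: positive if the mean completed stair-climb time
      exceeds this many seconds.
    - ``min_room_transitions``: positive if fewer confirmed room
      transitions than this were observed.
    - ``min_outings``: positive if fewer confirmed outings than this.
    """

    weight_loss_pct: Optional[float] = 5.0
    sedentary_total_s: Optional[float] = None
    stair_mean_s: Optional[float] = None
    min_room_transitions: Optional[int] = None
    min_outings: Optional[int] = None
    enabled: Optional[tuple[str, ...]] = None

    _THRESHOLD_OF = {
        "weight_loss": "weight_loss_pct",
        "sedentary_strength": "sedentary_total_s",
        "stair_performance": "stair_mean_s",
        "low_activity": "min_room_transitions",
        "constricted_life_space": "min_outings",
    }

    def enabled_criteria(self) -> tuple[str, ...]:
        if self.enabled is not None:
            for name in self.enabled:
                if name not in CRITERIA:
                    raise ConfigError(f"unknown criterion {name!r}")
                attr = self._THRESHOLD_OF.get(name)
                if attr is not None and getattr(self, attr) is None:
                    raise ConfigError(
                        f"criterion {name!r} is enabled but its threshold {attr!r} is unset"
                    )
            return tuple(self.enabled)
        auto = ["exhaustion"]
        for name, attr in self._THRESHOLD_OF.items():
            if getattr(self, attr) is not None:
                auto.append(name)
        return tuple(auto)


#: Thresholds used by the synthetic validation study scenarios.  These are
#: engineering defaults for exercising the pipeline, not clinical claims.
DEFAULT_STUDY_THRESHOLDS = CriterionThresholds(
    weight_loss_pct=5.0,
    sedentary_total_s=400.0,
    stair_mean_s=20.0,
    min_room_transitions=6,
    min_outings=2,
)


def _flag_exhaustion(indicators: "IndicatorSet") -> str:
    tokens = [
        ev.payload["answer"]
        for ev in indicators.dialogue_answers
        if ev.payload["question_id"] == "frequency"
        and ev.payload["answer"] in ("always", "sometimes", "rare")
    ]
    if not tokens:
        return "missing"
    return "positive" if tokens[-1] in FRAIL_FREQUENCY_TOKENS else "negative"


def flag_criteria(
    indicators: "IndicatorSet", thresholds: CriterionThresholds = CriterionThresholds()
) -> CriterionFlags:
    """Apply configurable thresholds to an indicator set.

    Disabled criteria and criteria without supporting data report
    ``missing``; otherwise the threshold comparison decides positive vs
    negative.  Flags are monotone in the thresholds: loosening a cut-off
    never turns a positive into a negative.
    """
    enabled = thresholds.enabled_criteria()
    flags: dict[str, str] = {}

    if "exhaustion" in enabled:
        flags["exhaustion"] = _flag_exhaustion(indicators)

    if "weight_loss" in enabled:
        ordered = sorted(indicators.weights, key=lambda r: r.timestamp)
        if len(ordered) < 2:
            flags["weight_loss"] = "missing"
        else:
            pct = 100.0 * (ordered[-1].mass_kg - ordered[0].mass_kg) / ordered[0].mass_kg
            flags["weight_loss"] = (
                "positive" if -pct >= thresholds.weight_loss_pct else "negative"
            )

    if "sedentary_strength" in enabled:
        total = sum(b.s for b in indicators.sedentary_bouts if b.complete)
        if not any(b.complete for b in indicators.sedentary_bouts):
            flags["sedentary_strength"] = "missing"
        else:
            flags["sedentary_strength"] = (
                "positive" if total > thresholds.sedentary_total_s else "negative"
            )

    if "stair_performance" in enabled:
        times = [c.sc for c in indicators.stair_climbs if c.complete]
        if not times:
            flags["stair_performance"] = "missing"
        else:
            mean = sum(times) / len(times)
            flags["stair_performance"] = (
                "positive" if mean > thresholds.stair_mean_s else "negative"
            )

    if "low_activity" in enabled:
        n_transitions = len(indicators.room_presences)
        if n_transitions == 0:
            flags["low_activity"] = "missing"
        else:
            flags["low_activity"] = (
                "positive" if n_transitions < thresholds.min_room_transitions else "negative"
            )

    if "constricted_life_space" in enabled:
        if not indicators.door_event_times:
            flags["constricted_life_space"] = "missing"
        else:
            n_outings = sum(o.o for o in indicators.outings)
            flags["constricted_life_space"] = (
                "positive" if n_outings < thresholds.min_outings else "negative"
            )

    return CriterionFlags(**flags)
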