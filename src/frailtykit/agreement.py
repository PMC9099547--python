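"""Concurrent-validity statistics: kappa, Bland-Altman, detection rates.

Compares sensor-derived measurements with ground truth.  Conventions:

- Differences are sensor minus reference.
- The standard deviation of differences uses the n-1 denominator.
- Limits of agreement are bias +/- z * SD (z = 1.96 by default); a value
  is "outside" only strictly beyond a limit, and the two methods agree
  when at most 20% of differences fall outside.
- Proportional bias is the least-squares slope of differences on pair
  means, with a two-sided t test.
- Kappa significance uses the null-hypothesis standard error from the
  confusion-matrix marginals with a normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .errors import DataError
from .event_model import ActivityRecord
from .indicators import IndicatorSet

__all__ = [
    "KappaResult",
    "BlandAltmanResult",
    "DetectionRate",
    "AlignedSamples",
    "cohens_kappa_from_proportions",
    "cohens_kappa",
    "bland_altman",
    "limits_of_agreement",
    "detection_rate",
    "pearson_correlation",
    "align_for_agreement",
    "match_intervals",
    "plot_bland_altman",
]


@dataclass(frozen=True)
class KappaResult:
    p_o: float
    p_e: float
    k: float
    z: Optional[float] = None
    p_value: Optional[float] = None
    n: Optional[int] = None


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    bias: float
    sd: float
    lower_loa: float
    upper_loa: float
    n_outside: int
    pct_outside: float
    agreement: bool
    prop_bias_t: float
    prop_bias_p: float


@dataclass(frozen=True)
class DetectionRate:
    detected: int
    undetected: int
    pct: float


def cohens_kappa_from_proportions(p_o: float, p_e: float) -> KappaResult:
    """Chance-corrected agreement from observed and chance proportions."""
    if not 0.0 <= p_o <= 1.0:
        raise DataError(f"p_o must be in [0, 1], got {p_o!r}")
    if not 0.0 <= p_e <= 1.0:
        raise DataError(f"p_e must be in [0, 1], got {p_e!r}")
    if p_e == 1.0:
        raise DataError("p_e = 1: chance agreement is total, kappa is degenerate")
    return KappaResult(p_o=p_o, p_e=p_e, k=(p_o - p_e) / (1.0 - p_e))


def cohens_kappa(pairs: Sequence[tuple]) -> KappaResult:
    """Cohen's kappa for aligned categorical pairs (sensor, reference).

    Builds the confusion matrix, takes p_o from the trace and p_e from the
    product of marginals, and attaches a z statistic and two-sided p value
    under the null of chance agreement.
    """
    if len(pairs) == 0:
        raise DataError("cohens_kappa requires at least one pair")
    sensor_labels = [a for a, _ in pairs]
    ref_labels = [b for _, b in pairs]
    categories = sorted(set(sensor_labels) | set(ref_labels), key=str)
    if len(categories) < 2:
        raise DataError("single category on both sides: p_e = 1, kappa is degenerate")
    index = {c: i for i, c in enumerate(categories)}
    n = len(pairs)
    table = np.zeros((len(categories), len(categories)), dtype=float)
    for a, b in pairs:
        table[index[a], index[b]] += 1.0
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    k = (p_o - p_e) / (1.0 - p_e)
    # Fleiss null-hypothesis SE from the marginals
    se0_num = p_e + p_e**2 - float(np.sum(row * col * (row + col)))
    se0 = math.sqrt(max(se0_num, 0.0)) / ((1.0 - p_e) * math.sqrt(n))
    if se0 > 0:
        z = k / se0
        p_value = float(2.0 * stats.norm.sf(abs(z)))
    else:  # marginals fully concentrated; no sampling variability under H0
        z = math.inf if k > 0 else (-math.inf if k < 0 else 0.0)
        p_value = 0.0 if k != 0 else 1.0
    return KappaResult(p_o=p_o, p_e=p_e, k=k, z=z, p_value=p_value, n=n)


def limits_of_agreement(bias: float, sd: float, z_mult: float = 1.96) -> tuple[float, float]:
    """(lower, upper) limits: bias -/+ z_mult * sd."""
    return bias - z_mult * sd, bias + z_mult * sd


def bland_altman(
    pairs: Sequence[tuple[float, float]],
    z_mult: float = 1.96,
    outside_threshold_pct: float = 20.0,
) -> BlandAltmanResult:
    """Bland-Altman agreement of continuous (sensor, reference) pairs."""
    if len(pairs) < 2:
        raise DataError(f"bland_altman requires at least 2 pairs, got {len(pairs)}")
    arr = np.asarray(pairs, dtype=float)
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    n = len(diffs)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lower, upper = limits_of_agreement(bias, sd, z_mult)
    n_outside = int(np.sum((diffs < lower) | (diffs > upper)))
    pct_outside = 100.0 * n_outside / n
    if np.ptp(means) > 0 and np.ptp(diffs) >= 0:
        fit = stats.linregress(means, diffs)
        if fit.stderr > 0:
            t_stat = float(fit.slope / fit.stderr)
            p_val = float(fit.pvalue)
        else:
            t_stat, p_val = float("nan"), float("nan")
    else:
        t_stat, p_val = float("nan"), float("nan")
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd=sd,
        lower_loa=lower,
        upper_loa=upper,
        n_outside=n_outside,
        pct_outside=pct_outside,
        agreement=pct_outside <= outside_threshold_pct,
        prop_bias_t=t_stat,
        prop_bias_p=p_val,
    )


def bland_altman_from_moments(
    bias: float,
    sd: float,
    n: int,
    n_outside: int,
    z_mult: float = 1.96,
    outside_threshold_pct: float = 20.0,
) -> BlandAltmanResult:
    """Limits, outside percentage and verdict from summary statistics alone.

    Useful when only the published bias/SD of a comparison is available;
    the proportional-bias regression is undefined without raw pairs.
    """
    if n < 2:
        raise DataError(f"need n >= 2, got {n}")
    if not 0 <= n_outside <= n:
        raise DataError(f"n_outside must be in [0, {n}], got {n_outside}")
    lower, upper = limits_of_agreement(bias, sd, z_mult)
    pct_outside = 100.0 * n_outside / n
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd=sd,
        lower_loa=lower,
        upper_loa=upper,
        n_outside=n_outside,
        pct_outside=pct_outside,
        agreement=pct_outside <= outside_threshold_pct,
        prop_bias_t=float("nan"),
        prop_bias_p=float("nan"),
    )


def detection_rate(detected: int, undetected: int) -> DetectionRate:
    """Percentage of events successfully detected."""
    if detected < 0 or undetected < 0:
        raise DataError("counts must be non-negative")
    total = detected + undetected
    if total == 0:
        raise DataError("detection rate undefined with zero events")
    return DetectionRate(detected=detected, undetected=undetected, pct=100.0 * detected / total)


def pearson_correlation(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Product-moment correlation of (sensor, reference) pairs with 2-sided p."""
    if len(pairs) < 3:
        raise DataError(f"pearson_correlation requires n >= 3, got {len(pairs)}")
    arr = np.asarray(pairs, dtype=float)
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise DataError("pearson correlation undefined with zero variance")
    res = stats.pearsonr(arr[:, 0], arr[:, 1])
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# alignment of derived indicators with ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedSamples:
    """Paired samples and detection tallies for one session comparison."""

    room_pairs: tuple[tuple[str, str], ...]  # (derived label, truth label)
    sedentary_pairs: tuple[tuple[float, float], ...]  # (derived s, truth duration)
    sedentary_detected: int
    sedentary_undetected: int
    sedentary_spurious: int
    climb_pairs: tuple[tuple[float, float], ...]
    climb_detected: int
    climb_undetected: int
    climb_spurious: int
    door_detected: int
    door_undetected: int


UNDETECTED_LABEL = "__undetected__"


def match_intervals(
    truth: Sequence[tuple[float, float]],
    derived: Sequence[tuple[float, float]],
    tolerance_s: float,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """One-to-one matching of (midpoint, duration) intervals.

    Solves the assignment problem minimizing total midpoint distance, then
    keeps only matches within ``tolerance_s``.  Returns (matches,
    unmatched_truth_indices, unmatched_derived_indices).
    """
    if not truth or not derived:
        return [], list(range(len(truth))), list(range(len(derived)))
    cost = np.abs(
        np.asarray([m for m, _ in truth], dtype=float)[:, None]
        - np.asarray([m for m, _ in derived], dtype=float)[None, :]
    )
    rows, cols = linear_sum_assignment(cost)
    matches = [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] <= tolerance_s]
    matched_truth = {i for i, _ in matches}
    matched_derived = {j for _, j in matches}
    return (
        matches,
        [i for i in range(len(truth)) if i not in matched_truth],
        [j for j in range(len(derived)) if j not in matched_derived],
    )


def _epoch(dt: datetime) -> float:
    return dt.timestamp()


def _match_points(
    truth_times: Sequence[float], derived_times: Sequence[float], tolerance_s: float
) -> tuple[int, int]:
    """(detected, undetected) counts for point-event matching."""
    matches, unmatched_truth, _ = match_intervals(
        [(t, 0.0) for t in truth_times],
        [(t, 0.0) for t in derived_times],
        tolerance_s,
    )
    return len(matches), len(unmatched_truth)


def align_for_agreement(
    truth: Sequence[ActivityRecord],
    derived: IndicatorSet,
    match_tolerance_s: float = 30.0,
    grid_s: float = 1.0,
) -> AlignedSamples:
    """Build paired samples comparing derived indicators with ground truth.

    Categorical room pairs are sampled every ``grid_s`` seconds at times
    covered by a ground-truth room-presence interval; interval durations
    (sedentary, stair) are matched one-to-one by midpoint within
    ``match_tolerance_s``; unmatched truth intervals count as undetected
    and unmatched derived ones as spurious.  Door detection matches the
    boundaries of each entry/exit absence against observed door events.
    """
    if not truth:
        raise DataError("align_for_agreement requires non-empty ground truth")
    by_type: dict[str, list[ActivityRecord]] = {}
    for rec in sorted(truth, key=lambda r: r.start):
        by_type.setdefault(rec.activity_type, []).append(rec)

    # --- room labels on a time grid -------------------------------------
    room_truth = by_type.get("room_presence", [])
    derived_rooms = [
        (_epoch(p.t_pre_motion), math.inf if p.t_next_motion is None else _epoch(p.t_next_motion), p.room)
        for p in derived.room_presences
    ]
    room_pairs: list[tuple[str, str]] = []
    for rec in room_truth:
        t = _epoch(rec.start)
        end = _epoch(rec.end)
        while t < end:
            label = UNDETECTED_LABEL
            for begin, stop, room in derived_rooms:
                if begin <= t < stop:
                    label = room
                    break
            room_pairs.append((label, rec.location))
            t += grid_s

    # --- sedentary bout durations ---------------------------------------
    sit_truth = by_type.get("sitting", [])
    bouts = [b for b in derived.sedentary_bouts if b.complete]
    truth_iv = [(_epoch(r.midpoint), r.duration_s) for r in sit_truth]
    derived_iv = [
        (_epoch(b.t_pre_occupied) + b.s / 2.0, b.s) for b in bouts
    ]
    matches, um_truth, um_derived = match_intervals(truth_iv, derived_iv, match_tolerance_s)
    sedentary_pairs = tuple(
        (derived_iv[j][1], truth_iv[i][1]) for i, j in matches
    )

    # --- stair climb durations ------------------------------------------
    climb_truth = by_type.get("stair_climbing", [])
    climbs = [c for c in derived.stair_climbs if c.complete]
    truth_cv = [(_epoch(r.midpoint), r.duration_s) for r in climb_truth]
    derived_cv = [
        ((_epoch(c.t_distance_sensor1) + _epoch(c.t_distance_sensor2)) / 2.0, c.sc)
        for c in climbs
    ]
    cmatches, cum_truth, cum_derived = match_intervals(truth_cv, derived_cv, match_tolerance_s)
    climb_pairs = tuple((derived_cv[j][1], truth_cv[i][1]) for i, j in cmatches)

    # --- door events -----------------------------------------------------
    door_truth_times: list[float] = []
    for rec in by_type.get("entry_exit", []):
        door_truth_times.append(_epoch(rec.start))
        door_truth_times.append(_epoch(rec.end))
    door_detected, door_undetected = _match_points(
        door_truth_times, [_epoch(t) for t in derived.door_event_times], match_tolerance_s
    )

    return AlignedSamples(
        room_pairs=tuple(room_pairs),
        sedentary_pairs=sedentary_pairs,
        sedentary_detected=len(matches),
        sedentary_undetected=len(um_truth),
        sedentary_spurious=len(um_derived),
        climb_pairs=climb_pairs,
        climb_detected=len(cmatches),
        climb_undetected=len(cum_truth),
        climb_spurious=len(cum_derived),
        door_detected=door_detected,
        door_undetected=door_undetected,
    )


def plot_bland_altman(
    pairs: Sequence[tuple[float, float]],
    path,
    z_mult: float = 1.96,
    title: str = "Bland-Altman plot",
) -> BlandAltmanResult:
    """Write a difference-vs-mean plot with bias and limit lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    result = bland_altman(pairs, z_mult=z_mult)
    arr = np.asarray(pairs, dtype=float)
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, alpha=0.7)
    ax.axhline(result.bias, color="purple", label=f"bias = {result.bias:.3f}")
    ax.axhline(result.upper_loa, color="green", ls="--", label=f"upper LoA = {result.upper_loa:.3f}")
    ax.axhline(result.lower_loa, color="green", ls="--", label=f"lower LoA = {result.lower_loa:.3f}")
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (sensor - reference)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return result
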