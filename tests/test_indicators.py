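"""Indicator detectors against brute-force interval oracles.

Each detector's duration is a single subtraction on a selected event pair;
the oracles here re-derive the expected pairings by independent means
(occupancy step functions, explicit index scans, direct rule evaluation)
and the tests enumerate all short event sequences exhaustively.
"""

from __future__ import annotations

import itertools

import pytest

from frailtykit.errors import ContractError, SchemaError, UnknownRoomError
from frailtykit.event_model import EventLog
from frailtykit.indicators import (
    IndicatorConfig,
    compute_room_presence,
    derive_indicators,
    detect_outings,
    detect_sedentary_bouts,
    detect_stair_climbs,
)

from conftest import distance, door, mat, motion, speaker, ts


# ---------------------------------------------------------------------------
# oracles (independent implementations)
# ---------------------------------------------------------------------------

def oracle_sedentary(transitions, debounce_s, min_bout_s):
    """Reference pairing via an occupancy step function.

    ``transitions``: list of (t_seconds, occupied).  Builds maximal occupied
    intervals, closes vacancy gaps shorter than the debounce, then filters.
    Returns (complete_bouts, open_start) with bouts as (start, end) tuples.
    """
    state = None
    intervals = []
    start = None
    for t, occupied in transitions:
        if occupied == state:
            continue
        if occupied:
            start = t
        elif start is not None:
            intervals.append([start, t])
            start = None
        state = occupied
    merged = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < debounce_s:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)
    complete = [(a, b) for a, b in merged if b - a >= min_bout_s]
    open_start = start
    if open_start is not None and merged and open_start - merged[-1][1] < debounce_s:
        # the open bout absorbs the preceding interval, which must then
        # not be reported as complete
        open_start = merged[-1][0]
        complete = [iv for iv in complete if iv[0] != open_start]
    return complete, open_start


def oracle_stairs(triggers, window_s):
    """Explicit index-scan pairing of (t, position) triggers."""
    paired = []
    incomplete = []
    i = 0
    while i < len(triggers):
        if i + 1 < len(triggers):
            t0, p0 = triggers[i]
            t1, p1 = triggers[i + 1]
            if p0 != p1 and t1 - t0 <= window_s:
                paired.append((t0, t1, "up" if p0 == "first_step" else "down"))
                i += 2
                continue
        incomplete.append(triggers[i][0])
        i += 1
    return paired, incomplete


def oracle_outing(t0, t1, interior_times, min_outing_s):
    """Direct rule: confirmed iff span > threshold and no strictly-interior events."""
    od = t1 - t0
    has_interior = any(t0 < t < t1 for t in interior_times)
    return 1 if (od > min_outing_s and not has_interior) else 0


# ---------------------------------------------------------------------------
# sedentary bouts
# ---------------------------------------------------------------------------

class TestSedentaryBouts:
    def test_single_bout_is_plain_subtraction(self):
        bouts = detect_sedentary_bouts([mat(0, True), mat(300, False)])
        assert len(bouts) == 1
        assert bouts[0].s == 300.0
        assert bouts[0].complete

    def test_empty_stream(self):
        assert detect_sedentary_bouts([]) == ()

    def test_flicker_merged_into_one_bout(self):
        events = [mat(0, True), mat(100, False), mat(101, True), mat(400, False)]
        bouts = detect_sedentary_bouts(events, debounce_s=2.0)
        assert len(bouts) == 1
        assert bouts[0].s == 400.0

    def test_trailing_occupied_is_open_bout(self):
        bouts = detect_sedentary_bouts([mat(0, True), mat(50, False), mat(60, True)])
        assert bouts[-1].complete is False
        assert bouts[-1].t_unoccupied is None and bouts[-1].s is None

    def test_min_bout_filter(self):
        events = [mat(0, True), mat(5, False), mat(100, True), mat(200, False)]
        bouts = detect_sedentary_bouts(events, min_bout_s=10.0)
        assert [b.s for b in bouts] == [100.0]

    def test_unsorted_is_contract_error(self):
        with pytest.raises(ContractError):
            detect_sedentary_bouts([mat(10, True), mat(0, False)])

    def test_non_mat_event_rejected(self):
        with pytest.raises(SchemaError):
            detect_sedentary_bouts([motion(0, "kitchen")])

    @pytest.mark.parametrize("debounce_s", [0.0, 2.0, 15.0])
    @pytest.mark.parametrize("min_bout_s", [0.0, 25.0])
    def test_exhaustive_sequences_match_oracle(self, debounce_s, min_bout_s):
        """All occupancy transition sequences up to length 6 on a 10 s grid."""
        for length in range(7):
            for states in itertools.product([True, False], repeat=length):
                times = [10.0 * i for i in range(length)]
                events = [mat(t, occ) for t, occ in zip(times, states)]
                bouts = detect_sedentary_bouts(events, debounce_s, min_bout_s)
                expected_complete, open_start = oracle_sedentary(
                    list(zip(times, states)), debounce_s, min_bout_s
                )
                got_complete = [
                    ((b.t_pre_occupied - ts(0)).total_seconds(), (b.t_unoccupied - ts(0)).total_seconds())
                    for b in bouts
                    if b.complete
                ]
                assert got_complete == expected_complete, (states, debounce_s, min_bout_s)
                open_bouts = [b for b in bouts if not b.complete]
                if open_start is None:
                    assert open_bouts == []
                else:
                    assert len(open_bouts) == 1
                    assert (open_bouts[0].t_pre_occupied - ts(0)).total_seconds() == open_start

    def test_raising_debounce_never_increases_bout_count(self):
        events = [
            mat(0, True), mat(30, False), mat(31, True), mat(90, False),
            mat(95, True), mat(180, False), mat(200, True), mat(260, False),
        ]
        counts = [
            len(detect_sedentary_bouts(events, debounce_s=d)) for d in (0.0, 1.5, 6.0, 25.0, 500.0)
        ]
        assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# stair climbs
# ---------------------------------------------------------------------------

class TestStairClimbs:
    def test_up_climb(self):
        climbs = detect_stair_climbs([distance(0, "first_step"), distance(12.3, "last_step")])
        (climb,) = climbs
        assert climb.sc == pytest.approx(12.3)
        assert climb.direction == "up"
        assert climb.complete

    def test_down_climb_absolute_duration(self):
        (climb,) = detect_stair_climbs([distance(0, "last_step"), distance(9.0, "first_step")])
        assert climb.sc == 9.0
        assert climb.direction == "down"

    def test_out_of_window_trigger_incomplete(self):
        climbs = detect_stair_climbs(
            [distance(0, "first_step"), distance(121.0, "last_step")], pairing_window_s=120.0
        )
        assert [c.complete for c in climbs] == [False, False]

    def test_window_boundary_pairs(self):
        (climb,) = detect_stair_climbs(
            [distance(0, "first_step"), distance(120.0, "last_step")], pairing_window_s=120.0
        )
        assert climb.complete

    def test_non_distance_event_rejected(self):
        with pytest.raises(SchemaError):
            detect_stair_climbs([door(0)])

    @pytest.mark.parametrize("window_s", [10.0, 35.0])
    def test_exhaustive_sequences_match_oracle(self, window_s):
        """All position patterns and gap patterns for sequences of length <= 5."""
        for length in range(6):
            for positions in itertools.product(["first_step", "last_step"], repeat=length):
                for gaps in itertools.product([5.0, 40.0], repeat=max(length - 1, 0)):
                    times = [0.0]
                    for g in gaps:
                        times.append(times[-1] + g)
                    times = times[:length]
                    events = [distance(t, p) for t, p in zip(times, positions)]
                    climbs = detect_stair_climbs(events, pairing_window_s=window_s)
                    expected_pairs, expected_incomplete = oracle_stairs(
                        list(zip(times, positions)), window_s
                    )
                    got_pairs = [
                        (
                            (c.t_distance_sensor1 - ts(0)).total_seconds(),
                            (c.t_distance_sensor2 - ts(0)).total_seconds(),
                            c.direction,
                        )
                        for c in climbs
                        if c.complete
                    ]
                    got_incomplete = [
                        (c.t_distance_sensor1 - ts(0)).total_seconds()
                        for c in climbs
                        if not c.complete
                    ]
                    assert got_pairs == expected_pairs, (positions, gaps, window_s)
                    assert got_incomplete == expected_incomplete

    def test_wider_window_never_loses_complete_climbs(self):
        events = [
            distance(0, "first_step"), distance(12, "last_step"),
            distance(50, "last_step"), distance(95, "first_step"),
            distance(200, "first_step"),
        ]
        counts = [
            sum(c.complete for c in detect_stair_climbs(events, pairing_window_s=w))
            for w in (5.0, 20.0, 60.0, 200.0)
        ]
        assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# room presence
# ---------------------------------------------------------------------------

class TestRoomPresence:
    def test_two_rooms_plain_subtraction(self):
        presences = compute_room_presence([motion(0, "living_room"), motion(240, "kitchen")])
        assert presences[0].room == "living_room"
        assert presences[0].r == 240.0
        assert presences[-1].complete is False

    def test_single_trigger_open_presence(self):
        (presence,) = compute_room_presence([motion(0, "bedroom")])
        assert presence.r is None and not presence.complete

    def test_same_room_runs_collapse(self):
        presences = compute_room_presence(
            [motion(0, "living_room"), motion(10, "living_room"), motion(50, "kitchen"),
             motion(80, "living_room")]
        )
        assert [p.room for p in presences] == ["living_room", "kitchen", "living_room"]
        assert [p.r for p in presences] == [50.0, 30.0, None]

    def test_presences_tile_and_conserve_span(self):
        events = [
            motion(0, "living_room"), motion(7, "living_room"), motion(30, "kitchen"),
            motion(55, "bedroom"), motion(60, "bedroom"), motion(90, "kitchen"),
        ]
        presences = compute_room_presence(events)
        complete = [p for p in presences if p.complete]
        # non-overlap and tiling
        for a, b in zip(complete, complete[1:]):
            assert a.t_next_motion == b.t_pre_motion
        assert sum(p.r for p in complete) == 90.0  # span of confirmed transitions

    def test_unknown_room_rejected(self):
        with pytest.raises(UnknownRoomError):
            compute_room_presence([motion(0, "attic")], known_rooms=["kitchen"])

    def test_quiet_period_suppresses_fast_retrigger(self):
        events = [motion(0, "living_room"), motion(1, "kitchen"), motion(60, "kitchen")]
        presences = compute_room_presence(events, confirm_quiet_s=5.0)
        assert [p.room for p in presences] == ["living_room", "kitchen"]
        assert presences[0].r == 60.0  # kitchen confirmed by the later trigger

    def test_non_motion_event_rejected(self):
        with pytest.raises(SchemaError):
            compute_room_presence([mat(0, True)])


# ---------------------------------------------------------------------------
# outings
# ---------------------------------------------------------------------------

class TestOutings:
    def test_long_quiet_absence_is_outing(self):
        (outing,) = detect_outings([door(0), door(360)], [])
        assert outing.od == 360.0
        assert outing.o == 1

    def test_short_absence_is_not(self):
        (outing,) = detect_outings([door(0), door(240)], [])
        assert outing.o == 0

    def test_boundary_exactly_at_threshold_is_not(self):
        (outing,) = detect_outings([door(0), door(300)], [])
        assert outing.o == 0

    def test_interior_event_cancels(self):
        (outing,) = detect_outings([door(0), door(600)], [motion(300, "kitchen")])
        assert outing.od == 600.0
        assert outing.interior_event_count == 1
        assert outing.o == 0

    def test_events_at_door_instants_do_not_cancel(self):
        (outing,) = detect_outings(
            [door(0), door(600)], [motion(0, "kitchen"), motion(600, "kitchen")]
        )
        assert outing.interior_event_count == 0
        assert outing.o == 1

    def test_exhaustive_enumeration_matches_rule(self):
        """Door/interior sequences up to 6 events total on a 2-minute grid."""
        grid = [0.0, 120.0, 240.0, 360.0, 480.0, 600.0]
        checked = 0
        for n_door in range(2, 5):
            for door_times in itertools.combinations(grid, n_door):
                remaining = [t for t in grid if t not in door_times]
                for n_int in range(0, min(6 - n_door, len(remaining)) + 1):
                    for interior in itertools.combinations(remaining, n_int):
                        door_events = [door(t) for t in door_times]
                        interior_events = [motion(t + 1.0, "kitchen") for t in interior]
                        outings = detect_outings(door_events, interior_events)
                        assert len(outings) == n_door - 1
                        for (t0, t1), outing in zip(
                            itertools.pairwise(door_times), outings
                        ):
                            expected = oracle_outing(
                                t0, t1, [t + 1.0 for t in interior], 300.0
                            )
                            assert outing.o == expected
                            assert outing.od == t1 - t0
                            checked += 1
        assert checked > 100

    def test_zero_threshold_limit_case(self):
        outings = detect_outings([door(0), door(5), door(10)], [], min_outing_s=0.0)
        assert all(o.o == 1 for o in outings)

    def test_coalescing_open_close_pair(self):
        events = [door(0, "opened"), door(2, "closed"), door(400, "opened")]
        outings = detect_outings(events, [], coalesce_window_s=5.0)
        assert len(outings) == 1
        assert outings[0].od == 400.0

    def test_door_in_other_events_rejected(self):
        with pytest.raises(SchemaError):
            detect_outings([door(0), door(10)], [door(5)])


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

class TestDeriveIndicators:
    def test_empty_log(self):
        derived = derive_indicators(EventLog())
        assert derived.is_empty()

    def test_mat_only_log(self):
        log = EventLog(events=(mat(0, True), mat(60, False)))
        derived = derive_indicators(log)
        assert len(derived.sedentary_bouts) == 1
        assert derived.stair_climbs == ()
        assert derived.room_presences == ()
        assert derived.outings == ()

    def test_deterministic(self):
        log = EventLog(
            events=(mat(0, True), mat(60, False), door(100), door(500),
                    speaker(600, "frequency", "rare"))
        )
        assert derive_indicators(log) == derive_indicators(log)

    def test_weights_and_answers_passed_through(self):
        from conftest import scale

        log = EventLog(events=(scale(0, 70.5), speaker(10, "frequency", "always")))
        derived = derive_indicators(log)
        assert derived.weights[0].mass_kg == 70.5
        assert derived.dialogue_answers[0].payload["answer"] == "always"
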