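"""Event response time, compliance rate, PT, utilization, demand, deltas."""

from __future__ import annotations

import math

import numpy as np
import pytest

from emsim.data_prep import AvailabilityTimeline, expand_rosters
from emsim.engine import SimResult, simulate
from emsim.kpi import (
    color_class,
    compare_scenarios,
    demand_profile,
    event_response_time,
    prehospital_time,
    rtcr,
    rtcr_by_community,
    size_bin,
    utilization,
)
from emsim.scenario import (
    Community,
    EventGroup,
    GeoPoint,
    IncidentRecord,
    Priority,
    TimestampChain,
    UnitType,
)
from emsim.synthgen import SynthConfig, gen_scenario


def _chains(rows: dict[str, dict]) -> dict[str, TimestampChain]:
    return {iid: TimestampChain(**fields) for iid, fields in rows.items()}


class TestEventResponseTime:
    def test_four_unit_event_takes_first_call_and_first_arrival(self):
        # first call at t=0; four units arrive after 9/8/14/12 minutes
        chains = _chains({
            "a": {"t_call_dispatch": -60, "t_call_ems": 0, "t_arrive_scene": 9 * 60},
            "b": {"t_call_dispatch": 0, "t_call_ems": 60, "t_arrive_scene": 8 * 60},
            "c": {"t_call_dispatch": 30, "t_call_ems": 120, "t_arrive_scene": 14 * 60},
            "d": {"t_call_dispatch": 60, "t_call_ems": 180, "t_arrive_scene": 12 * 60},
        })
        ev = EventGroup("E1", ("a", "b", "c", "d"))
        assert event_response_time(ev, chains, "PREP_PLUS_TRANSIT") == 8.0

    def test_single_incident_event(self):
        chains = _chains({"a": {"t_call_ems": 600, "t_arrive_scene": 1200}})
        assert event_response_time(EventGroup("E", ("a",)), chains) == 10.0

    def test_variant_difference_equals_start_field_difference(self):
        chains = _chains({
            "a": {"t_call_dispatch": 0, "t_call_ems": 90, "t_depart_base": 150,
                  "t_arrive_scene": 600},
            "b": {"t_call_dispatch": 30, "t_call_ems": 80, "t_depart_base": 200,
                  "t_arrive_scene": 700},
        })
        ev = EventGroup("E", ("a", "b"))
        transit = event_response_time(ev, chains, "TRANSIT_ONLY")
        from_dispatch = event_response_time(ev, chains, "FROM_DISPATCH_CALL")
        # differ by exactly (first t_depart_base - first t_call_dispatch)
        assert from_dispatch - transit == pytest.approx((150 - 0) / 60.0)

    def test_unserved_event_is_infinite(self):
        chains = _chains({"a": {"t_call_ems": 0}})
        assert math.isinf(event_response_time(EventGroup("E", ("a",)), chains))

    def test_missing_start_everywhere_raises(self):
        chains = _chains({"a": {"t_call_ems": 0, "t_arrive_scene": 60}})
        with pytest.raises(ValueError):
            event_response_time(EventGroup("E", ("a",)), chains, "TRANSIT_ONLY")


class TestRtcr:
    def _events(self, rts_min: list[float], mart=15):
        chains = {}
        events = []
        for k, rt in enumerate(rts_min):
            iid = f"i{k}"
            chains[iid] = TimestampChain(t_call_ems=0, t_arrive_scene=int(rt * 60))
            events.append(EventGroup(f"e{k}", (iid,)))
        return events, chains

    def test_all_compliant(self):
        ev, ch = self._events([1, 5, 14.9])
        assert rtcr(ev, ch) == 100.0

    def test_47_events_35_compliant_rounds_to_74_5(self):
        ev, ch = self._events([10.0] * 35 + [20.0] * 12)
        assert rtcr(ev, ch) == 74.5

    def test_boundary_rt_equal_mart_is_compliant(self):
        ev, ch = self._events([15.0])
        assert rtcr(ev, ch, mart_min=15.0) == 100.0

    def test_monotone_in_stricter_mart(self):
        ev, ch = self._events([3, 7, 11, 14, 18, 25])
        vals = [rtcr(ev, ch, mart_min=m, decimals=None) for m in (20, 15, 10, 5)]
        assert vals == sorted(vals, reverse=True)

    def test_invariant_under_event_reordering(self):
        ev, ch = self._events([3, 18, 7, 25, 14])
        assert rtcr(ev, ch) == rtcr(list(reversed(ev)), ch)

    def test_empty_event_set_rejected(self):
        with pytest.raises(ValueError):
            rtcr([], {})


class TestCommunities:
    def _square(self, lon0, lat0, d=0.1):
        return {"type": "Polygon", "coordinates": [[
            [lon0, lat0], [lon0 + d, lat0], [lon0 + d, lat0 + d], [lon0, lat0 + d],
            [lon0, lat0]]]}

    def _setup(self):
        incs, evs, chains = [], [], {}
        spots = [(9.05, 47.05)] * 3 + [(9.25, 47.05)] * 2 + [(10.5, 48.0)]
        for k, (lon, lat) in enumerate(spots):
            iid = f"i{k}"
            incs.append(IncidentRecord(iid, f"e{k}", GeoPoint(lon, lat), Priority.P1,
                                       UnitType.AMBULANCE, TimestampChain(t_call_ems=0)))
            chains[iid] = TimestampChain(t_call_ems=0,
                                         t_arrive_scene=(10 if k % 2 == 0 else 20) * 60)
            evs.append(EventGroup(f"e{k}", (iid,)))
        comms = [Community("C1", "West", self._square(9.0, 47.0)),
                 Community("C2", "East", self._square(9.2, 47.0))]
        return incs, evs, chains, comms

    def test_rows_partition_events_and_unassigned_catches_rest(self):
        incs, evs, chains, comms = self._setup()
        rows = rtcr_by_community(evs, chains, incs, comms)
        assert sum(r.n_events for r in rows) == len(evs)
        by_id = {r.community_id: r for r in rows}
        assert by_id["C1"].n_events == 3 and by_id["C2"].n_events == 2
        assert by_id["UNASSIGNED"].n_events == 1

    def test_single_community_recovers_global_rtcr(self):
        incs, evs, chains, _ = self._setup()
        whole = [Community("ALL", "all", self._square(8.0, 46.0, d=5.0))]
        rows = rtcr_by_community(evs, chains, incs, whole)
        assert len(rows) == 1
        assert rows[0].rtcr == rtcr(evs, chains)

    def test_size_bins_and_colors(self):
        assert size_bin(47) == "10-99"
        assert size_bin(5) == "0-9"
        assert size_bin(2024) == "1000-9999"
        assert color_class(60.0) == "RED"
        assert color_class(74.5) == "ORANGE"
        assert color_class(95.0) == "GREEN"


class TestPrehospitalTime:
    def test_compliant_at_60(self):
        c = TimestampChain(t_call_ems=0, t_arrive_hospital=55 * 60)
        assert prehospital_time(c) == (55.0, True)

    def test_absent_for_non_transport(self):
        assert prehospital_time(TimestampChain(t_call_ems=0, t_depart_scene=900)) is None

    def test_pt_at_least_rt_on_same_chain(self):
        c = TimestampChain(t_call_ems=0, t_arrive_scene=600, t_arrive_hospital=2400)
        rt = (c.t_arrive_scene - c.t_call_ems) / 60
        assert prehospital_time(c)[0] >= rt


class TestUtilization:
    def test_no_missions_zero_utilization(self):
        tl = [AvailabilityTimeline("U1", [(0, 43200)])]
        df, mean = utilization(SimResult(), tl)
        assert df.loc["U1", "utilization_pct"] == 0.0 and mean == 0.0

    def test_three_hours_of_twelve(self):
        tl = [AvailabilityTimeline("U1", [(0, 12 * 3600)])]
        sr = SimResult(unit_busy={"U1": [(0, 3600), (7200, 2 * 3600 + 7200)]})
        df, mean = utilization(sr, tl)
        assert df.loc["U1", "utilization_pct"] == pytest.approx(25.0)
        assert mean == pytest.approx(25.0)

    def test_overtime_is_busy_outside_staffed(self):
        tl = [AvailabilityTimeline("U1", [(0, 3600)])]
        sr = SimResult(unit_busy={"U1": [(1800, 5400)]})  # 30 min over the edge
        df, _ = utilization(sr, tl)
        assert df.loc["U1", "overtime_h"] == pytest.approx(0.5)


class TestDemandProfile:
    def _incident(self, t):
        return IncidentRecord(f"i{t}", f"e{t}", GeoPoint(9, 47), Priority.P1,
                              UnitType.AMBULANCE, TimestampChain(t_call_ems=t))

    def test_uniform_one_per_bin(self):
        incs = [self._incident(900 * b + 10) for b in range(96)]
        curve = demand_profile(incs)
        assert np.allclose(curve["all"].to_numpy(), 1.0)

    def test_mass_conservation(self):
        rng = np.random.default_rng(2)
        incs = [self._incident(int(t)) for t in rng.uniform(0, 3 * 86400, 500)]
        curve = demand_profile(incs)
        n_days = 3
        assert curve["all"].sum() * n_days == pytest.approx(500)


class TestCompareScenarios:
    def test_gain_translates_to_incident_equivalent(self):
        a = {"rtcr": 88.0, "mart_min": 15, "rt_variant": "PREP_PLUS_TRANSIT"}
        b = {"rtcr": 88.7, "mart_min": 15, "rt_variant": "PREP_PLUS_TRANSIT"}
        delta = compare_scenarios(a, b, n_incidents=10_000)
        assert delta["incident_equivalent"] == 70
        assert delta["delta_rtcr_pp"] == pytest.approx(0.7)

    def test_identity_compare_is_all_zero(self):
        a = {"rtcr": 90.0, "mart_min": 15, "rt_variant": "PREP_PLUS_TRANSIT",
             "utilization_mean_pct": 40.0, "overtime_h": 12.0}
        delta = compare_scenarios(a, dict(a), n_incidents=5000)
        assert delta["incident_equivalent"] == 0
        assert delta["delta_utilization_pp"] == 0.0 and delta["delta_overtime_h"] == 0.0

    def test_negative_delta(self):
        a = {"rtcr": 90.0, "mart_min": 15, "rt_variant": "PREP_PLUS_TRANSIT"}
        b = {"rtcr": 88.0, "mart_min": 15, "rt_variant": "PREP_PLUS_TRANSIT"}
        assert compare_scenarios(a, b, 20_000)["incident_equivalent"] == -400

    def test_mismatched_configs_rejected(self):
        a = {"rtcr": 90.0, "mart_min": 15, "rt_variant": "PREP_PLUS_TRANSIT"}
        b = {"rtcr": 90.0, "mart_min": 12, "rt_variant": "PREP_PLUS_TRANSIT"}
        with pytest.raises(ValueError):
            compare_scenarios(a, b, 1000)


def test_adding_a_unit_lowers_mean_utilization_without_hurting_rtcr():
    """The staffing trade-off: more units -> lower utilization, >= RTCR."""
    from emsim.capacity import DAY_SHIFT
    from emsim.scenario import EMSUnit, Shift

    wins = 0
    n_seeds = 6
    for seed in range(n_seeds):
        cfg = SynthConfig(horizon_days=1, annual_volume=20000, n_bases=2,
                          units_day_per_base=1, units_night_per_base=1, seed=300 + seed)
        scn = gen_scenario(cfg, complete_chains=False)
        import copy as _copy
        aug = _copy.deepcopy(scn)
        aug.units.append(EMSUnit("EXTRA", UnitType.AMBULANCE, "B1"))
        aug.shifts.append(Shift("EXTRA", DAY_SHIFT[0], DAY_SHIFT[1], "daily"))

        def measure(s):
            sim = simulate(s, "STANDARD")
            tls = expand_rosters(s.shifts, s.horizon())
            _, mean = utilization(sim, tls)
            value = rtcr(s.events, sim.sim_times, decimals=None)
            return mean, value

        u0, r0 = measure(scn)
        u1, r1 = measure(aug)
        if u1 < u0 and r1 >= r0:
            wins += 1
    assert wins >= n_seeds - 1
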