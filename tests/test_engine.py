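"""Dispatch policies, service timelines, queueing, determinism, oracle equivalence."""

from __future__ import annotations

import copy
import dataclasses

import pytest

from emsim.engine import (
    closest_idle,
    historic_or_closest,
    mco_or_ground,
    mission_durations,
    select_hospital,
    service_timeline,
    simulate,
)
from emsim.reference import derive_assignments
from emsim.scenario import (
    EventGroup,
    GeoPoint,
    Hospital,
    IncidentRecord,
    Priority,
    Scenario,
    TimestampChain,
    UnitType,
)
from emsim.synthgen import SynthConfig, gen_scenario
from emsim.travel import SpeedProfile

from conftest import ORIGIN, burst_scenario, fixed_config, offset_north


class TestPolicyPrimitives:
    def test_closest_idle_argmin(self):
        assert closest_idle([("u1", 7.0), ("u2", 5.0), ("u3", 9.0)]) == ("u2", 5.0)

    def test_closest_idle_tie_by_unit_id(self):
        assert closest_idle([("u2", 5.0), ("u1", 5.0)]) == ("u1", 5.0)

    def test_closest_idle_empty(self):
        assert closest_idle([]) is None

    def test_historic_unit_preferred_even_if_farther(self):
        got = historic_or_closest("u_old", [("u_near", 3.0), ("u_old", 12.0)])
        assert got == ("u_old", 12.0, "HISTORIC")

    def test_historic_busy_falls_back_to_closest(self):
        got = historic_or_closest("u_gone", [("u_near", 3.0), ("u_far", 9.0)])
        assert got == ("u_near", 3.0, "HISTORIC_FALLBACK_CLOSEST")

    def test_no_historic_id_is_plain_closest(self):
        got = historic_or_closest(None, [("u_near", 3.0)])
        assert got == ("u_near", 3.0, "CLOSEST_IDLE")


class TestMcoOrGround:
    def test_mco_wins_when_faster_and_in_range(self):
        got = mco_or_ground([("pep", 25.0)], [("mco", 12.0, 40.0)], range_km=50)
        assert got == ("mco", 12.0, "MCO", False)

    def test_range_gate_blocks_mco(self):
        got = mco_or_ground([("pep", 25.0)], [("mco", 12.0, 60.0)], range_km=50)
        assert got == ("pep", 25.0, "CLOSEST_IDLE", False)

    def test_no_mco_collapses_to_closest_idle(self):
        got = mco_or_ground([("pep1", 9.0), ("pep2", 7.0)], [], range_km=50)
        assert got == ("pep2", 7.0, "CLOSEST_IDLE", False)

    def test_transport_incident_flags_ambulance_pairing(self):
        got = mco_or_ground([], [("mco", 12.0, 40.0)], range_km=50, transport_required=True)
        assert got == ("mco", 12.0, "MCO", True)


class TestSelectHospital:
    PROF = SpeedProfile("p", "GROUND", {"*|*": 60.0}, 1.0, 0.0)
    SCENE = GeoPoint(0, 0)

    def _hospital(self, hid, km, caps):
        return Hospital(hid, GeoPoint(0, km / 111.19494), frozenset(caps))

    def test_capability_gates_nearest(self):
        hs = [self._hospital("near", 5, {"GENERAL"}),
              self._hospital("far", 15, {"GENERAL", "STROKE"})]
        got = select_hospital(self.SCENE, hs, "STROKE", UnitType.AMBULANCE,
                              Priority.P1, self.PROF)
        assert got == (hs[1], False)

    def test_all_capable_takes_nearest(self):
        hs = [self._hospital("a", 12, {"GENERAL"}), self._hospital("b", 4, {"GENERAL"})]
        got = select_hospital(self.SCENE, hs, None, UnitType.AMBULANCE,
                              Priority.P1, self.PROF)
        assert got == (hs[1], False)

    def test_downgrade_to_general_when_no_capable_in_cutoff(self):
        hs = [self._hospital("gen", 5, {"GENERAL"}),
              self._hospital("stroke", 90, {"STROKE"})]
        got = select_hospital(self.SCENE, hs, "STROKE", UnitType.AMBULANCE,
                              Priority.P1, self.PROF, cutoff_min=30)
        assert got == (hs[0], True)

    def test_no_hospitals_returns_none(self):
        assert select_hospital(self.SCENE, [], "STROKE", UnitType.AMBULANCE,
                               Priority.P1, self.PROF) is None


class TestServiceTimeline:
    def _incident(self, transport=False):
        return IncidentRecord(
            "I1", "E1", offset_north(0.05), Priority.P1, UnitType.AMBULANCE,
            TimestampChain(t_call_dispatch=100, t_call_ems=200),
            hospital_id="H1" if transport else None)

    def test_non_transport_chain_and_free_at_scene_departure(self):
        cfg = fixed_config()
        prof = SpeedProfile("p", "GROUND", {"*|*": 60.0}, 1.0, 0.0)
        inc = self._incident()
        # decision at call time; place ~5.56 km north -> 5.56 min -> 334 s
        chain, free_pos, arrive_base = service_timeline(
            inc, 200, ORIGIN, ORIGIN, UnitType.AMBULANCE, prof, cfg)
        assert chain.t_depart_base == 200 + 60            # 1-min turnout
        travel = chain.t_arrive_scene - chain.t_depart_base
        assert travel == pytest.approx(334, abs=1)
        assert chain.t_depart_scene == chain.t_arrive_scene + 1200
        assert chain.t_free == chain.t_depart_scene       # freed on scene departure
        assert chain.t_arrive_hospital is None
        assert free_pos == inc.place
        assert arrive_base == chain.t_free + travel

    def test_transport_adds_hospital_and_handover_legs(self):
        cfg = fixed_config()
        prof = SpeedProfile("p", "GROUND", {"*|*": 60.0}, 1.0, 0.0)
        hosp = Hospital("H1", offset_north(0.10), frozenset({"GENERAL"}))
        inc = self._incident(transport=True)
        chain, free_pos, _ = service_timeline(
            inc, 200, ORIGIN, ORIGIN, UnitType.AMBULANCE, prof, cfg, hospital=hosp)
        leg = chain.t_arrive_hospital - chain.t_depart_scene
        assert leg == pytest.approx(334, abs=1)           # 0.05 deg further north
        assert chain.t_free == chain.t_arrive_hospital + 300  # 5-min handover
        assert free_pos == hosp.location

    def test_chain_ordering_holds_for_random_draws(self):
        cfg = fixed_config(seed=9, service_times={
            "turnout": {"median_min": 1.5, "sigma": 0.4},
            "on_scene": {"median_min": 15, "sigma": 0.5},
            "handover": {"median_min": 10, "sigma": 0.4},
            "transport": {"median_min": 10, "sigma": 0.5}})
        prof = SpeedProfile("p", "GROUND", {"*|*": 60.0}, 1.3, 0.0)
        for k in range(300):
            inc = IncidentRecord(f"I{k}", f"E{k}", offset_north(0.02 + 0.0001 * k),
                                 Priority.P2, UnitType.AMBULANCE,
                                 TimestampChain(t_call_ems=1000 + k),
                                 hospital_id="H1" if k % 2 else None)
            chain, _, _ = service_timeline(inc, 1000 + k, ORIGIN, ORIGIN,
                                           UnitType.AMBULANCE, prof, cfg)
            assert chain.is_ordered(), chain

    def test_durations_deterministic_per_incident(self):
        cfg = fixed_config(seed=5, service_times={
            "turnout": {"median_min": 1.5, "sigma": 0.4},
            "on_scene": {"median_min": 15, "sigma": 0.5},
            "handover": {"median_min": 10, "sigma": 0.4},
            "transport": {"median_min": 10, "sigma": 0.5}})
        inc = self._incident()
        assert mission_durations(cfg, inc) == mission_durations(cfg, inc)

    def test_replay_reuses_historical_durations(self):
        cfg = fixed_config(replay=True)
        inc = self._incident()
        inc.times = TimestampChain(t_call_ems=0, t_depart_base=90,
                                   t_arrive_scene=500, t_depart_scene=1100)
        d = mission_durations(cfg, inc)
        assert d["turnout"] == 90 and d["on_scene"] == 600


class TestSimulate:
    def test_single_incident_trace(self):
        # one unit 10 effective minutes away: RT = turnout + travel
        place = offset_north(10.0 / 111.19494)  # 10 km
        scn = burst_scenario(1, [9.0], place=place, n_units=1)
        scn.speed_profiles = {"default": SpeedProfile("default", "GROUND", {"*|*": 60.0}, 1.0, 0.0)}
        sim = simulate(scn, "STANDARD")
        a = sim.assignments[0]
        assert a.policy == "CLOSEST_IDLE" and a.unit_id == "U1"
        chain = sim.sim_times["I001"]
        rt = (chain.t_arrive_scene - chain.t_call_ems) / 60.0
        assert rt == pytest.approx(11.0, abs=0.05)  # 1 min turnout + 10 min travel

    def test_two_simultaneous_calls_one_unit_queues_second(self):
        scn = burst_scenario(2, [9.0], n_units=1)
        sim = simulate(scn, "STANDARD")
        by_id = sim.assignment_by_incident()
        assert by_id["I001"].queue_delay_min == 0.0
        assert by_id["I002"].queue_delay_min > 0.0
        (iid, enq, deq), = sim.queue_log
        assert iid == "I002"
        # dequeued exactly when U1 is dispatchable again (back at base = t_free here)
        assert deq == sim.sim_times["I001"].t_arrive_base

    def test_unserved_when_required_type_absent(self):
        scn = burst_scenario(1, [9.0])
        scn.incidents[0] = dataclasses.replace(scn.incidents[0],
                                               required_type=UnitType.HELICOPTER)
        sim = simulate(scn, "STANDARD")
        assert sim.assignments[0].policy == "UNSERVED"
        assert sim.assignments[0].unit_id is None

    def test_cutoff_minutes_queue_then_unserved(self):
        scn = burst_scenario(1, [9.0], place=offset_north(0.3))  # ~33 km away
        scn.config.cutoff_min = 15.0
        sim = simulate(scn, "STANDARD")
        assert sim.assignments[0].policy == "UNSERVED"

    def test_determinism_bit_identical(self, synth_small):
        a = simulate(synth_small, "STANDARD")
        b = simulate(copy.deepcopy(synth_small), "STANDARD")
        assert a == b

    def test_no_unit_serves_overlapping_missions(self, synth_small):
        sim = simulate(synth_small, "STANDARD")
        for unit_id, spans in sim.unit_busy.items():
            spans = sorted(spans)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 >= e1, f"{unit_id} double-booked: {(s1, e1)} vs {(s2, e2)}"

    def test_chained_mode_dispatches_from_freeing_position(self):
        # second call at the first scene right when the unit frees up there:
        # CHAINED serves it immediately (travel 0), START_AT_BASE must first return
        place = offset_north(0.09)
        scn = burst_scenario(1, [9.0], place=place, n_units=1)
        first = simulate(scn, "STANDARD").sim_times["I001"]
        t2 = first.t_free + 60
        inc2 = IncidentRecord("I900", "E900", place, Priority.P1, UnitType.AMBULANCE,
                              TimestampChain(t_call_ems=t2))
        scn.incidents.append(inc2)
        scn.events.append(EventGroup("E900", ("I900",)))
        scn.incidents.sort(key=lambda i: i.times.t_call_ems)

        std = simulate(scn, "STANDARD").sim_times["I900"]
        scn2 = copy.deepcopy(scn)
        scn2.config.follow_up_mode = "CHAINED"
        chained = simulate(scn2, "STANDARD").sim_times["I900"]
        assert chained.t_arrive_scene < std.t_arrive_scene
        # zero travel from the freeing position: arrival == depart
        assert chained.t_arrive_scene == chained.t_depart_base


class TestOracleEquivalence:
    def _small(self, seed):
        cfg = SynthConfig(horizon_days=1, annual_volume=25000, n_bases=2,
                          units_day_per_base=1, units_night_per_base=1, seed=seed)
        scn = gen_scenario(cfg, complete_chains=True)
        scn.incidents = scn.incidents[:60]
        keep = {i.incident_id for i in scn.incidents}
        scn.events = [EventGroup(e.event_id, tuple(i for i in e.incident_ids if i in keep))
                      for e in scn.events]
        scn.events = [e for e in scn.events if e.incident_ids]
        return scn

    @pytest.mark.parametrize("seed", range(6))
    def test_engine_matches_literal_policy_walk(self, seed):
        scn = self._small(seed)
        sim = simulate(scn, "STANDARD")
        engine = {a.incident_id: a.unit_id for a in sim.assignments}
        oracle = derive_assignments(scn)
        assert engine == oracle
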