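"""Rule-based discrete-event simulation core.

The engine steps through all incidents in call order. At each decision
epoch it searches for the "best" unit under the dispatch rules: closest
idle for high-priority incidents, historic-unit-else-closest for low
priority, and a dedicated ground-vs-multicopter rule for physician (PEP)
incidents when multicopters are in the fleet. Unserved incidents wait in a
two-class priority queue that is re-evaluated whenever a unit becomes
dispatchable again or comes on shift.

Two modes exist: STANDARD respects rosters and unit availability;
UNLIMITED serves every incident with a fresh unit of the required type from
its best base, which turns the resulting compliance rate into an upper
bound for any roster at the given base locations.
"""

from __future__ import annotations

import heapq
import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_prep import AvailabilityTimeline, expand_rosters
from .scenario import (
    GeoPoint,
    Hospital,
    IncidentRecord,
    Priority,
    Scenario,
    SimConfig,
    TimestampChain,
    UnitType,
    validate_scenario,
)
from .travel import SpeedProfile, default_profiles, haversine_km, travel_minutes

__all__ = [
    "DispatchDecision",
    "SimResult",
    "UnitState",
    "simulate",
    "closest_idle",
    "historic_or_closest",
    "mco_or_ground",
    "select_hospital",
    "service_timeline",
    "mission_durations",
]


@dataclass
class DispatchDecision:
    incident_id: str
    unit_id: Optional[str] = None
    policy: str = "QUEUED"  # CLOSEST_IDLE | HISTORIC | HISTORIC_FALLBACK_CLOSEST | MCO | QUEUED | UNSERVED
    eta_min: Optional[float] = None
    queue_delay_min: float = 0.0
    support_unit_id: Optional[str] = None  # ambulance paired with a multicopter


@dataclass
class UnitState:
    """Mutable runtime state of one unit during a simulation."""

    unit_id: str
    status: str = "OFF_SHIFT"  # OFF_SHIFT IDLE_AT_BASE EN_ROUTE ON_SCENE TRANSPORT AT_HOSPITAL RETURNING
    position: Optional[GeoPoint] = None
    busy_until: Optional[int] = None
    # bookkeeping used by the dispatcher
    ready_at: int = -(1 << 60)        # instant the unit may be dispatched again
    free_at: int = -(1 << 60)         # instant the unit is free (handover/scene end)
    arrive_base_at: int = -(1 << 60)  # instant the unit is back at base
    free_pos: Optional[GeoPoint] = None


@dataclass
class SimResult:
    assignments: list[DispatchDecision] = field(default_factory=list)
    sim_times: dict[str, TimestampChain] = field(default_factory=dict)
    queue_log: list[tuple[str, int, int]] = field(default_factory=list)  # (id, enqueue, dequeue)
    unit_busy: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    mode: str = "STANDARD"
    seed: int = 0
    config: dict = field(default_factory=dict)

    def assignment_by_incident(self) -> dict[str, DispatchDecision]:
        return {a.incident_id: a for a in self.assignments}


# ---------------------------------------------------------------------------
# duration model
# ---------------------------------------------------------------------------

def _incident_rng(cfg: SimConfig, incident_id: str) -> np.random.Generator:
    # per-incident stream: draws do not depend on dispatch order or mode
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, zlib.crc32(incident_id.encode())])


def mission_durations(cfg: SimConfig, incident: IncidentRecord) -> dict[str, int]:
    """Distance-independent duration draws in whole seconds.

    Lognormal around the configured medians. With ``cfg.replay`` the
    historical durations of the incident are reused where present (what
    makes the simulated-historical scenario comparable to history); sampled
    values fill any gaps.
    """
    rng = _incident_rng(cfg, incident.incident_id)
    out: dict[str, int] = {}
    for key in ("turnout", "on_scene", "handover", "transport"):
        p = cfg.service_times[key]
        z = rng.standard_normal()
        minutes = p["median_min"] * math.exp(p["sigma"] * z)
        out[key] = max(0, int(round(minutes * 60.0)))
    if cfg.replay:
        t = incident.times
        if t.t_call_ems is not None and t.t_depart_base is not None:
            out["turnout"] = t.t_depart_base - t.t_call_ems
        if t.t_arrive_scene is not None and t.t_depart_scene is not None:
            out["on_scene"] = t.t_depart_scene - t.t_arrive_scene
        if t.t_arrive_hospital is not None and t.t_free is not None:
            out["handover"] = t.t_free - t.t_arrive_hospital
        if t.t_depart_scene is not None and t.t_arrive_hospital is not None:
            out["transport"] = t.t_arrive_hospital - t.t_depart_scene
    return out


# ---------------------------------------------------------------------------
# policy primitives
# ---------------------------------------------------------------------------

def closest_idle(candidates: Sequence[tuple[str, float]]) -> Optional[tuple[str, float]]:
    """Pick the (unit_id, eta) pair with the smallest ETA; ties go to the
    lexicographically smallest unit id. Candidates are assumed pre-filtered
    for compatibility, availability, cut-offs and region constraints."""
    if not candidates:
        return None
    return min(candidates, key=lambda c: (c[1], c[0]))


def historic_or_closest(
    historic_unit_id: Optional[str],
    candidates: Sequence[tuple[str, float]],
) -> Optional[tuple[str, float, str]]:
    """Low-priority rule: the historic vehicle if available, else closest idle.

    Returns (unit_id, eta, policy) or None.
    """
    if historic_unit_id is not None:
        for uid, eta in candidates:
            if uid == historic_unit_id:
                return (uid, eta, "HISTORIC")
    best = closest_idle(candidates)
    if best is None:
        return None
    policy = "HISTORIC_FALLBACK_CLOSEST" if historic_unit_id is not None else "CLOSEST_IDLE"
    return (best[0], best[1], policy)


def mco_or_ground(
    ground_candidates: Sequence[tuple[str, float]],
    mco_candidates: Sequence[tuple[str, float, float]],  # (unit_id, eta, round_trip_km)
    range_km: float,
    transport_required: bool = False,
) -> Optional[tuple[str, float, str, bool]]:
    """Ground-PEP vs multicopter rule for physician incidents.

    Dispatch the multicopter iff one is available, its round trip
    base->scene->base fits the range, and it beats the ground ETA (or no
    ground physician is available). Multicopters never carry patients, so a
    transport incident additionally needs the closest ambulance; the last
    element of the result flags that.

    Returns (unit_id, eta, policy, needs_ambulance) or None.
    """
    feasible_mco = [(uid, eta) for uid, eta, rt in mco_candidates if rt <= range_km]
    best_mco = closest_idle(feasible_mco)
    best_ground = closest_idle(ground_candidates)
    if best_mco is not None and (best_ground is None or best_mco[1] < best_ground[1]):
        return (best_mco[0], best_mco[1], "MCO", transport_required)
    if best_ground is not None:
        return (best_ground[0], best_ground[1], "CLOSEST_IDLE", False)
    return None


def select_hospital(
    scene: GeoPoint,
    hospitals: Sequence[Hospital],
    required_capability: Optional[str],
    unit_type: UnitType | str,
    priority: Priority | str,
    profile: SpeedProfile,
    cutoff_min: Optional[float] = None,
) -> Optional[tuple[Hospital, bool]]:
    """Nearest capable hospital by travel time from the scene.

    The nature of the emergency gates eligibility: a stroke patient goes to
    the nearest hospital with stroke capability even if a general hospital
    is closer. When no capable hospital exists within the cut-off, the
    nearest GENERAL hospital is used and flagged downgraded.

    Returns (hospital, downgraded) or None when no hospital qualifies.
    """
    if not hospitals:
        return None
    need = required_capability or "GENERAL"

    def eta(h: Hospital) -> float:
        return travel_minutes(scene, h.location, unit_type, priority, profile)

    capable = [h for h in hospitals if need in h.capabilities]
    if cutoff_min is not None:
        capable = [h for h in capable if eta(h) <= cutoff_min]
    if capable:
        return (min(capable, key=lambda h: (eta(h), h.hospital_id)), False)
    general = [h for h in hospitals if "GENERAL" in h.capabilities]
    if general:
        return (min(general, key=lambda h: (eta(h), h.hospital_id)), True)
    return None


# ---------------------------------------------------------------------------
# timeline construction
# ---------------------------------------------------------------------------

def service_timeline(
    incident: IncidentRecord,
    decision_time: int,
    unit_pos: GeoPoint,
    base_pos: GeoPoint,
    unit_type: UnitType | str,
    profile: SpeedProfile,
    cfg: SimConfig,
    hospital: Optional[Hospital] = None,
    durations: Optional[dict[str, int]] = None,
) -> tuple[TimestampChain, GeoPoint, int]:
    """Simulated timestamp chain for one mission.

    Chain: turnout from the dispatch decision, travel to the scene,
    on-scene interval, optional transport and handover legs, then the
    return trip. t_free is the handover end (or scene departure for
    non-transport incidents): the instant that matters for the next
    incident is when the unit is free again, not when it reaches its base.

    Returns (chain, freeing_position, t_arrive_base).
    """
    if durations is None:
        durations = mission_durations(cfg, incident)
    pr = incident.priority
    t_call = incident.times.t_call_ems
    chain = TimestampChain(
        t_call_dispatch=(incident.times.t_call_dispatch
                         if incident.times.t_call_dispatch is not None else t_call),
        t_call_ems=t_call,
    )
    chain.t_depart_base = decision_time + durations["turnout"]
    travel_s = int(round(travel_minutes(unit_pos, incident.place, unit_type, pr, profile) * 60.0))
    chain.t_arrive_scene = chain.t_depart_base + travel_s
    chain.t_depart_scene = chain.t_arrive_scene + durations["on_scene"]
    if incident.requires_transport:
        if hospital is not None:
            tr_s = int(round(travel_minutes(incident.place, hospital.location,
                                            unit_type, pr, profile) * 60.0))
            free_pos = hospital.location
        else:
            tr_s = durations["transport"]
            free_pos = incident.place
        chain.t_arrive_hospital = chain.t_depart_scene + tr_s
        chain.t_free = chain.t_arrive_hospital + durations["handover"]
    else:
        chain.t_free = chain.t_depart_scene
        free_pos = incident.place
    ret_s = int(round(travel_minutes(free_pos, base_pos, unit_type, pr, profile) * 60.0))
    chain.t_arrive_base = chain.t_free + ret_s
    return chain, free_pos, chain.t_arrive_base


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

class _Fleet:
    """Dispatcher-side view of units, rosters and speed profiles."""

    def __init__(self, scenario: Scenario):
        cfg = scenario.config
        self.cfg = cfg
        self.profiles = dict(scenario.speed_profiles) if scenario.speed_profiles else {}
        defaults = default_profiles(cfg.mco_speed_kmh, cfg.mco_overhead_min)
        for pid, prof in defaults.items():
            self.profiles.setdefault(pid, prof)
        bases = scenario.base_by_id()
        self.units = list(scenario.units)
        self.base_of = {u.unit_id: bases[u.base_id] for u in self.units}
        self.unit_by_id = {u.unit_id: u for u in self.units}
        horizon = scenario.horizon()
        self.timelines = {tl.unit_id: tl
                          for tl in expand_rosters(scenario.shifts, horizon)}
        self.state = {
            u.unit_id: UnitState(u.unit_id, position=self.base_of[u.unit_id].location)
            for u in self.units
        }

    def profile_of(self, unit) -> SpeedProfile:
        pid = unit.speed_profile_id
        if pid in self.profiles:
            return self.profiles[pid]
        if unit.type in (UnitType.MCO, UnitType.HELICOPTER):
            return self.profiles["air"]
        return self.profiles["default"]

    def staffed_at(self, unit_id: str, t: int) -> bool:
        tl = self.timelines.get(unit_id)
        return tl.staffed_at(t) if tl else False

    def dispatchable(self, unit_id: str, t: int) -> bool:
        return self.state[unit_id].ready_at <= t and self.staffed_at(unit_id, t)

    def position(self, unit_id: str, t: int) -> GeoPoint:
        st = self.state[unit_id]
        if self.cfg.follow_up_mode == "CHAINED" and st.free_pos is not None and t < st.arrive_base_at:
            return st.free_pos
        return self.base_of[unit_id].location

    def eta_min(self, unit_id: str, place: GeoPoint, priority, t: int) -> float:
        unit = self.unit_by_id[unit_id]
        return travel_minutes(self.position(unit_id, t), place, unit.type, priority,
                              self.profile_of(unit))

    def passes_cutoffs(self, unit_id: str, incident: IncidentRecord, t: int) -> bool:
        cfg = self.cfg
        if cfg.cutoff_km is not None:
            if haversine_km(self.position(unit_id, t), incident.place) > cfg.cutoff_km:
                return False
        if cfg.cutoff_min is not None:
            if self.eta_min(unit_id, incident.place, incident.priority, t) > cfg.cutoff_min:
                return False
        return True

    def region_ok(self, unit_id: str, incident: IncidentRecord) -> bool:
        if not self.cfg.enforce_regions or incident.organization == "external":
            return True
        return self.base_of[unit_id].region == incident.organization

    def candidates(self, incident: IncidentRecord, t: int,
                   unit_type: UnitType) -> list[tuple[str, float]]:
        out = []
        for u in self.units:
            if u.type != unit_type:
                continue
            if not self.dispatchable(u.unit_id, t):
                continue
            if not self.region_ok(u.unit_id, incident):
                continue
            if not self.passes_cutoffs(u.unit_id, incident, t):
                continue
            out.append((u.unit_id, self.eta_min(u.unit_id, incident.place, incident.priority, t)))
        return out


def _try_dispatch(fleet: _Fleet, scenario: Scenario, incident: IncidentRecord,
                  t: int) -> Optional[DispatchDecision]:
    """Apply the dispatch policy at epoch ``t``; None means stay queued."""
    cfg = fleet.cfg
    rtype = incident.required_type
    has_mco = any(u.type == UnitType.MCO for u in fleet.units)

    if rtype == UnitType.PEP_CAR and has_mco:
        ground = fleet.candidates(incident, t, UnitType.PEP_CAR)
        mcos = []
        for uid, eta in fleet.candidates(incident, t, UnitType.MCO):
            base = fleet.base_of[uid]
            rt_km = 2.0 * haversine_km(base.location, incident.place)
            mcos.append((uid, eta, rt_km))
        pick = mco_or_ground(ground, mcos, cfg.mco_range_km,
                             transport_required=incident.requires_transport)
        if pick is None:
            return None
        uid, eta, policy, needs_amb = pick
        dec = DispatchDecision(incident.incident_id, uid, policy, eta)
        if needs_amb:
            amb = closest_idle(fleet.candidates(incident, t, UnitType.AMBULANCE))
            if amb is not None:
                dec.support_unit_id = amb[0]
        return dec

    cands = fleet.candidates(incident, t, rtype)
    if incident.priority.value in cfg.high_priority:
        best = closest_idle(cands)
        if best is None:
            return None
        return DispatchDecision(incident.incident_id, best[0], "CLOSEST_IDLE", best[1])
    pick = historic_or_closest(incident.historic_unit_id, cands)
    if pick is None:
        return None
    return DispatchDecision(incident.incident_id, pick[0], pick[2], pick[1])


def _commit(fleet: _Fleet, scenario: Scenario, incident: IncidentRecord,
            dec: DispatchDecision, t: int, result: SimResult,
            wake: list, seq_counter: list[int]) -> None:
    cfg = fleet.cfg
    unit = fleet.unit_by_id[dec.unit_id]
    st = fleet.state[dec.unit_id]
    profile = fleet.profile_of(unit)
    pos = fleet.position(dec.unit_id, t)
    base = fleet.base_of[dec.unit_id]

    hospital = None
    if incident.requires_transport and scenario.hospitals:
        hid = incident.hospital_id
        by_id = scenario.hospital_by_id()
        if hid is not None and hid in by_id:
            hospital = by_id[hid]
        else:
            picked = select_hospital(incident.place, scenario.hospitals,
                                     incident.required_capability, unit.type,
                                     incident.priority, profile, cfg.cutoff_min)
            hospital = picked[0] if picked else None
    chain, free_pos, arrive_base = service_timeline(
        incident, t, pos, base.location, unit.type, profile, cfg, hospital)

    dec.queue_delay_min = (t - incident.times.t_call_ems) / 60.0
    result.assignments.append(dec)
    result.sim_times[incident.incident_id] = chain
    result.unit_busy.setdefault(dec.unit_id, []).append((t, chain.t_free))

    st.free_at = chain.t_free
    st.arrive_base_at = arrive_base
    st.free_pos = free_pos
    st.busy_until = chain.t_free
    st.ready_at = chain.t_free if cfg.follow_up_mode == "CHAINED" else arrive_base
    seq_counter[0] += 1
    heapq.heappush(wake, (st.ready_at, seq_counter[0]))

    if dec.support_unit_id is not None:
        # ambulance paired with a multicopter: mirrors the mission window
        sup = fleet.state[dec.support_unit_id]
        sup_base = fleet.base_of[dec.support_unit_id]
        sup_ret = int(round(travel_minutes(free_pos, sup_base.location,
                                           UnitType.AMBULANCE, incident.priority,
                                           fleet.profile_of(fleet.unit_by_id[dec.support_unit_id]))
                            * 60.0))
        sup.free_at = chain.t_free
        sup.free_pos = free_pos
        sup.arrive_base_at = chain.t_free + sup_ret
        sup.ready_at = sup.free_at if cfg.follow_up_mode == "CHAINED" else sup.arrive_base_at
        result.unit_busy.setdefault(dec.support_unit_id, []).append((t, chain.t_free))
        seq_counter[0] += 1
        heapq.heappush(wake, (sup.ready_at, seq_counter[0]))


def _simulate_standard(scenario: Scenario) -> SimResult:
    cfg = scenario.config
    fleet = _Fleet(scenario)
    result = SimResult(mode="STANDARD", seed=cfg.seed, config=cfg.to_dict())

    fleet_types = {u.type for u in fleet.units}
    incidents = sorted(scenario.incidents,
                       key=lambda i: (i.times.t_call_ems, i.incident_id))
    wake: list[tuple[int, int]] = []
    seq = [0]
    # shift starts are natural re-evaluation epochs
    for tl in fleet.timelines.values():
        for s, _ in tl.intervals:
            seq[0] += 1
            heapq.heappush(wake, (s, seq[0]))

    queue: list[tuple[int, int, str, int]] = []  # (class, t_call, incident_id, enqueue_t)
    by_id = {i.incident_id: i for i in incidents}
    idx = 0
    n = len(incidents)

    def queue_sort_key(entry):
        return (entry[0], entry[1], entry[2])

    while idx < n or queue:
        t_call = incidents[idx].times.t_call_ems if idx < n else None
        t_wake = wake[0][0] if wake else None
        if t_call is None and t_wake is None:
            break
        if t_wake is None or (t_call is not None and t_call <= t_wake):
            t = t_call
        else:
            t = t_wake
        while wake and wake[0][0] <= t:
            heapq.heappop(wake)
        # enqueue calls arriving now
        while idx < n and incidents[idx].times.t_call_ems == t:
            inc = incidents[idx]
            idx += 1
            compatible = inc.required_type in fleet_types or (
                inc.required_type == UnitType.PEP_CAR and UnitType.MCO in fleet_types)
            if not compatible:
                result.assignments.append(
                    DispatchDecision(inc.incident_id, None, "UNSERVED"))
                continue
            cls = 0 if inc.priority.value in cfg.high_priority else 1
            queue.append((cls, inc.times.t_call_ems, inc.incident_id, t))
        # serve the queue: high priority first, FIFO within class
        queue.sort(key=queue_sort_key)
        remaining = []
        for entry in queue:
            cls, t_c, iid, t_enq = entry
            inc = by_id[iid]
            dec = _try_dispatch(fleet, scenario, inc, t)
            if dec is None:
                remaining.append(entry)
            else:
                _commit(fleet, scenario, inc, dec, t, result, wake, seq)
                if t > t_c:
                    result.queue_log.append((iid, t_enq, t))
        queue = remaining
        if queue and idx >= n and not wake:
            # nothing will ever free up for these incidents
            for cls, t_c, iid, t_enq in queue:
                result.assignments.append(DispatchDecision(iid, None, "UNSERVED"))
                result.queue_log.append((iid, t_enq, -1))
            queue = []
    return result


def _simulate_unlimited(scenario: Scenario) -> SimResult:
    cfg = scenario.config
    result = SimResult(mode="UNLIMITED", seed=cfg.seed, config=cfg.to_dict())
    profiles = dict(scenario.speed_profiles) if scenario.speed_profiles else {}
    defaults = default_profiles(cfg.mco_speed_kmh, cfg.mco_overhead_min)
    for pid, prof in defaults.items():
        profiles.setdefault(pid, prof)
    # per required type, the set of profiles used by real fleet units
    prof_ids_by_type: dict[UnitType, set[str]] = {}
    for u in scenario.units:
        prof_ids_by_type.setdefault(u.type, set()).add(u.speed_profile_id)

    hospitals = scenario.hospitals
    hosp_by_id = scenario.hospital_by_id()
    for inc in scenario.incidents:
        rtype = inc.required_type
        pids = prof_ids_by_type.get(rtype) or (
            {"air"} if rtype in (UnitType.MCO, UnitType.HELICOPTER) else {"default"})
        best = None  # (eta, base_id, profile_id, profile, base)
        for b in scenario.bases:
            for pid in sorted(pids):
                prof = profiles.get(pid, defaults["default"])
                eta = travel_minutes(b.location, inc.place, rtype, inc.priority, prof)
                if best is None or (eta, b.base_id, pid) < (best[0], best[1], best[2]):
                    best = (eta, b.base_id, pid, prof, b)
        eta, base_id, pid, prof, base = best
        t = inc.times.t_call_ems
        hospital = None
        if inc.requires_transport and hospitals:
            if inc.hospital_id is not None and inc.hospital_id in hosp_by_id:
                hospital = hosp_by_id[inc.hospital_id]
            else:
                picked = select_hospital(inc.place, hospitals, inc.required_capability,
                                         rtype, inc.priority, prof, cfg.cutoff_min)
                hospital = picked[0] if picked else None
        chain, _, _ = service_timeline(inc, t, base.location, base.location,
                                       rtype, prof, cfg, hospital)
        result.assignments.append(
            DispatchDecision(inc.incident_id, f"virtual@{base_id}", "CLOSEST_IDLE", eta))
        result.sim_times[inc.incident_id] = chain
    return result


def simulate(scenario: Scenario, mode: str = "STANDARD") -> SimResult:
    """Run the rule-based DES on a validated scenario.

    Deterministic given (scenario, config, seed). Incidents whose required
    unit type never exists in the fleet are marked UNSERVED, not raised.
    """
    violations = validate_scenario(scenario)
    if violations:
        head = "; ".join(v.message for v in violations[:5])
        raise ValueError(f"scenario invalid ({len(violations)} violations): {head}")
    if mode == "UNLIMITED":
        return _simulate_unlimited(scenario)
    if mode != "STANDARD":
        raise ValueError(f"unknown mode {mode!r}")
    return _simulate_standard(scenario)
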