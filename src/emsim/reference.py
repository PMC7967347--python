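"""Naive re-derivation of dispatch assignments, used for validation.

This module re-derives the per-incident assignments of a STANDARD
simulation by brute force: it walks candidate decision instants in
increasing time, and at each instant scans *every* unit and applies the
policy definitions literally (closest idle for high priority; historic
vehicle else closest idle for low priority), with no event queue, no
caching and no shortcuts. It shares only the input contracts with the
engine (travel model, duration draws, roster expansion); the dispatch
logic is written independently so the two can disagree.

Intended for validation on small fleets; complexity is O(instants x units x
queue) and it does not implement multicopter pairing.
"""

from __future__ import annotations

from typing import Optional

from .data_prep import expand_rosters
from .engine import mission_durations, service_timeline
from .scenario import Scenario, UnitType
from .travel import default_profiles, haversine_km, travel_minutes

__all__ = ["derive_assignments"]


def derive_assignments(scenario: Scenario) -> dict[str, Optional[str]]:
    """Map incident_id -> serving unit_id (None if unserved), START_AT_BASE.

    Literal policy walk: at every candidate instant (call times, instants
    at which a unit becomes dispatchable, shift starts), waiting incidents
    are considered high-priority-first, oldest-call-first, and each scans
    the full fleet for eligible units.
    """
    cfg = scenario.config
    if cfg.follow_up_mode != "START_AT_BASE":
        raise ValueError("reference dispatcher only covers START_AT_BASE")
    bases = scenario.base_by_id()
    profiles = dict(scenario.speed_profiles) if scenario.speed_profiles else {}
    for pid, p in default_profiles(cfg.mco_speed_kmh, cfg.mco_overhead_min).items():
        profiles.setdefault(pid, p)

    def profile_of(unit):
        if unit.speed_profile_id in profiles:
            return profiles[unit.speed_profile_id]
        return profiles["air" if unit.type in (UnitType.MCO, UnitType.HELICOPTER) else "default"]

    timelines = {tl.unit_id: tl for tl in
                 expand_rosters(scenario.shifts, scenario.horizon())}
    ready_at = {u.unit_id: -(10 ** 15) for u in scenario.units}
    hosp_by_id = scenario.hospital_by_id()

    def eligible(unit, inc, t):
        if unit.type != inc.required_type:
            return False
        tl = timelines.get(unit.unit_id)
        if tl is None or not tl.staffed_at(t):
            return False
        if ready_at[unit.unit_id] > t:
            return False
        if cfg.enforce_regions and inc.organization != "external":
            if bases[unit.base_id].region != inc.organization:
                return False
        pos = bases[unit.base_id].location
        if cfg.cutoff_km is not None and haversine_km(pos, inc.place) > cfg.cutoff_km:
            return False
        if cfg.cutoff_min is not None:
            if travel_minutes(pos, inc.place, unit.type, inc.priority,
                              profile_of(unit)) > cfg.cutoff_min:
                return False
        return True

    def pick(inc, t):
        cands = []
        for unit in scenario.units:
            if eligible(unit, inc, t):
                eta = travel_minutes(bases[unit.base_id].location, inc.place,
                                     unit.type, inc.priority, profile_of(unit))
                cands.append((eta, unit.unit_id, unit))
        if not cands:
            return None
        if inc.priority.value not in cfg.high_priority and inc.historic_unit_id is not None:
            for eta, uid, unit in cands:
                if uid == inc.historic_unit_id:
                    return (eta, uid, unit)
        return min(cands, key=lambda c: (c[0], c[1]))

    served: dict[str, Optional[str]] = {}
    fleet_types = {u.type for u in scenario.units}
    waiting = []
    for inc in sorted(scenario.incidents, key=lambda i: (i.times.t_call_ems, i.incident_id)):
        if inc.required_type in fleet_types:
            waiting.append(inc)
        else:
            served[inc.incident_id] = None  # no such unit exists at all

    while waiting:
        instants = {i.times.t_call_ems for i in waiting}
        instants |= {r for r in ready_at.values()}
        for tl in timelines.values():
            instants |= {s for s, _ in tl.intervals}
        progressed = False
        for t in sorted(instants):
            batch = [i for i in waiting if i.times.t_call_ems <= t]
            batch.sort(key=lambda i: (0 if i.priority.value in cfg.high_priority else 1,
                                      i.times.t_call_ems, i.incident_id))
            for inc in batch:
                hit = pick(inc, t)
                if hit is None:
                    continue
                eta, uid, unit = hit
                base = bases[unit.base_id]
                hospital = hosp_by_id.get(inc.hospital_id) if inc.hospital_id else None
                if inc.requires_transport and scenario.hospitals and hospital is None:
                    from .engine import select_hospital
                    res = select_hospital(inc.place, scenario.hospitals,
                                          inc.required_capability, unit.type,
                                          inc.priority, profile_of(unit), cfg.cutoff_min)
                    hospital = res[0] if res else None
                chain, _, arrive_base = service_timeline(
                    inc, t, base.location, base.location, unit.type,
                    profile_of(unit), cfg, hospital,
                    durations=mission_durations(cfg, inc))
                ready_at[uid] = arrive_base
                served[inc.incident_id] = uid
                waiting = [w for w in waiting if w.incident_id != inc.incident_id]
                progressed = True
                break  # re-derive instants from scratch after every assignment
            if progressed:
                break
        if not progressed:
            for inc in waiting:
                served[inc.incident_id] = None
            break
    return served
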