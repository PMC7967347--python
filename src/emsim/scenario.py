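"""Domain model for EMS simulation scenarios.

A *scenario* is the single merged data structure the simulator operates on:
incidents (one per dispatched unit), events (the real-world emergencies that
group incidents), the EMS fleet with its bases and rosters, optional
hospitals with their clinical capabilities, optional community polygons, and
the simulation configuration.

All regulatory symbols live here and nowhere else: the maximum allowed
response time (MART, 15 min default), the required compliance rate
(MARTCR, 90 % default), the three response-time variants, and the
priority scheme (P1..P3 primary incidents, S1..S3 transports; P1/P2 are
treated as high priority by default).

Time is represented internally as integer seconds since the scenario epoch;
files use ISO-8601. Coordinates are WGS84 lon/lat degrees.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

__all__ = [
    "Priority",
    "UnitType",
    "GeoPoint",
    "TimestampChain",
    "IncidentRecord",
    "EventGroup",
    "Base",
    "EMSUnit",
    "Shift",
    "Hospital",
    "SimConfig",
    "Scenario",
    "Community",
    "Violation",
    "validate_scenario",
    "CHAIN_FIELDS",
    "RT_VARIANTS",
    "CAPABILITIES",
    "DEFAULT_MART_MIN",
    "DEFAULT_MARTCR_PCT",
    "DEFAULT_HIGH_PRIORITY",
    "ROSTER_RESOLUTION_S",
]

#: Regulatory defaults (Swiss convention): 15-minute maximum allowed
#: response time, to be met for 90 % of events.
DEFAULT_MART_MIN = 15.0
DEFAULT_MARTCR_PCT = 90.0

#: Rosters must be resolved at least every quarter of an hour.
ROSTER_RESOLUTION_S = 900

#: The three response-time start conventions in use across regions:
#: transit only (Bavaria), preparation+transit (Switzerland), and from the
#: call to the dispatch center (Baden-Wuerttemberg).
RT_VARIANTS = ("TRANSIT_ONLY", "PREP_PLUS_TRANSIT", "FROM_DISPATCH_CALL")

#: Tracer-diagnosis capability codes for hospitals, plus GENERAL.
CAPABILITIES = ("TBI", "STROKE", "POLYTRAUMA", "STEMI", "SCD", "SEPSIS", "GENERAL")


class Priority(str, enum.Enum):
    """Dispatch priority. P* are emergency incidents, S* transports."""

    P1 = "P1"  # traffic privileges, suspected impairment of vital functions
    P2 = "P2"  # emergency without suspected impairment of vital functions
    P3 = "P3"  # preordered incident
    S1 = "S1"  # relocation with suspected impairment of vital functions
    S2 = "S2"  # time-critical relocation
    S3 = "S3"  # preordered relocation


DEFAULT_HIGH_PRIORITY = frozenset({"P1", "P2"})


class UnitType(str, enum.Enum):
    AMBULANCE = "AMBULANCE"          # RTW
    TRANSPORT = "TRANSPORT"          # KTW
    PEP_CAR = "PEP_CAR"              # ground vehicle of the emergency physician
    HELICOPTER = "HELICOPTER"
    MCO = "MCO"                      # multicopter; delivers a physician, never transports
    FIRST_RESPONDER = "FIRST_RESPONDER"


#: Multicopters (limited payload) and first responders cannot transport patients.
TRANSPORT_CAPABLE = {
    UnitType.AMBULANCE: True,
    UnitType.TRANSPORT: True,
    UnitType.PEP_CAR: False,
    UnitType.HELICOPTER: True,
    UnitType.MCO: False,
    UnitType.FIRST_RESPONDER: False,
}


@dataclass(frozen=True)
class GeoPoint:
    """WGS84 position in degrees."""

    lon: float
    lat: float

    def valid(self) -> bool:
        return -180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0


#: Canonical order of the per-incident timestamps. Present fields must be
#: non-decreasing in this order.
CHAIN_FIELDS = (
    "t_call_dispatch",
    "t_call_ems",
    "t_depart_base",
    "t_arrive_scene",
    "t_depart_scene",
    "t_arrive_hospital",
    "t_free",
    "t_arrive_base",
)


@dataclass
class TimestampChain:
    """Seconds since scenario epoch; any field after t_call_ems may be missing.

    t_call_dispatch: call reaches the dispatch center.
    t_call_ems: the EMS unit is alerted (call to EMS).
    t_free: the unit is free for the next incident (handover end, or scene
    departure for non-transport incidents) -- the crucial instant for
    availability, distinct from t_arrive_base.
    """

    t_call_dispatch: Optional[int] = None
    t_call_ems: Optional[int] = None
    t_depart_base: Optional[int] = None
    t_arrive_scene: Optional[int] = None
    t_depart_scene: Optional[int] = None
    t_arrive_hospital: Optional[int] = None
    t_free: Optional[int] = None
    t_arrive_base: Optional[int] = None

    def present(self) -> list[tuple[str, int]]:
        return [(f, getattr(self, f)) for f in CHAIN_FIELDS if getattr(self, f) is not None]

    def ordering_violations(self) -> list[tuple[str, str]]:
        """Pairs of (earlier_field, later_field) whose values are out of order."""
        out = []
        pres = self.present()
        for (fa, va), (fb, vb) in zip(pres, pres[1:]):
            if vb < va:
                out.append((fa, fb))
        return out

    def is_ordered(self) -> bool:
        return not self.ordering_violations()


@dataclass
class IncidentRecord:
    """One EMS-unit call: a single unit's involvement in an emergency."""

    incident_id: str
    event_id: str
    place: GeoPoint
    priority: Priority
    required_type: UnitType
    times: TimestampChain
    historic_unit_id: Optional[str] = None
    hospital_id: Optional[str] = None
    required_capability: Optional[str] = None
    organization: str = "own"
    discontinued: bool = False

    @property
    def requires_transport(self) -> bool:
        """Whether the incident includes a patient-transport leg."""
        return self.hospital_id is not None or self.times.t_arrive_hospital is not None


@dataclass
class EventGroup:
    """One real-world emergency; may trigger several incidents."""

    event_id: str
    incident_ids: tuple[str, ...]


@dataclass
class Base:
    base_id: str
    location: GeoPoint
    name: str = ""
    region: str = ""


@dataclass
class EMSUnit:
    """A vehicle plus its crew, available for bounded shift periods."""

    unit_id: str
    type: UnitType
    base_id: str
    speed_profile_id: str = "default"


@dataclass
class Shift:
    """Roster entry. For recurrence 'daily'/'weekly', start/end are seconds
    from midnight (end may exceed 86400 for shifts crossing midnight); for
    'once' they are absolute seconds since the scenario epoch. weekdays is a
    set of ints (0=epoch weekday reference Monday) used for 'weekly'."""

    unit_id: str
    start: int
    end: int
    recurrence: str = "daily"  # once | daily | weekly
    weekdays: frozenset[int] = frozenset()


@dataclass
class Hospital:
    hospital_id: str
    location: GeoPoint
    capabilities: frozenset[str] = frozenset({"GENERAL"})


@dataclass
class Community:
    """Administrative unit used for spatial KPI aggregation. geometry is a
    GeoJSON-style dict (Polygon/MultiPoint) or None when only a centroid is
    known."""

    community_id: str
    name: str = ""
    geometry: Optional[dict] = None
    centroid: Optional[GeoPoint] = None


def default_service_times() -> dict:
    """Distance-independent mission-duration model: lognormal with the given
    median (minutes) and log-sd sigma. transport is the fallback used when no
    hospital table is supplied."""
    return {
        "turnout": {"median_min": 1.5, "sigma": 0.35},
        "on_scene": {"median_min": 15.0, "sigma": 0.45},
        "handover": {"median_min": 10.0, "sigma": 0.40},
        "transport": {"median_min": 10.0, "sigma": 0.50},
    }


@dataclass
class SimConfig:
    """Simulation configuration; every KPI report echoes it."""

    mart_min: float = DEFAULT_MART_MIN
    martcr_target_pct: float = DEFAULT_MARTCR_PCT
    rt_variant: str = "PREP_PLUS_TRANSIT"
    high_priority: frozenset[str] = DEFAULT_HIGH_PRIORITY
    cutoff_km: Optional[float] = None
    cutoff_min: Optional[float] = None
    enforce_regions: bool = False
    follow_up_mode: str = "START_AT_BASE"  # START_AT_BASE | CHAINED
    seed: int = 0
    epsilon_pp: float = 1.0
    epoch: str = "2024-01-01T00:00:00"  # a Monday; anchors rosters and ISO times
    replay: bool = False                 # reuse historical durations per incident
    count_unserved: bool = True          # unserved incidents count as non-compliant
    service_times: dict = field(default_factory=default_service_times)
    mco_speed_kmh: float = 100.0
    mco_range_km: float = 50.0
    mco_overhead_min: float = 1.0        # takeoff + landing

    def to_dict(self) -> dict:
        d = asdict(self)
        d["high_priority"] = sorted(self.high_priority)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "high_priority" in d:
            d["high_priority"] = frozenset(d["high_priority"])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class Scenario:
    """The merged structure of incidents, events, units, rosters, bases,
    hospitals and configuration on which all simulations run."""

    incidents: list[IncidentRecord] = field(default_factory=list)
    events: list[EventGroup] = field(default_factory=list)
    units: list[EMSUnit] = field(default_factory=list)
    shifts: list[Shift] = field(default_factory=list)
    bases: list[Base] = field(default_factory=list)
    hospitals: list[Hospital] = field(default_factory=list)
    communities: list[Community] = field(default_factory=list)
    config: SimConfig = field(default_factory=SimConfig)
    speed_profiles: dict = field(default_factory=dict)
    area: Optional[dict] = None  # optional GeoJSON polygon bounding the region

    def base_by_id(self) -> dict[str, Base]:
        return {b.base_id: b for b in self.bases}

    def unit_by_id(self) -> dict[str, EMSUnit]:
        return {u.unit_id: u for u in self.units}

    def hospital_by_id(self) -> dict[str, Hospital]:
        return {h.hospital_id: h for h in self.hospitals}

    def incident_by_id(self) -> dict[str, IncidentRecord]:
        return {i.incident_id: i for i in self.incidents}

    def horizon(self, pad_s: int = 2 * 86400) -> tuple[int, int]:
        """(start, end) seconds covering all calls plus a settling pad."""
        calls = [i.times.t_call_ems for i in self.incidents if i.times.t_call_ems is not None]
        if not calls:
            return (0, 86400)
        return (min(0, min(calls)), max(calls) + pad_s)


@dataclass(frozen=True)
class Violation:
    """One invariant violation; data, never an exception."""

    entity: str     # e.g. "incident", "unit", "shift"
    entity_id: str
    field: str
    rule: str       # short machine-readable rule name
    message: str


def _violation(entity, entity_id, fld, rule, message) -> Violation:
    return Violation(entity, str(entity_id), fld, rule, message)


def validate_scenario(s: Scenario, resolution_s: int = ROSTER_RESOLUTION_S) -> list[Violation]:
    """Check every structural invariant; total (never raises on well-typed input).

    Returns an empty list iff the scenario is valid.
    """
    v: list[Violation] = []
    base_ids = {b.base_id for b in s.bases}
    unit_ids = {u.unit_id for u in s.units}
    hosp_ids = {h.hospital_id for h in s.hospitals}

    # -- bases / units / shifts / hospitals -------------------------------
    if len(base_ids) != len(s.bases):
        v.append(_violation("base", "*", "base_id", "unique", "duplicate base_id"))
    for b in s.bases:
        if not b.location.valid():
            v.append(_violation("base", b.base_id, "location", "wgs84_range",
                                f"coordinates out of range: {b.location}"))
    if len(unit_ids) != len(s.units):
        v.append(_violation("unit", "*", "unit_id", "unique", "duplicate unit_id"))
    for u in s.units:
        if u.base_id not in base_ids:
            v.append(_violation("unit", u.unit_id, "base_id", "ref_base",
                                f"unit {u.unit_id} references unknown base {u.base_id}"))
    for k, sh in enumerate(s.shifts):
        sid = f"{sh.unit_id}#{k}"
        if sh.unit_id not in unit_ids:
            v.append(_violation("shift", sid, "unit_id", "ref_unit",
                                f"shift references unknown unit {sh.unit_id}"))
        if sh.end <= sh.start:
            v.append(_violation("shift", sid, "end", "end_after_start",
                                f"shift end {sh.end} <= start {sh.start}"))
        elif (sh.end - sh.start) % resolution_s != 0:
            v.append(_violation("shift", sid, "end", "grid_aligned",
                                f"shift duration not a multiple of {resolution_s}s"))
        if sh.recurrence not in ("once", "daily", "weekly"):
            v.append(_violation("shift", sid, "recurrence", "enum",
                                f"unknown recurrence {sh.recurrence!r}"))
    if len(hosp_ids) != len(s.hospitals):
        v.append(_violation("hospital", "*", "hospital_id", "unique", "duplicate hospital_id"))
    for h in s.hospitals:
        if not h.capabilities:
            v.append(_violation("hospital", h.hospital_id, "capabilities", "nonempty",
                                "hospital has empty capability set"))
        if not h.location.valid():
            v.append(_violation("hospital", h.hospital_id, "location", "wgs84_range",
                                f"coordinates out of range: {h.location}"))
        for c in h.capabilities:
            if c not in CAPABILITIES:
                v.append(_violation("hospital", h.hospital_id, "capabilities", "enum",
                                    f"unknown capability {c!r}"))

    # -- incidents --------------------------------------------------------
    inc_ids = [i.incident_id for i in s.incidents]
    if len(set(inc_ids)) != len(inc_ids):
        seen, dups = set(), set()
        for i in inc_ids:
            (dups if i in seen else seen).add(i)
        for d in sorted(dups):
            v.append(_violation("incident", d, "incident_id", "unique",
                                f"duplicate incident_id {d}"))
    area_poly = None
    if s.area is not None:
        try:
            from shapely.geometry import shape
            area_poly = shape(s.area)
        except Exception:
            v.append(_violation("scenario", "*", "area", "geometry", "invalid area polygon"))
    prev_call = None
    for inc in s.incidents:
        if not inc.place.valid():
            v.append(_violation("incident", inc.incident_id, "place", "wgs84_range",
                                f"coordinates out of range: {inc.place}"))
        for fa, fb in inc.times.ordering_violations():
            v.append(_violation("incident", inc.incident_id, fb, "chain_order",
                                f"{fb} earlier than {fa}"))
        if inc.times.t_call_ems is None:
            v.append(_violation("incident", inc.incident_id, "t_call_ems", "required",
                                "missing call time"))
        else:
            if prev_call is not None and inc.times.t_call_ems < prev_call:
                v.append(_violation("incident", inc.incident_id, "t_call_ems", "sorted",
                                    "incidents not sorted by t_call_ems"))
            prev_call = inc.times.t_call_ems
        if inc.hospital_id is not None and inc.hospital_id not in hosp_ids and s.hospitals:
            v.append(_violation("incident", inc.incident_id, "hospital_id", "ref_hospital",
                                f"unknown hospital {inc.hospital_id}"))
        if inc.required_capability is not None and inc.required_capability not in CAPABILITIES:
            v.append(_violation("incident", inc.incident_id, "required_capability", "enum",
                                f"unknown capability {inc.required_capability!r}"))
        if area_poly is not None and inc.organization != "external":
            from shapely.geometry import Point
            if not area_poly.covers(Point(inc.place.lon, inc.place.lat)):
                v.append(_violation("incident", inc.incident_id, "place", "inside_area",
                                    "incident outside scenario area and not 'external'"))

    # -- events partition the incidents -----------------------------------
    ev_ids = [e.event_id for e in s.events]
    if len(set(ev_ids)) != len(ev_ids):
        v.append(_violation("event", "*", "event_id", "unique", "duplicate event_id"))
    counted: dict[str, int] = {}
    for e in s.events:
        if not e.incident_ids:
            v.append(_violation("event", e.event_id, "incident_ids", "nonempty",
                                "event group is empty"))
        for iid in e.incident_ids:
            counted[iid] = counted.get(iid, 0) + 1
    inc_set = set(inc_ids)
    for iid, n in counted.items():
        if n > 1:
            v.append(_violation("event", iid, "incident_ids", "partition",
                                f"incident {iid} appears in {n} event groups"))
        if iid not in inc_set:
            v.append(_violation("event", iid, "incident_ids", "ref_incident",
                                f"event references unknown incident {iid}"))
    if s.events:
        for iid in inc_set - set(counted):
            v.append(_violation("incident", iid, "event_id", "partition",
                                f"incident {iid} belongs to no event group"))

    # -- config ------------------------------------------------------------
    c = s.config
    if not c.mart_min > 0:
        v.append(_violation("config", "*", "mart_min", "positive", "MART must be > 0"))
    if not (0 < c.martcr_target_pct <= 100):
        v.append(_violation("config", "*", "martcr_target_pct", "range",
                            "compliance target must be in (0, 100]"))
    if not c.epsilon_pp > 0:
        v.append(_violation("config", "*", "epsilon_pp", "positive", "epsilon must be > 0"))
    if c.rt_variant not in RT_VARIANTS:
        v.append(_violation("config", "*", "rt_variant", "enum",
                            f"unknown RT variant {c.rt_variant!r}"))
    if c.follow_up_mode not in ("START_AT_BASE", "CHAINED"):
        v.append(_violation("config", "*", "follow_up_mode", "enum",
                            f"unknown follow-up mode {c.follow_up_mode!r}"))
    return v
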