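"""Travel-time estimation for ground and air EMS units.

EMS vehicles drive faster than civilian traffic, so travel times come from
unit-type- and priority-specific *effective speeds* applied to great-circle
distance with a detour factor (ground) or straight-line flight plus a fixed
takeoff/landing overhead (air). An external routing backend (e.g. an OSRM
server speaking the ``table``/``route`` API) can be plugged in; the default
closed-form model needs no network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

from .scenario import GeoPoint, Priority, UnitType

__all__ = [
    "EARTH_RADIUS_KM",
    "SpeedProfile",
    "RoutingBackend",
    "default_profiles",
    "haversine_km",
    "travel_minutes",
    "isochrone_bands",
    "static_coverage",
    "OUTSIDE",
]

EARTH_RADIUS_KM = 6371.0

#: Band index returned for points beyond the last isochrone threshold.
OUTSIDE = -1

# Default effective speeds (km/h) at highest priority; lower priorities
# (no lights/siren or scheduled runs) drive at 85 % of these. These are
# configuration, not constants: every KPI report records the profile used.
_BASE_SPEED_KMH = {
    "AMBULANCE": 62.0,
    "TRANSPORT": 55.0,
    "PEP_CAR": 70.0,
    "HELICOPTER": 180.0,
    "MCO": 100.0,
    "FIRST_RESPONDER": 55.0,
}
_LOW_PRIORITY_FACTOR = 0.85


@dataclass(frozen=True)
class SpeedProfile:
    """Effective-speed model for one class of units.

    speeds_kmh maps (unit_type, priority) -> km/h; the wildcard "*" may be
    used on either key. detour_factor inflates great-circle distance for the
    road network (ground only); overhead_min is a fixed per-trip surcharge
    (air: takeoff + landing).
    """

    profile_id: str = "default"
    mode: str = "GROUND"  # GROUND | AIR
    speeds_kmh: dict = field(default_factory=dict)
    detour_factor: float = 1.3
    overhead_min: float = 0.0

    def __post_init__(self):
        if self.detour_factor < 1.0:
            raise ValueError("detour_factor must be >= 1")
        if self.overhead_min < 0:
            raise ValueError("overhead_min must be >= 0")

    def speed_for(self, unit_type: UnitType | str, priority: Priority | str) -> float:
        ut = unit_type.value if isinstance(unit_type, UnitType) else str(unit_type)
        pr = priority.value if isinstance(priority, Priority) else str(priority)
        for key in ((ut, pr), (ut, "*"), ("*", pr), ("*", "*")):
            k = "|".join(key)
            if k in self.speeds_kmh:
                v = float(self.speeds_kmh[k])
                if v <= 0:
                    raise ValueError(f"non-positive speed for {k}")
                return v
        raise KeyError(f"speed profile {self.profile_id!r} has no entry for ({ut}, {pr})")

    def to_dict(self) -> dict:
        return {
            "profile_id": self.profile_id,
            "mode": self.mode,
            "speeds_kmh": dict(self.speeds_kmh),
            "detour_factor": self.detour_factor,
            "overhead_min": self.overhead_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeedProfile":
        return cls(
            profile_id=d.get("profile_id", "default"),
            mode=d.get("mode", "GROUND"),
            speeds_kmh=dict(d.get("speeds_kmh", {})),
            detour_factor=float(d.get("detour_factor", 1.3)),
            overhead_min=float(d.get("overhead_min", 0.0)),
        )


def _full_speed_table(factor: float = 1.0) -> dict:
    table = {}
    for ut, base in _BASE_SPEED_KMH.items():
        for pr in ("P1", "P2", "P3", "S1", "S2", "S3"):
            f = 1.0 if pr == "P1" else _LOW_PRIORITY_FACTOR
            table[f"{ut}|{pr}"] = base * f * factor
    return table


def default_profiles(mco_speed_kmh: float = 100.0, mco_overhead_min: float = 1.0) -> dict:
    """The shipped ground and air profiles, keyed by profile id."""
    ground = SpeedProfile("default", "GROUND", _full_speed_table(), 1.3, 0.0)
    air_speeds = {f"{ut}|*": _BASE_SPEED_KMH[ut] for ut in ("HELICOPTER",)}
    air_speeds["MCO|*"] = mco_speed_kmh
    air_speeds["*|*"] = mco_speed_kmh
    air = SpeedProfile("air", "AIR", air_speeds, 1.0, mco_overhead_min)
    return {"default": ground, "air": air}


class RoutingBackend(Protocol):
    """Minimal routing interface: durations in seconds for civilian traffic.

    ``table`` mirrors the OSRM table service; implementations may call an
    OSRM HTTP endpoint or any other router.
    """

    def table(self, origins: Sequence[GeoPoint], destinations: Sequence[GeoPoint]) -> list[list[float]]:
        ...


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance on a sphere of mean radius 6371 km."""
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def travel_minutes(
    o: GeoPoint,
    d: GeoPoint,
    unit_type: UnitType | str,
    priority: Priority | str,
    profile: SpeedProfile,
    backend: Optional[RoutingBackend] = None,
    backend_speedup: float = 1.0,
    fallback: bool = True,
) -> float:
    """Estimated door-to-door travel time in minutes.

    Default model: haversine x detour_factor / effective_speed x 60
    + overhead. With a routing backend, the backend's civilian duration is
    divided by ``backend_speedup`` (the priority-specific speed-up of EMS
    over civilian traffic) and the overhead added.
    """
    if backend is not None:
        try:
            sec = backend.table([o], [d])[0][0]
            return max(0.0, sec / 60.0 / backend_speedup) + profile.overhead_min
        except Exception:
            if not fallback:
                raise
            import logging
            logging.getLogger(__name__).warning(
                "routing backend unreachable; falling back to speed-profile model")
    speed = profile.speed_for(unit_type, priority)
    dist = haversine_km(o, d)
    detour = profile.detour_factor if profile.mode == "GROUND" else 1.0
    return dist * detour / speed * 60.0 + profile.overhead_min


def isochrone_bands(
    origin: GeoPoint,
    points: Sequence[GeoPoint],
    thresholds_min: Sequence[float] = (6.0, 9.0, 12.0, 15.0),
    unit_type: UnitType | str = UnitType.AMBULANCE,
    priority: Priority | str = Priority.P1,
    profile: Optional[SpeedProfile] = None,
) -> list[int]:
    """Assign each point the index of its travel-time band from ``origin``.

    Bands are half-open upper-inclusive: band i covers
    (thresholds[i-1], thresholds[i]]; points beyond the last threshold get
    :data:`OUTSIDE` (-1). The default 6/9/12/15-minute scheme matches the
    usual choropleth coloring, with everything past 15 min unreached.
    """
    if not thresholds_min:
        raise ValueError("thresholds_min must be non-empty")
    if any(b <= a for a, b in zip(thresholds_min, thresholds_min[1:])):
        raise ValueError("thresholds_min must be strictly increasing")
    if profile is None:
        profile = default_profiles()["default"]
    out = []
    for p in points:
        t = travel_minutes(origin, p, unit_type, priority, profile)
        band = OUTSIDE
        for i, hi in enumerate(thresholds_min):
            if t <= hi:
                band = i
                break
        out.append(band)
    return out


def static_coverage(
    points: Sequence[GeoPoint],
    bases: Sequence[GeoPoint],
    mart_min: float = 15.0,
    unit_type: UnitType | str = UnitType.AMBULANCE,
    priority: Priority | str = Priority.P1,
    profile: Optional[SpeedProfile] = None,
) -> float:
    """Percentage of demand points whose best base is within ``mart_min``.

    A static (roster-free) upper view of coverage: each point is scored by
    the minimum travel time over all bases.
    """
    if not points:
        raise ValueError("empty point set")
    if not bases:
        raise ValueError("need at least one base")
    if profile is None:
        profile = default_profiles()["default"]
    n_ok = 0
    for p in points:
        t = min(travel_minutes(b, p, unit_type, priority, profile) for b in bases)
        if t <= mart_min:
            n_ok += 1
    return 100.0 * n_ok / len(points)
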