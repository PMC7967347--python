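"""Preparation of raw incident tables into a clean scenario.

Dispatch-center exports arrive in arbitrary dialects. The pipeline here is:
standardize column names and types, restrict to the planning area (foreign
providers inside the area become the sentinel organization "external"),
apply the three cleaning rules in order, group incidents into events, and
unroll rosters to quarter-hour availability timelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence

import pandas as pd

from .scenario import (
    CHAIN_FIELDS,
    GeoPoint,
    IncidentRecord,
    EventGroup,
    Priority,
    Shift,
    TimestampChain,
    UnitType,
    ROSTER_RESOLUTION_S,
)
from .travel import haversine_km

__all__ = [
    "CleaningReport",
    "AvailabilityTimeline",
    "RowFailure",
    "standardize",
    "restrict_to_area",
    "clean",
    "group_events",
    "expand_rosters",
    "staffed_count",
]

MANDATORY_COLUMNS = ("incident_id", "lon", "lat", "priority", "t_call_ems")
OPTIONAL_COLUMNS = (
    "event_id", "required_type", "historic_unit_id", "hospital_id",
    "required_capability", "organization", "discontinued",
    "t_call_dispatch", "t_depart_base", "t_arrive_scene", "t_depart_scene",
    "t_arrive_hospital", "t_free", "t_arrive_base",
)


@dataclass
class CleaningReport:
    """Per-rule removal counts; additive by construction.

    Rule i removes inconsistent/wrong timestamps, rule ii missing turnout or
    response times, rule iii incomplete chains after arrival at scene.
    Discontinued incidents are dropped before rule i and counted separately.
    """

    n_input: int = 0
    n_removed_discontinued: int = 0
    n_removed_inconsistent: int = 0        # rule i
    n_removed_missing_rt: int = 0          # rule ii
    n_removed_incomplete_post_arrival: int = 0  # rule iii
    n_retained: int = 0

    def conserved(self) -> bool:
        return self.n_input == (
            self.n_retained
            + self.n_removed_discontinued
            + self.n_removed_inconsistent
            + self.n_removed_missing_rt
            + self.n_removed_incomplete_post_arrival
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class AvailabilityTimeline:
    """Staffed intervals of one unit on the roster grid; disjoint, sorted."""

    unit_id: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def staffed_at(self, t: int) -> bool:
        for s, e in self.intervals:
            if s <= t < e:
                return True
        return False

    def staffed_seconds(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass(frozen=True)
class RowFailure:
    row: int
    column: str
    message: str


def _parse_time(value, epoch: datetime) -> Optional[int]:
    """ISO-8601 string or numeric seconds -> integer seconds since epoch."""
    if value is None:
        return None
    if isinstance(value, (int, float)):
        if isinstance(value, float) and math.isnan(value):
            return None
        return int(value)
    txt = str(value).strip()
    if not txt:
        return None
    try:
        return int(txt)
    except ValueError:
        pass
    dt = datetime.fromisoformat(txt)
    return int((dt - epoch).total_seconds())


def standardize(
    raw: pd.DataFrame | Sequence[dict],
    column_map: Optional[dict[str, str]] = None,
    epoch: Optional[datetime] = None,
) -> tuple[list[IncidentRecord], list[RowFailure]]:
    """Map raw tabular records onto typed incident records.

    column_map maps standard names to raw column names (identity by
    default). Unknown raw columns are dropped with a warning; rows with
    unparseable mandatory fields are excluded and reported as failures.
    """
    if not isinstance(raw, pd.DataFrame):
        raw = pd.DataFrame(list(raw))
    column_map = column_map or {}
    epoch = epoch or datetime.fromisoformat("2024-01-01T00:00:00")

    resolved = {}
    for std in MANDATORY_COLUMNS + OPTIONAL_COLUMNS:
        src = column_map.get(std, std)
        if src in raw.columns:
            resolved[std] = src
    missing = [c for c in MANDATORY_COLUMNS if c not in resolved]
    if missing:
        raise KeyError(f"unmapped mandatory column(s): {', '.join(missing)}")
    unknown = set(raw.columns) - set(resolved.values())
    if unknown:
        warnings.warn(f"dropping unknown columns: {sorted(unknown)}", stacklevel=2)

    records: list[IncidentRecord] = []
    failures: list[RowFailure] = []
    time_cols = [c for c in CHAIN_FIELDS]
    for idx, row in raw.iterrows():
        def get(std, default=None):
            if std not in resolved:
                return default
            val = row[resolved[std]]
            if val is None or (isinstance(val, float) and math.isnan(val)):
                return default
            if isinstance(val, str) and not val.strip():
                return default
            return val

        try:
            times = {}
            for c in time_cols:
                times[c] = _parse_time(get(c), epoch)
            if times["t_call_ems"] is None:
                raise ValueError("missing t_call_ems")
            prio = Priority(str(get("priority")))
            rtype = UnitType(str(get("required_type", "AMBULANCE")))
            rec = IncidentRecord(
                incident_id=str(get("incident_id")),
                event_id=str(get("event_id", get("incident_id"))),
                place=GeoPoint(float(get("lon")), float(get("lat"))),
                priority=prio,
                required_type=rtype,
                times=TimestampChain(**times),
                historic_unit_id=(None if get("historic_unit_id") is None
                                  else str(get("historic_unit_id"))),
                hospital_id=(None if get("hospital_id") is None else str(get("hospital_id"))),
                required_capability=(None if get("required_capability") is None
                                     else str(get("required_capability"))),
                organization=str(get("organization", "own")),
                discontinued=str(get("discontinued", "")).strip().lower()
                in ("1", "true", "yes"),
            )
            records.append(rec)
        except (ValueError, TypeError, KeyError) as exc:
            failures.append(RowFailure(int(idx), "*", str(exc)))
    return records, failures


def restrict_to_area(
    records: Sequence[IncidentRecord],
    area,
    own_orgs: set[str] | frozenset[str],
) -> list[IncidentRecord]:
    """Keep incidents inside ``area`` (boundary counts as inside); incidents
    served by organizations outside ``own_orgs`` are relabelled "external".

    Incidents outside the area are dropped: the goal is to optimize EMS for
    its own region, not the neighbours'.
    """
    from shapely.geometry import Point, shape
    from shapely.geometry.base import BaseGeometry

    poly = area if isinstance(area, BaseGeometry) else shape(area)
    if poly.is_empty or not poly.is_valid:
        raise ValueError("degenerate area polygon")
    out = []
    for rec in records:
        if not poly.covers(Point(rec.place.lon, rec.place.lat)):
            continue
        if rec.organization not in own_orgs:
            rec = IncidentRecord(**{**rec.__dict__, "organization": "external"})
        out.append(rec)
    return out


def _rule_i(rec: IncidentRecord, horizon: Optional[tuple[int, int]]) -> bool:
    """Inconsistent or wrong timestamps: ordering violation among present
    fields (equivalently a negative implied duration) or a call outside the
    scenario horizon."""
    if not rec.times.is_ordered():
        return True
    if horizon is not None and rec.times.t_call_ems is not None:
        lo, hi = horizon
        if not (lo <= rec.times.t_call_ems <= hi):
            return True
    return False


def _rule_ii(rec: IncidentRecord) -> bool:
    """Missing turnout or response time."""
    return rec.times.t_depart_base is None or rec.times.t_arrive_scene is None


def _rule_iii(rec: IncidentRecord) -> bool:
    """Incomplete chain after arrival at scene."""
    t = rec.times
    if t.t_arrive_scene is None:
        return False
    if rec.hospital_id is not None and t.t_depart_scene is not None and t.t_arrive_hospital is None:
        return True
    if t.t_arrive_hospital is not None and t.t_free is None:
        return True
    return False


def clean(
    records: Sequence[IncidentRecord],
    horizon: Optional[tuple[int, int]] = None,
    rules: Sequence[str] = ("i", "ii", "iii"),
) -> tuple[list[IncidentRecord], CleaningReport]:
    """Apply the cleaning rules in order i -> ii -> iii with single
    attribution: each removed record is counted under the first rule that
    catches it, so the report is additive. Cleaning is total and idempotent.
    """
    report = CleaningReport(n_input=len(records))
    kept: list[IncidentRecord] = []
    for rec in records:
        if rec.discontinued:
            report.n_removed_discontinued += 1
        elif "i" in rules and _rule_i(rec, horizon):
            report.n_removed_inconsistent += 1
        elif "ii" in rules and _rule_ii(rec):
            report.n_removed_missing_rt += 1
        elif "iii" in rules and _rule_iii(rec):
            report.n_removed_incomplete_post_arrival += 1
        else:
            kept.append(rec)
    report.n_retained = len(kept)
    return kept, report


def group_events(
    records: Sequence[IncidentRecord],
    max_dist_m: float = 100.0,
    max_gap_s: int = 300,
) -> list[EventGroup]:
    """Partition incidents into events.

    Records sharing an event_id form one group. Records without one fall
    back to spatio-temporal clustering: an incident joins an existing
    fallback group when it lies within ``max_dist_m`` of the group's first
    incident and its call is within ``max_gap_s`` of the group's first call.
    """
    by_id: dict[str, list[str]] = {}
    fallback: list[dict] = []  # {"ids": [...], "place": GeoPoint, "t0": int}
    for rec in sorted(records, key=lambda r: (r.times.t_call_ems or 0, r.incident_id)):
        if rec.event_id:
            by_id.setdefault(rec.event_id, []).append(rec.incident_id)
            continue
        t = rec.times.t_call_ems or 0
        attached = False
        for grp in fallback:
            if (t - grp["t0"] <= max_gap_s
                    and haversine_km(rec.place, grp["place"]) * 1000.0 <= max_dist_m):
                grp["ids"].append(rec.incident_id)
                attached = True
                break
        if not attached:
            fallback.append({"ids": [rec.incident_id], "place": rec.place, "t0": t})
    groups = [EventGroup(eid, tuple(ids)) for eid, ids in by_id.items()]
    groups += [EventGroup(f"F{k}", tuple(g["ids"])) for k, g in enumerate(fallback)]
    return groups


def expand_rosters(
    shifts: Sequence[Shift],
    horizon: tuple[int, int],
    resolution: int = ROSTER_RESOLUTION_S,
    epoch_weekday: int = 0,
) -> list[AvailabilityTimeline]:
    """Unroll shift recurrences over ``horizon`` into per-unit staffed
    intervals, clipped to the horizon and merged when overlapping or
    adjacent. The count of staffed units at any instant is then the roster
    curve a demand/roster chart displays.
    """
    if 3600 % resolution != 0:
        raise ValueError("resolution must divide 3600")
    lo, hi = horizon
    if hi <= lo:
        raise ValueError("empty horizon")

    raw: dict[str, list[tuple[int, int]]] = {}
    day_lo = lo // 86400 - 2
    day_hi = hi // 86400 + 2
    for sh in shifts:
        spans: list[tuple[int, int]] = []
        if sh.recurrence == "once":
            spans.append((sh.start, sh.end))
        else:
            for day in range(day_lo, day_hi + 1):
                if sh.recurrence == "weekly":
                    wd = (epoch_weekday + day) % 7
                    if wd not in sh.weekdays:
                        continue
                spans.append((day * 86400 + sh.start, day * 86400 + sh.end))
        for s, e in spans:
            s, e = max(s, lo), min(e, hi)
            if e > s:
                raw.setdefault(sh.unit_id, []).append((s, e))

    out = []
    for unit_id, ivs in raw.items():
        ivs.sort()
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out.append(AvailabilityTimeline(unit_id, merged))
    return out


def staffed_count(timelines: Sequence[AvailabilityTimeline], t: int) -> int:
    """Number of staffed units at instant ``t``."""
    return sum(1 for tl in timelines if tl.staffed_at(t))
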