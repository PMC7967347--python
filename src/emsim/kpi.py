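"""Key performance indicators of an EMS system.

Response time (RT) is an *event*-level quantity: an emergency may trigger
several incidents, and its RT is the first arrival at the scene minus the
first call, under one of three regional start conventions. The response-
time compliance rate (RTCR) is the percentage of events whose RT is within
the maximum allowed response time (MART); prehospital time (PT), service
time, utilization and overtime complete the picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .data_prep import AvailabilityTimeline
from .engine import SimResult
from .scenario import (
    Community,
    EventGroup,
    GeoPoint,
    IncidentRecord,
    TimestampChain,
)
from .travel import haversine_km

__all__ = [
    "CommunityRTCR",
    "event_response_time",
    "rtcr",
    "rtcr_by_community",
    "prehospital_time",
    "utilization",
    "demand_profile",
    "compare_scenarios",
    "size_bin",
    "color_class",
]

_VARIANT_START = {
    "TRANSIT_ONLY": "t_depart_base",
    "PREP_PLUS_TRANSIT": "t_call_ems",
    "FROM_DISPATCH_CALL": "t_call_dispatch",
}

#: Event-count bins used for symbol sizes on compliance maps.
SIZE_BINS = ((0, 9, "0-9"), (10, 99, "10-99"), (100, 999, "100-999"), (1000, 9999, "1000-9999"))

#: Compliance color classes (percent thresholds, configurable per call).
DEFAULT_COLOR_THRESHOLDS = (70.0, 85.0)  # RED < 70 <= ORANGE < 85 <= GREEN


@dataclass
class CommunityRTCR:
    community_id: str
    name: str
    n_events: int
    rtcr: float
    size_bin: str
    color_class: str


def size_bin(n: int) -> str:
    for lo, hi, label in SIZE_BINS:
        if lo <= n <= hi:
            return label
    return SIZE_BINS[-1][2]


def color_class(rtcr_pct: float,
                thresholds: tuple[float, float] = DEFAULT_COLOR_THRESHOLDS) -> str:
    if rtcr_pct < thresholds[0]:
        return "RED"
    if rtcr_pct < thresholds[1]:
        return "ORANGE"
    return "GREEN"


def event_response_time(
    event: EventGroup,
    chains: dict[str, TimestampChain],
    variant: str = "PREP_PLUS_TRANSIT",
) -> float:
    """Event RT in minutes: first arrival at scene minus first call.

    Both the minimum arrival and the minimum variant-specific start are
    taken event-wide over all incidents. Returns ``inf`` when no unit ever
    arrived (the event was not served); raises if the start field is
    missing in every incident.
    """
    start_field = _VARIANT_START[variant]
    starts = []
    arrivals = []
    for iid in event.incident_ids:
        c = chains.get(iid)
        if c is None:
            continue
        s = getattr(c, start_field)
        if s is not None:
            starts.append(s)
        if c.t_arrive_scene is not None:
            arrivals.append(c.t_arrive_scene)
    if not starts:
        raise ValueError(
            f"event {event.event_id}: field {start_field} missing in all incidents")
    if not arrivals:
        return math.inf
    return (min(arrivals) - min(starts)) / 60.0


def rtcr(
    events: Sequence[EventGroup],
    chains: dict[str, TimestampChain],
    mart_min: float = 15.0,
    variant: str = "PREP_PLUS_TRANSIT",
    decimals: Optional[int] = 1,
    include_unserved: bool = True,
) -> float:
    """Percentage of events with RT <= MART (boundary counts as compliant).

    Unserved events (infinite RT) count as non-compliant by default;
    ``include_unserved=False`` drops them from the denominator. Rounded to
    one decimal for reporting; pass ``decimals=None`` for the raw value.
    """
    if not events:
        raise ValueError("empty event set")
    n = 0
    ok = 0
    for e in events:
        rt = event_response_time(e, chains, variant)
        if math.isinf(rt) and not include_unserved:
            continue
        n += 1
        if rt <= mart_min:
            ok += 1
    if n == 0:
        raise ValueError("no events left after exclusions")
    value = 100.0 * ok / n
    return round(value, decimals) if decimals is not None else value


def _event_place(event: EventGroup, incidents: dict[str, IncidentRecord]) -> Optional[GeoPoint]:
    for iid in event.incident_ids:
        if iid in incidents:
            return incidents[iid].place
    return None


def rtcr_by_community(
    events: Sequence[EventGroup],
    chains: dict[str, TimestampChain],
    incidents: Sequence[IncidentRecord],
    communities: Sequence[Community],
    mart_min: float = 15.0,
    variant: str = "PREP_PLUS_TRANSIT",
    color_thresholds: tuple[float, float] = DEFAULT_COLOR_THRESHOLDS,
) -> list[CommunityRTCR]:
    """Aggregate compliance per community (one row per community with >= 1
    event). Events covered by no polygon land in "UNASSIGNED"; communities
    given only as centroids are matched by nearest centroid."""
    from shapely.geometry import Point, shape

    inc_by_id = {i.incident_id: i for i in incidents}
    polys = []
    centroids = []
    for c in communities:
        if c.geometry is not None:
            polys.append((c, shape(c.geometry)))
        elif c.centroid is not None:
            centroids.append(c)

    groups: dict[str, list[EventGroup]] = {}
    meta: dict[str, str] = {}
    for e in events:
        place = _event_place(e, inc_by_id)
        cid, name = "UNASSIGNED", "UNASSIGNED"
        if place is not None:
            pt = Point(place.lon, place.lat)
            hit = next((c for c, g in polys if g.covers(pt)), None)
            if hit is None and centroids:
                hit = min(centroids, key=lambda c: haversine_km(place, c.centroid))
            if hit is not None:
                cid, name = hit.community_id, hit.name
        groups.setdefault(cid, []).append(e)
        meta[cid] = name

    out = []
    for cid, evs in sorted(groups.items()):
        val = rtcr(evs, chains, mart_min, variant, decimals=1)
        out.append(CommunityRTCR(cid, meta[cid], len(evs), val,
                                 size_bin(len(evs)), color_class(val, color_thresholds)))
    return out


def prehospital_time(chain: TimestampChain, limit_min: float = 60.0
                     ) -> Optional[tuple[float, bool]]:
    """(PT minutes, compliant at the 60-min working limit), or None for a
    non-transport incident. PT runs from the call to the EMS until arrival
    at the hospital."""
    if chain.t_arrive_hospital is None or chain.t_call_ems is None:
        return None
    pt = (chain.t_arrive_hospital - chain.t_call_ems) / 60.0
    return pt, pt <= limit_min


def utilization(
    simresult: SimResult,
    timelines: Sequence[AvailabilityTimeline],
) -> tuple[pd.DataFrame, float]:
    """Per-unit busy/staffed ratio and fleet mean.

    Busy time runs from the dispatch decision to t_free. Overtime is busy
    time outside staffed intervals (a unit finishes its mission when the
    shift ends mid-mission), reported in hours over the simulated horizon.
    Units with zero staffed time but nonzero busy time are flagged with NaN
    utilization.
    """
    tl_by_unit = {tl.unit_id: tl for tl in timelines}
    rows = []
    for unit_id in sorted(set(tl_by_unit) | set(simresult.unit_busy)):
        busy = simresult.unit_busy.get(unit_id, [])
        busy_s = sum(e - s for s, e in busy)
        tl = tl_by_unit.get(unit_id)
        staffed_s = tl.staffed_seconds() if tl else 0
        over_s = 0
        if tl is not None:
            for s, e in busy:
                cov = 0
                for a, b in tl.intervals:
                    cov += max(0, min(e, b) - max(s, a))
                over_s += (e - s) - cov
        else:
            over_s = busy_s
        util = 100.0 * busy_s / staffed_s if staffed_s > 0 else (
            math.nan if busy_s > 0 else 0.0)
        rows.append({
            "unit_id": unit_id,
            "staffed_h": staffed_s / 3600.0,
            "busy_h": busy_s / 3600.0,
            "utilization_pct": util,
            "overtime_h": over_s / 3600.0,
        })
    df = pd.DataFrame(rows).set_index("unit_id") if rows else pd.DataFrame(
        columns=["staffed_h", "busy_h", "utilization_pct", "overtime_h"])
    staffed = df[df["staffed_h"] > 0] if len(df) else df
    fleet_mean = float(staffed["utilization_pct"].mean()) if len(staffed) else 0.0
    return df, fleet_mean


def demand_profile(
    incidents: Sequence[IncidentRecord],
    resolution_s: int = 900,
    split: Optional[str] = None,
    epoch_weekday: int = 0,
) -> pd.DataFrame:
    """Mean incidents per quarter-hour-of-day bin per day.

    Without a split the curve conserves mass: sum(curve) x number of days
    equals the incident count. ``split='weekday_weekend'`` returns one
    column per part (Mon-Fri vs Sat-Sun).
    """
    if not incidents:
        raise ValueError("no incidents")
    n_bins = 86400 // resolution_s
    calls = np.array([i.times.t_call_ems for i in incidents], dtype=np.int64)
    days = calls // 86400
    bins = (calls % 86400) // resolution_s
    day_lo, day_hi = int(days.min()), int(days.max())
    all_days = np.arange(day_lo, day_hi + 1)
    if split is None:
        counts = np.zeros(n_bins)
        np.add.at(counts, bins, 1.0)
        curve = counts / len(all_days)
        return pd.DataFrame({"all": curve},
                            index=pd.Index(np.arange(n_bins) * resolution_s, name="second_of_day"))
    if split != "weekday_weekend":
        raise ValueError(f"unknown split {split!r}")
    wd = (epoch_weekday + days) % 7
    wd_all = (epoch_weekday + all_days) % 7
    out = {}
    for label, mask_days in (("weekday", wd_all < 5), ("weekend", wd_all >= 5)):
        sel = (wd < 5) if label == "weekday" else (wd >= 5)
        counts = np.zeros(n_bins)
        np.add.at(counts, bins[sel], 1.0)
        n_days = max(1, int(mask_days.sum()))
        out[label] = counts / n_days
    return pd.DataFrame(out, index=pd.Index(np.arange(n_bins) * resolution_s,
                                            name="second_of_day"))


def compare_scenarios(a: dict, b: dict, n_incidents: int) -> dict:
    """Delta report between two KPI sets (b relative to a).

    The headline translation: a compliance gain of x percentage points on n
    incidents means round(x/100 x n) additional incidents estimated to be
    reached within the MART (e.g. +0.7 pp on 10,000 incidents = 70).
    Requires both KPI sets to use the same MART and RT variant.
    """
    for key in ("mart_min", "rt_variant"):
        if a.get(key) != b.get(key):
            raise ValueError(f"mismatched configs: {key} {a.get(key)!r} != {b.get(key)!r}")
    d_pp = b["rtcr"] - a["rtcr"]
    out = {
        "delta_rtcr_pp": d_pp,
        "incident_equivalent": int(round(d_pp / 100.0 * n_incidents)),
        "n_incidents": n_incidents,
    }
    for key, label in (("utilization_mean_pct", "delta_utilization_pp"),
                       ("overtime_h", "delta_overtime_h")):
        if key in a and key in b:
            out[label] = b[key] - a[key]
    return out
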