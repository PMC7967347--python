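"""Synthetic scenario generator.

Real dispatch-center data are confidential, so this module generates
scenarios with the statistical structure the simulator assumes: call times
from a non-homogeneous Poisson process with a quarter-hour piecewise-
constant daily intensity, locations from an urban-cluster + rural-
background spatial mixture, a configurable priority mix, lognormal service
times, bases with day/night rosters, and hospitals with capabilities.
Historical timestamp chains are completed by running the engine once, so
the "history" is internally consistent with the model's own rules.

Defect injection mutates an exact number of records per cleaning class and
returns a ground-truth manifest, the oracle for cleaning tests.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .scenario import (
    Base,
    EMSUnit,
    EventGroup,
    GeoPoint,
    Hospital,
    IncidentRecord,
    Priority,
    Scenario,
    Shift,
    SimConfig,
    TimestampChain,
    UnitType,
    validate_scenario,
)

__all__ = ["SynthConfig", "gen_scenario", "inject_defects", "default_demand_curve"]

#: km per degree of latitude (and of longitude at the equator).
KM_PER_DEG = 111.32


def default_demand_curve() -> list[float]:
    """The shipped 96-bin relative demand weights (sum 1): low overnight,
    rising after 06:00, broad daytime plateau, evening decline."""
    with resources.files("emsim.data").joinpath("demand_curve.json").open() as fh:
        return list(json.load(fh)["weights"])


def _default_mixture() -> list[dict]:
    # one main urban cluster, one secondary town, plus uniform background
    return [
        {"lon": 9.37, "lat": 47.42, "sd_km": 2.5, "weight": 0.60},
        {"lon": 9.55, "lat": 47.47, "sd_km": 1.8, "weight": 0.22},
    ]


def _default_priority_mix() -> dict[str, float]:
    return {"P1": 0.25, "P2": 0.35, "P3": 0.10, "S1": 0.05, "S2": 0.10, "S3": 0.15}


@dataclass
class SynthConfig:
    """Study conditions for synthetic scenarios.

    Defaults emulate a mid-size Swiss EMS region: about 20,000 incidents
    per year, two urban clusters over a ~30 km rural background, and three
    bases staffed day and night.
    """

    horizon_days: int = 7
    annual_volume: int = 20000
    demand_curve: list[float] = field(default_factory=default_demand_curve)
    weekend_scale: float = 1.0
    spatial_mixture: list[dict] = field(default_factory=_default_mixture)
    background_weight: float = 0.18
    bbox: tuple[float, float, float, float] = (9.20, 47.30, 9.70, 47.56)  # lon/lat
    priority_mix: dict[str, float] = field(default_factory=_default_priority_mix)
    transport_fraction: float = 0.55
    multi_incident_fraction: float = 0.05
    n_bases: int = 3
    units_day_per_base: int = 2
    units_night_per_base: int = 1
    n_hospitals: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.horizon_days < 1 or self.annual_volume < 0:
            raise ValueError("horizon_days must be >=1 and annual_volume >=0")
        if self.n_bases < 1 and self.annual_volume > 0:
            raise ValueError("need at least one base for nonzero volume")
        if abs(sum(self.priority_mix.values()) - 1.0) > 1e-6:
            raise ValueError("priority_mix must sum to 1")
        if any(w < 0 for w in self.demand_curve) or sum(self.demand_curve) <= 0:
            raise ValueError("demand_curve weights must be non-negative, not all zero")


def _sample_locations(rng: np.random.Generator, n: int, cfg: SynthConfig) -> np.ndarray:
    comps = cfg.spatial_mixture
    weights = np.array([c["weight"] for c in comps] + [cfg.background_weight], dtype=float)
    weights /= weights.sum()
    choice = rng.choice(len(weights), size=n, p=weights)
    lon = np.empty(n)
    lat = np.empty(n)
    lon0, lat0, lon1, lat1 = cfg.bbox
    for k, comp in enumerate(comps):
        m = choice == k
        nm = int(m.sum())
        if nm == 0:
            continue
        sd_deg_lat = comp["sd_km"] / KM_PER_DEG
        sd_deg_lon = comp["sd_km"] / (KM_PER_DEG * math.cos(math.radians(comp["lat"])))
        lat[m] = rng.normal(comp["lat"], sd_deg_lat, nm)
        lon[m] = rng.normal(comp["lon"], sd_deg_lon, nm)
    m = choice == len(comps)
    nm = int(m.sum())
    lon[m] = rng.uniform(lon0, lon1, nm)
    lat[m] = rng.uniform(lat0, lat1, nm)
    return np.clip(lon, lon0, lon1), np.clip(lat, lat0, lat1)


def _sample_call_times(rng: np.random.Generator, cfg: SynthConfig,
                       epoch_weekday: int = 0) -> np.ndarray:
    """Non-homogeneous Poisson arrivals: quarter-hour piecewise-constant
    intensity scaled so one day's expectation is annual_volume/365 (times
    the weekend factor on Sat/Sun)."""
    weights = np.asarray(cfg.demand_curve, dtype=float)
    weights = weights / weights.sum()
    daily = cfg.annual_volume / 365.0
    times = []
    for day in range(cfg.horizon_days):
        wd = (epoch_weekday + day) % 7
        scale = cfg.weekend_scale if wd >= 5 else 1.0
        lam = weights * daily * scale
        counts = rng.poisson(lam)
        for b, c in enumerate(counts):
            if c:
                offs = rng.uniform(0.0, 900.0, c)
                times.extend(day * 86400 + b * 900 + offs)
    return np.sort(np.array(times)).astype(np.int64)


def gen_scenario(cfg: SynthConfig, complete_chains: bool = True) -> Scenario:
    """Generate a validated scenario; deterministic per cfg.seed.

    With ``complete_chains`` the engine runs once over the generated calls
    and the simulated chains (and serving units) become the historical
    record, so cleaning, replay and validation-ladder tests operate on
    internally consistent data.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sim_cfg = SimConfig(seed=cfg.seed)

    # --- infrastructure ---------------------------------------------------
    comps = cfg.spatial_mixture
    bases = []
    for k in range(cfg.n_bases):
        comp = comps[k % len(comps)]
        jitter = 0.004 * (k // len(comps))
        bases.append(Base(
            f"B{k + 1}",
            GeoPoint(round(comp["lon"] + jitter, 6), round(comp["lat"] + jitter, 6)),
            name=f"Base {k + 1}", region="own"))
    units, shifts = [], []
    for b in bases:
        for j in range(cfg.units_day_per_base):
            uid = f"U_{b.base_id}_D{j + 1}"
            units.append(EMSUnit(uid, UnitType.AMBULANCE, b.base_id))
            shifts.append(Shift(uid, 7 * 3600, 19 * 3600, "daily"))
        for j in range(cfg.units_night_per_base):
            uid = f"U_{b.base_id}_N{j + 1}"
            units.append(EMSUnit(uid, UnitType.AMBULANCE, b.base_id))
            shifts.append(Shift(uid, 19 * 3600, 31 * 3600, "daily"))
    hospitals = []
    full = frozenset({"GENERAL", "STROKE", "STEMI", "POLYTRAUMA", "TBI", "SCD", "SEPSIS"})
    for k in range(cfg.n_hospitals):
        comp = comps[k % len(comps)]
        caps = full if k == 0 else frozenset({"GENERAL"})
        hospitals.append(Hospital(
            f"H{k + 1}", GeoPoint(round(comp["lon"] + 0.006, 6), round(comp["lat"] - 0.006, 6)),
            caps))

    # --- incidents ---------------------------------------------------------
    calls = _sample_call_times(rng, cfg)
    n = len(calls)
    lon, lat = _sample_locations(rng, n, cfg)
    prios = rng.choice(list(cfg.priority_mix), size=n,
                       p=np.array(list(cfg.priority_mix.values())))
    transport = rng.random(n) < cfg.transport_fraction
    extra_event = rng.random(n) < cfg.multi_incident_fraction
    dispatch_lag = rng.integers(30, 120, size=n)

    def nearest_hospital(p: GeoPoint) -> str:
        from .travel import haversine_km
        return min(hospitals, key=lambda h: haversine_km(p, h.location)).hospital_id

    incidents: list[IncidentRecord] = []
    events: list[EventGroup] = []
    for i in range(n):
        place = GeoPoint(float(lon[i]), float(lat[i]))
        eid = f"E{i + 1:06d}"
        members = []
        n_members = 2 if extra_event[i] else 1
        for m in range(n_members):
            iid = f"I{i + 1:06d}" + ("" if m == 0 else f"_{m + 1}")
            t_call = int(calls[i]) + (0 if m == 0 else int(rng.integers(10, 60)))
            hosp = nearest_hospital(place) if (transport[i] and hospitals and m == 0) else None
            incidents.append(IncidentRecord(
                incident_id=iid,
                event_id=eid,
                place=place,
                priority=Priority(str(prios[i])),
                required_type=UnitType.AMBULANCE,
                times=TimestampChain(
                    t_call_dispatch=t_call - int(dispatch_lag[i]),
                    t_call_ems=t_call,
                ),
                hospital_id=hosp,
                organization="own",
            ))
            members.append(iid)
        events.append(EventGroup(eid, tuple(members)))

    incidents.sort(key=lambda r: (r.times.t_call_ems, r.incident_id))
    scn = Scenario(
        incidents=incidents, events=events, units=units, shifts=shifts,
        bases=bases, hospitals=hospitals, config=sim_cfg,
    )
    violations = validate_scenario(scn)
    if violations:
        raise AssertionError(f"generator produced invalid scenario: {violations[:3]}")

    if complete_chains and incidents:
        from .engine import simulate
        sim = simulate(scn, "STANDARD")
        assign = sim.assignment_by_incident()
        for inc in scn.incidents:
            dec = assign.get(inc.incident_id)
            chain = sim.sim_times.get(inc.incident_id)
            if dec is not None and dec.unit_id is not None and chain is not None:
                inc.times = copy.copy(chain)
                inc.historic_unit_id = dec.unit_id
    return scn


def inject_defects(
    records: Sequence[IncidentRecord],
    spec: dict[str, int],
    seed: int = 0,
) -> tuple[list[IncidentRecord], dict[str, list[str]]]:
    """Mutate exactly spec['i'|'ii'|'iii'] records per cleaning class.

    i: swap t_depart_base and t_arrive_scene (ordering violation);
    ii: blank t_arrive_scene (missing response time);
    iii: blank t_arrive_hospital on a transport record whose t_depart_scene
    stays present (incomplete chain after arrival at scene).

    Returns mutated copies and the manifest of mutated ids per class; the
    manifest is the exact ground truth the cleaning report must recover.
    """
    rng = np.random.default_rng(seed)
    spec = {"i": int(spec.get("i", 0)), "ii": int(spec.get("ii", 0)),
            "iii": int(spec.get("iii", 0))}
    out = [copy.deepcopy(r) for r in records]
    used: set[int] = set()

    def eligible_i(r):
        t = r.times
        return (t.t_depart_base is not None and t.t_arrive_scene is not None
                and t.t_depart_base < t.t_arrive_scene)

    def eligible_ii(r):
        return r.times.t_arrive_scene is not None

    def eligible_iii(r):
        t = r.times
        return (r.hospital_id is not None and t.t_arrive_scene is not None
                and t.t_depart_scene is not None and t.t_arrive_hospital is not None)

    manifest: dict[str, list[str]] = {"i": [], "ii": [], "iii": []}
    # assign the scarcest class first so overlapping eligibility is not wasted
    for cls, pred in (("iii", eligible_iii), ("i", eligible_i), ("ii", eligible_ii)):
        want = spec[cls]
        pool = [k for k, r in enumerate(out) if k not in used and pred(r)]
        if want > len(pool):
            raise ValueError(
                f"requested {want} class-{cls} defects but only {len(pool)} eligible records")
        picks = rng.choice(len(pool), size=want, replace=False) if want else []
        for p in picks:
            k = pool[int(p)]
            used.add(k)
            t = out[k].times
            if cls == "i":
                t.t_depart_base, t.t_arrive_scene = t.t_arrive_scene, t.t_depart_base
            elif cls == "ii":
                t.t_arrive_scene = None
            else:
                t.t_arrive_hospital = None
            manifest[cls].append(out[k].incident_id)
    for v in manifest.values():
        v.sort()
    return out, manifest
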