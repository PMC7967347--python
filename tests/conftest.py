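"""Shared fixtures: deterministic hand-built scenarios and synthetic ones."""

from __future__ import annotations

import pytest

from emsim.scenario import (
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
)

#: Degenerate duration model (sigma 0 -> exact medians) for hand-traced tests.
FIXED_SERVICE_TIMES = {
    "turnout": {"median_min": 1.0, "sigma": 0.0},
    "on_scene": {"median_min": 20.0, "sigma": 0.0},
    "handover": {"median_min": 5.0, "sigma": 0.0},
    "transport": {"median_min": 8.0, "sigma": 0.0},
}

ORIGIN = GeoPoint(9.0, 47.0)


def offset_north(deg: float) -> GeoPoint:
    return GeoPoint(9.0, 47.0 + deg)


def fixed_config(**kw) -> SimConfig:
    base = dict(seed=0, service_times={k: dict(v) for k, v in FIXED_SERVICE_TIMES.items()})
    base.update(kw)
    return SimConfig(**base)


def burst_scenario(
    burst_size: int,
    burst_hours: list[float],
    place: GeoPoint = ORIGIN,
    n_units: int = 1,
    config: SimConfig | None = None,
) -> Scenario:
    """Single base at ORIGIN; ``burst_size`` simultaneous P1 calls at each
    hour; all units on a daily 07:00-19:00 shift. With the fixed duration
    model every timestamp is exactly traceable by hand."""
    cfg = config or fixed_config()
    bases = [Base("B1", ORIGIN, region="own")]
    units = [EMSUnit(f"U{j + 1}", UnitType.AMBULANCE, "B1") for j in range(n_units)]
    shifts = [Shift(u.unit_id, 7 * 3600, 19 * 3600, "daily") for u in units]
    incidents, events = [], []
    k = 0
    for h in burst_hours:
        for _ in range(burst_size):
            k += 1
            t = int(h * 3600)
            iid = f"I{k:03d}"
            incidents.append(IncidentRecord(
                iid, f"E{k:03d}", place, Priority.P1, UnitType.AMBULANCE,
                TimestampChain(t_call_dispatch=t - 60, t_call_ems=t)))
            events.append(EventGroup(f"E{k:03d}", (iid,)))
    incidents.sort(key=lambda i: (i.times.t_call_ems, i.incident_id))
    return Scenario(incidents=incidents, events=events, units=units,
                    shifts=shifts, bases=bases, config=cfg)


@pytest.fixture
def tiny_scenario() -> Scenario:
    """One base, one day unit, two spaced P1 incidents, one hospital."""
    cfg = fixed_config()
    base = Base("B1", ORIGIN, name="Main", region="own")
    unit = EMSUnit("U1", UnitType.AMBULANCE, "B1")
    shift = Shift("U1", 7 * 3600, 19 * 3600, "daily")
    hosp = Hospital("H1", offset_north(0.02), frozenset({"GENERAL", "STROKE"}))
    place = offset_north(0.05)
    incs = []
    evs = []
    for k, hour in enumerate((9.0, 13.0), start=1):
        t = int(hour * 3600)
        iid = f"I{k}"
        incs.append(IncidentRecord(
            iid, f"E{k}", place, Priority.P1, UnitType.AMBULANCE,
            TimestampChain(t_call_dispatch=t - 90, t_call_ems=t),
            hospital_id="H1" if k == 1 else None))
        evs.append(EventGroup(f"E{k}", (iid,)))
    return Scenario(incidents=incs, events=evs, units=[unit], shifts=[shift],
                    bases=[base], hospitals=[hosp], config=cfg)


@pytest.fixture
def synth_small():
    from emsim.synthgen import SynthConfig, gen_scenario
    return gen_scenario(SynthConfig(horizon_days=2, annual_volume=10000, seed=7))
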