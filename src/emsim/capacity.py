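"""Capacity planning on top of the simulator.

Three planning tools: the unlimited-resources upper bound on the
compliance rate; the iterative reserve-capacity algorithm that adds 12-hour
day/night shifts at existing bases until the compliance target is met (or
the marginal gain drops below epsilon); and the multicopter coverage tools
(operation-radius model and greedy covering location allocation).
"""

from __future__ import annotations

import copy
import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .engine import simulate
from .kpi import rtcr
from .scenario import (
    Base,
    EMSUnit,
    GeoPoint,
    Scenario,
    Shift,
    UnitType,
)
from .travel import haversine_km

__all__ = [
    "CapacityStep",
    "CapacityCurve",
    "CoverPlan",
    "unlimited_bound",
    "reserve_capacity",
    "operation_radius",
    "greedy_cover",
    "DAY_SHIFT",
    "NIGHT_SHIFT",
]

#: 12-hour shift anchors: day 07:00-19:00, night 19:00-07:00 (seconds of day).
DAY_SHIFT = (7 * 3600, 19 * 3600)
NIGHT_SHIFT = (19 * 3600, 31 * 3600)


@dataclass
class CapacityStep:
    label: str                 # S0, S1, ...
    added: Optional[str]       # "base_id/DAY" descriptor; None for S0
    rtcr: float                # percent, unrounded


@dataclass
class CapacityCurve:
    steps: list[CapacityStep] = field(default_factory=list)
    stop_reason: str = "TARGET_REACHED"  # TARGET_REACHED | GAIN_BELOW_EPSILON | MAX_ITER

    @property
    def n_added(self) -> int:
        return sum(1 for s in self.steps if s.added is not None)


@dataclass
class CoverPlan:
    selected_sites: list[GeoPoint] = field(default_factory=list)
    selected_indices: list[int] = field(default_factory=list)
    radius_km: float = 0.0
    covered_fraction: float = 0.0
    uncovered_point_ids: list[int] = field(default_factory=list)


def _scenario_rtcr(s: Scenario, mode: str = "STANDARD") -> float:
    sim = simulate(s, mode)
    cfg = s.config
    return rtcr(s.events, sim.sim_times, cfg.mart_min, cfg.rt_variant,
                decimals=None, include_unserved=cfg.count_unserved)


def unlimited_bound(s: Scenario) -> float:
    """RTCR of the unlimited-resources simulation (percent, unrounded).

    An upper bound for any roster at the given bases: if this stays low,
    the base locations themselves are the problem, not the fleet size.
    """
    return _scenario_rtcr(s, "UNLIMITED")


def _with_extra_unit(s: Scenario, base_id: str, shift_kind: str,
                     unit_type: UnitType, tag: str) -> Scenario:
    start, end = DAY_SHIFT if shift_kind == "DAY" else NIGHT_SHIFT
    s2 = copy.deepcopy(s)
    uid = f"RC_{tag}_{base_id}_{shift_kind}"
    s2.units.append(EMSUnit(uid, unit_type, base_id))
    s2.shifts.append(Shift(uid, start, end, "daily"))
    return s2


def reserve_capacity(
    s: Scenario,
    target_pct: Optional[float] = None,
    epsilon_pp: Optional[float] = None,
    unit_type: UnitType = UnitType.AMBULANCE,
    max_iter: int = 20,
    candidates: Optional[Sequence[tuple[str, str]]] = None,
) -> tuple[CapacityCurve, list[Scenario]]:
    """Minimal staffed shifts needed to meet the compliance target.

    Base locations stay fixed; only the number of units changes. Each
    iteration simulates every candidate addition (each base x {DAY, NIGHT}
    12-h shift), permanently adds the one with the highest resulting RTCR
    (ties: smallest base_id, DAY before NIGHT), then stops when the target
    is reached, the best gain falls below epsilon percentage points, or
    max_iter is hit. S0 is the starting (simulated-historical) scenario;
    one scenario is emitted per step.
    """
    if not s.bases:
        raise ValueError("scenario has no bases")
    cfg = s.config
    target = cfg.martcr_target_pct if target_pct is None else target_pct
    eps = cfg.epsilon_pp if epsilon_pp is None else epsilon_pp
    cand = list(candidates) if candidates is not None else [
        (b.base_id, kind) for b in sorted(s.bases, key=lambda b: b.base_id)
        for kind in ("DAY", "NIGHT")
    ]
    if not cand:
        raise ValueError("empty candidate set")

    current = copy.deepcopy(s)
    cur_rtcr = _scenario_rtcr(current)
    curve = CapacityCurve(steps=[CapacityStep("S0", None, cur_rtcr)])
    scenarios = [current]
    if cur_rtcr >= target:
        curve.stop_reason = "TARGET_REACHED"
        return curve, scenarios

    for it in range(1, max_iter + 1):
        best = None  # (rtcr, order_index, base_id, kind, scenario)
        for order, (base_id, kind) in enumerate(cand):
            trial = _with_extra_unit(current, base_id, kind, unit_type, f"S{it}")
            val = _scenario_rtcr(trial)
            if best is None or (val, -order) > (best[0], -best[1]):
                best = (val, order, base_id, kind, trial)
        val, _, base_id, kind, trial = best
        if val - cur_rtcr < eps:
            curve.stop_reason = "GAIN_BELOW_EPSILON"
            return curve, scenarios
        current, cur_rtcr = trial, val
        curve.steps.append(CapacityStep(f"S{it}", f"{base_id}/{kind}", cur_rtcr))
        scenarios.append(current)
        if cur_rtcr >= target:
            curve.stop_reason = "TARGET_REACHED"
            return curve, scenarios
    curve.stop_reason = "MAX_ITER"
    return curve, scenarios


def operation_radius(
    speed_kmh: float,
    range_km: float,
    t_max_min: float,
    overhead_min: float = 0.0,
    missions_per_sortie: int = 1,
) -> float:
    """Operation radius of an air unit in km.

    The radius follows from range and speed: the time-limited reach
    speed x (t_max - overhead)/60, capped by the endurance-limited reach
    range / (2 x missions_per_sortie) (each mission is a round trip;
    several missions may have to fit one charge). A 72 km/h aircraft with a
    20-min window reaches 24 km; at 80 km/h with a 50 km range the range
    binds at 25 km.
    """
    if speed_kmh <= 0 or range_km <= 0 or missions_per_sortie < 1:
        raise ValueError("speed, range and missions_per_sortie must be positive")
    if t_max_min <= overhead_min:
        raise ValueError("t_max_min must exceed overhead_min")
    r_time = speed_kmh * (t_max_min - overhead_min) / 60.0
    r_range = range_km / (2.0 * missions_per_sortie)
    return min(r_time, r_range)


def greedy_cover(
    demand_points: Sequence[GeoPoint],
    candidate_sites: Sequence[GeoPoint],
    radius_km: float,
    require_complete: bool = False,
) -> CoverPlan:
    """Greedy covering location allocation.

    Repeatedly select the candidate site covering the most still-uncovered
    demand points (ties: smallest site index) until everything is covered
    or no candidate adds coverage. The classical greedy guarantee applies:
    the selection is at most H(n) times larger than the optimum.
    """
    if demand_points and not candidate_sites:
        raise ValueError("no candidate sites for nonempty demand")
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    n = len(demand_points)
    cover_sets = [
        {i for i, p in enumerate(demand_points) if haversine_km(site, p) <= radius_km}
        for site in candidate_sites
    ]
    uncovered = set(range(n))
    chosen: list[int] = []
    while uncovered:
        gains = [len(cs & uncovered) for cs in cover_sets]
        best_gain = max(gains, default=0)
        if best_gain == 0:
            break
        j = gains.index(best_gain)  # smallest index among ties
        chosen.append(j)
        uncovered -= cover_sets[j]
    frac = 1.0 if n == 0 else (n - len(uncovered)) / n
    if require_complete and uncovered:
        warnings.warn(
            f"complete coverage requested but {len(uncovered)} of {n} demand "
            f"points are beyond {radius_km} km of every candidate site",
            stacklevel=2)
    return CoverPlan(
        selected_sites=[candidate_sites[j] for j in chosen],
        selected_indices=chosen,
        radius_km=radius_km,
        covered_fraction=frac,
        uncovered_point_ids=sorted(uncovered),
    )
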