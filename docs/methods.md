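# Methods

## Scope and model

`emsim` simulates an EMS region as a marked point process of incidents served
by a fleet of units under explicit dispatch rules. The simulator is
event-driven: decision epochs are incident call times, the instants at which
units become dispatchable again, and shift starts. It is deterministic given
(scenario, configuration, seed).

### Entities and time

Time is integer seconds since a scenario epoch (files use ISO-8601); the
quarter-hour roster grid and sub-minute travel times are both exactly
representable. Coordinates are WGS84 lon/lat; distance is the haversine on a
6371-km sphere. An *event* groups the incidents of one emergency; the event
response time takes the event-wide first call and first arrival, so one
late unit does not spoil the RT of an otherwise fast response, and one fast
unit suffices for compliance.

### Dispatch rules

- High priority (P1/P2 by default; the set is configurable, and S1 —
  relocation with suspected impairment of vital functions — is *not* high
  priority by default): closest idle compatible unit by ETA; ties go to the
  lexicographically smallest unit id so runs are reproducible.
- Low priority: the historic vehicle when idle and compatible, else closest
  idle.
- Physician (PEP) incidents with multicopters (MCO) in the fleet: dispatch
  the MCO iff one is available, the round trip base→scene→base fits its
  range, and it beats the ground ETA. MCOs never transport patients; a
  transport-requiring PEP incident pairs the MCO with the closest idle
  ambulance when one exists, otherwise the transport leg falls back to the
  duration model.
- Optional gates: cut-off distance/time, and a regional border constraint
  (a unit may only serve incidents of its base's region; incidents marked
  "external" are exempt).
- Queue: two classes (high before low), FIFO within class; re-evaluated at
  every epoch. An incident whose required unit type never exists or never
  becomes available is marked UNSERVED and counted as non-compliant by
  default (configurable to be excluded from the denominator).

### Availability semantics

`t_free` (handover end, or scene departure for non-transport incidents) is
the instant a unit can accept work again, distinct from `t_arrive_base`. In
the default `START_AT_BASE` follow-up mode a unit is dispatchable again only
once back at its base and always departs from the base — the deliberate
simplification of neglecting follow-up incidents. `CHAINED` mode makes the
unit dispatchable at `t_free` from its freeing position (scene or hospital);
positions are not interpolated along the return route. A shift ending
mid-mission never aborts the mission; the excess busy time is reported as
overtime.

### Durations

Turnout, on-scene, handover and fallback-transport durations are lognormal:
`median · exp(sigma · Z)`. Defaults (median minutes / sigma): turnout
1.5/0.35, on-scene 15/0.45, handover 10/0.40, transport 10/0.50 — declared
assumptions in the range of published prehospital process times, since no
canonical values exist for the synthetic region. Draws use a per-incident
RNG keyed by (config seed, CRC32 of the incident id), so they are identical
across simulation modes and across the engine and the brute-force
re-derivation; this is what makes the per-incident dominance check exact
rather than statistical. A `replay` switch reuses the historical durations
of each incident where present, which is what makes the simulated-historical
scenario comparable to history.

### Travel model

Ground: haversine × detour factor (default 1.3) ÷ effective speed × 60.
Default effective speeds: 62 km/h for ambulances and 70 km/h for physician
cars at P1, 85 % of that at other priorities; these are configuration
recorded with every KPI report, not constants. Air: straight line at cruise
speed plus a fixed takeoff+landing overhead (default 1 min). An external
routing backend with the OSRM table interface can replace the closed form;
its civilian durations are divided by a configurable speed-up factor.
Travel legs are rounded to whole seconds.

### Validation ladder

1. *Historical scenario*: the (cleaned) input chains themselves.
2. *Simulated-historical scenario*: the engine replays history; discrepancies
   localize over-simplifications.
3. *Unlimited resources*: every incident is served by a fresh unit of its
   required type from the ETA-best base at the call instant. Per incident,
   the best-base ETA minimizes over the speed profiles actually present in
   the fleet for that type, which guarantees RT(unlimited) ≤ RT(standard)
   incident-by-incident in `START_AT_BASE` mode, hence
   RTCR(unlimited) ≥ RTCR(standard). A low bound diagnoses badly placed
   bases rather than understaffing.

### Reserve capacity

With bases fixed, each iteration simulates every candidate addition — one
ambulance on a 12-h DAY (07:00–19:00) or NIGHT (19:00–07:00) daily shift per
base — and permanently adds the argmax-RTCR candidate (ties: smallest base
id, DAY before NIGHT). Stops: target reached, best gain < epsilon (default
1 pp, compared on unrounded RTCR), or max 20 iterations (bounding the
|bases| × 2 × iterations simulation budget). The curve starts at S0, the
unmodified scenario, and one scenario bundle is emitted per step.

### Coverage planning

The operation radius of an air unit is
`min(speed · (t_max − overhead)/60, range/(2 · missions_per_sortie))` —
time-limited reach capped by endurance, where `missions_per_sortie` encodes
how many round trips must fit one charge (the reading that reconciles a
25-km radius with a ~150-km range requirement at 3 missions; a single round
trip would need only 50 km). Site selection is greedy set cover (most new
demand points per step, ties to the smallest site index), carrying the
classical H(n) approximation guarantee; tests compare it against exhaustive
enumeration up to 12 candidate sites.

## KPI conventions

- RTCR is reported to 1 decimal; all internal comparisons (reserve-capacity
  gains, monotonicity) use the unrounded value. Compliance uses RT ≤ MART
  (boundary compliant).
- Isochrone bands are half-open upper-inclusive: a point at exactly 6.0 min
  belongs to the 0–6 band; beyond the last threshold is OUTSIDE.
- Community aggregation: polygon containment with the boundary counted
  inside; events under no polygon fall into UNASSIGNED; community event
  counts partition the total. Size bins 0–9/10–99/100–999/1000–9999; color
  classes RED < 70 ≤ ORANGE < 85 ≤ GREEN (configurable).
- Utilization = busy seconds (dispatch → free) / staffed seconds; overtime
  is busy time outside staffed intervals, in hours over the horizon.
- Prehospital time (call to hospital arrival) is checked against the
  pragmatic 60-min working limit for time-critical (tracer) diagnoses; it is
  absent, not zero, for non-transport incidents.

## Data preparation

Cleaning applies three rules in order with single attribution, so the report
is additive and idempotent: (i) inconsistent timestamps — any ordering
violation among present fields (equivalently a negative implied duration) or
a call outside the horizon; (ii) missing turnout or response time
(`t_depart_base` or `t_arrive_scene` absent); (iii) incomplete chain after
arrival at scene (a transport incident — operationalized as `hospital_id`
present — with `t_depart_scene` but no `t_arrive_hospital`, or an arrival at
hospital without `t_free`). Incidents flagged discontinued are removed
before rule i and counted separately. Area restriction keeps incidents
inside the planning polygon (boundary inside) and relabels those served by
foreign organizations as "external" rather than dropping them. Fallback
event grouping (for records without an event id) clusters within 100 m and
5 min of a group's first call; both thresholds are configurable and
deliberately conservative.

## Synthetic generator

The generator emulates the statistical structure the simulator assumes, not
any real region: arrivals are a non-homogeneous Poisson process with a
quarter-hour piecewise-constant intensity scaled to `annual_volume/365`
per day (default 20,000/yr; the shipped 96-bin shape — low overnight,
rising after 06:00, broad daytime plateau, evening decline — lives in
`data/demand_curve.json` as configuration data); locations mix Gaussian
urban clusters with a uniform rural background; the priority mix default
(P1 .25, P2 .35, P3 .10, S1 .05, S2 .10, S3 .15) is a placeholder recorded
with every experiment; 55 % of incidents carry a transport leg. Historical
chains are completed by one engine pass, so generated "history" is
internally consistent and replayable. What it does **not** emulate: road
networks and traffic (straight-line travel only), seasonality and weekday
structure (weekend scale defaults to 1), multi-day surges, inter-regional
mutual aid, and real hospital capacity. Passing tests therefore demonstrate
correctness of the rules and estimators on data satisfying the model's own
assumptions — not predictive validity for any real region, which requires
the historical-vs-simulated-historical comparison on real data.

Defect injection mutates an exact per-class count of records (swap
depart/arrive for rule i; blank the scene arrival for rule ii; blank the
hospital arrival of a transport record for rule iii), choosing only records
where the mutation is detectable by exactly the intended rule, and returns
the manifest as ground truth.

## Numerical and design choices

- Violations are data (`validate_scenario` returns a list and never raises);
  simulation refuses invalid scenarios with a summarized error.
- Bundle round-trips are exact: coordinates serialize via `repr`, times as
  ISO-8601 integers, missing values as empty CSV fields.
- Problem sizes in the test and acceptance runs — one-week study scenarios
  (~380 incidents, 9 units), 50-scenario dispatch sweeps at ≤ 8 units and
  ≤ 60 incidents, 20-seed trade-off batches — were chosen as the smallest
  sizes at which the checked properties are exercised with queueing and
  spatial structure present; all invariant checks are exact, not sampled.
- The brute-force dispatcher (`emsim.reference`) intentionally re-implements
  the policy text naively (full fleet scan per decision, restart after every
  assignment) and shares only the input contracts (travel, durations,
  rosters) with the engine.

## Known limitations

- No dynamic relocation between bases (a RELOCATING state is reserved).
- The multicopter decision tree is the two-gate ETA/range rule; richer
  queue-ranking schemes used in multi-country settings are out of scope.
- Speed parameters are scalar per (unit type, priority); no per-road-class
  regression from real traces.
- `CHAINED` mode approximates the return leg by the freeing position.
- The reference dispatcher covers `START_AT_BASE` without multicopters;
  engine behavior beyond that is covered by unit tests, not the oracle.
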