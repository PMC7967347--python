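"""Readers and writers for the scenario bundle.

A bundle is a directory of RFC-4180 CSV tables plus one JSON config:
``incidents.csv``, ``events.csv``, ``units.csv``, ``shifts.csv``,
``bases.csv``, optional ``hospitals.csv``, optional
``communities.geojson``, and ``config.json``. Timestamps are ISO-8601
(UTC-naive, relative to the epoch in the config); missing optional
timestamps are empty fields, never zero.
"""

from __future__ import annotations

import csv
import json
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

from .scenario import (
    Base,
    CHAIN_FIELDS,
    Community,
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
from .travel import SpeedProfile

__all__ = ["read_scenario", "write_scenario", "ScenarioFormatError"]

INCIDENT_COLUMNS = (
    ("incident_id", "event_id", "lon", "lat", "priority", "required_type")
    + CHAIN_FIELDS
    + ("historic_unit_id", "hospital_id", "required_capability", "organization", "discontinued")
)


class ScenarioFormatError(ValueError):
    """Parse failure identifying file, row and column."""

    def __init__(self, file: str, row: Optional[int], column: str, message: str):
        self.file, self.row, self.column = file, row, column
        where = f"{file}" + (f", row {row}" if row is not None else "") + f", column {column}"
        super().__init__(f"{where}: {message}")


def _epoch(cfg: SimConfig) -> datetime:
    return datetime.fromisoformat(cfg.epoch)


def _fmt_time(seconds: Optional[int], epoch: datetime) -> str:
    if seconds is None:
        return ""
    return (epoch + timedelta(seconds=int(seconds))).isoformat()


def _parse_time_cell(cell: str, epoch: datetime) -> Optional[int]:
    cell = cell.strip()
    if not cell:
        return None
    return int((datetime.fromisoformat(cell) - epoch).total_seconds())


def _write_csv(path: Path, header: tuple[str, ...], rows: list[tuple]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def write_scenario(s: Scenario, path: str | Path, force: bool = False) -> None:
    """Write a scenario bundle; refuses to overwrite unless ``force``."""
    path = Path(path)
    if (path / "config.json").exists() and not force:
        raise FileExistsError(f"{path} already holds a bundle; pass force=True to overwrite")
    path.mkdir(parents=True, exist_ok=True)
    epoch = _epoch(s.config)

    rows = []
    for i in s.incidents:
        rows.append(
            (i.incident_id, i.event_id, repr(i.place.lon), repr(i.place.lat),
             i.priority.value, i.required_type.value)
            + tuple(_fmt_time(getattr(i.times, f), epoch) for f in CHAIN_FIELDS)
            + (i.historic_unit_id or "", i.hospital_id or "",
               i.required_capability or "", i.organization,
               "true" if i.discontinued else ""))
    _write_csv(path / "incidents.csv", INCIDENT_COLUMNS, rows)

    _write_csv(path / "events.csv", ("event_id", "incident_id"),
               [(e.event_id, iid) for e in s.events for iid in e.incident_ids])
    _write_csv(path / "units.csv", ("unit_id", "type", "base_id", "speed_profile_id"),
               [(u.unit_id, u.type.value, u.base_id, u.speed_profile_id) for u in s.units])
    _write_csv(path / "shifts.csv",
               ("unit_id", "start_s", "end_s", "recurrence", "weekdays"),
               [(sh.unit_id, sh.start, sh.end, sh.recurrence,
                 "|".join(str(d) for d in sorted(sh.weekdays))) for sh in s.shifts])
    _write_csv(path / "bases.csv", ("base_id", "lon", "lat", "name", "region"),
               [(b.base_id, repr(b.location.lon), repr(b.location.lat), b.name, b.region)
                for b in s.bases])
    _write_csv(path / "hospitals.csv", ("hospital_id", "lon", "lat", "capabilities"),
               [(h.hospital_id, repr(h.location.lon), repr(h.location.lat),
                 "|".join(sorted(h.capabilities))) for h in s.hospitals])

    if s.communities:
        features = []
        for c in s.communities:
            geom = c.geometry
            if geom is None and c.centroid is not None:
                geom = {"type": "Point", "coordinates": [c.centroid.lon, c.centroid.lat]}
            features.append({"type": "Feature",
                             "properties": {"community_id": c.community_id, "name": c.name},
                             "geometry": geom})
        (path / "communities.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, indent=1),
            encoding="utf-8")

    cfg = {"config": s.config.to_dict(),
           "speed_profiles": {pid: p.to_dict() for pid, p in (s.speed_profiles or {}).items()},
           "area": s.area}
    (path / "config.json").write_text(json.dumps(cfg, indent=1), encoding="utf-8")


def _read_rows(path: Path) -> tuple[list[str], list[list[str]]]:
    with path.open(newline="", encoding="utf-8") as fh:
        rd = csv.reader(fh)
        rows = list(rd)
    if not rows:
        raise ScenarioFormatError(path.name, None, "*", "empty file")
    return rows[0], rows[1:]


def read_scenario(path: str | Path) -> Scenario:
    """Read and validate a scenario bundle.

    Raises :class:`ScenarioFormatError` on parse problems (naming file, row
    and column) and ValueError listing the violations when the bundle fails
    structural validation (e.g. referential integrity).
    """
    path = Path(path)
    cfg_file = path / "config.json"
    if not cfg_file.exists():
        raise ScenarioFormatError("config.json", None, "*", f"missing in {path}")
    raw_cfg = json.loads(cfg_file.read_text(encoding="utf-8"))
    config = SimConfig.from_dict(raw_cfg.get("config", {}))
    profiles = {pid: SpeedProfile.from_dict(d)
                for pid, d in raw_cfg.get("speed_profiles", {}).items()}
    epoch = _epoch(config)

    for mandatory in ("incidents.csv", "events.csv", "units.csv", "shifts.csv", "bases.csv"):
        if not (path / mandatory).exists():
            raise ScenarioFormatError(mandatory, None, "*", f"missing mandatory table in {path}")

    def table(name, expected):
        header, rows = _read_rows(path / name)
        if header != list(expected):
            raise ScenarioFormatError(name, 0, "*",
                                      f"schema mismatch: expected columns {list(expected)}, got {header}")
        return rows

    incidents = []
    for r, row in enumerate(table("incidents.csv", INCIDENT_COLUMNS), start=1):
        cells = dict(zip(INCIDENT_COLUMNS, row))
        try:
            times = TimestampChain(**{f: _parse_time_cell(cells[f], epoch) for f in CHAIN_FIELDS})
        except ValueError as exc:
            raise ScenarioFormatError("incidents.csv", r, "timestamps", str(exc)) from exc
        try:
            incidents.append(IncidentRecord(
                incident_id=cells["incident_id"],
                event_id=cells["event_id"],
                place=GeoPoint(float(cells["lon"]), float(cells["lat"])),
                priority=Priority(cells["priority"]),
                required_type=UnitType(cells["required_type"]),
                times=times,
                historic_unit_id=cells["historic_unit_id"] or None,
                hospital_id=cells["hospital_id"] or None,
                required_capability=cells["required_capability"] or None,
                organization=cells["organization"] or "own",
                discontinued=cells["discontinued"].strip().lower() in ("1", "true", "yes"),
            ))
        except ValueError as exc:
            raise ScenarioFormatError("incidents.csv", r, "*", str(exc)) from exc

    members: dict[str, list[str]] = {}
    order: list[str] = []
    for r, row in enumerate(table("events.csv", ("event_id", "incident_id")), start=1):
        eid, iid = row
        if eid not in members:
            members[eid] = []
            order.append(eid)
        members[eid].append(iid)
    events = [EventGroup(eid, tuple(members[eid])) for eid in order]

    units = []
    for r, row in enumerate(table("units.csv", ("unit_id", "type", "base_id", "speed_profile_id")),
                            start=1):
        try:
            units.append(EMSUnit(row[0], UnitType(row[1]), row[2], row[3] or "default"))
        except ValueError as exc:
            raise ScenarioFormatError("units.csv", r, "type", str(exc)) from exc

    shifts = []
    for r, row in enumerate(
            table("shifts.csv", ("unit_id", "start_s", "end_s", "recurrence", "weekdays")),
            start=1):
        try:
            weekdays = frozenset(int(x) for x in row[4].split("|") if x.strip())
            shifts.append(Shift(row[0], int(row[1]), int(row[2]), row[3] or "daily", weekdays))
        except ValueError as exc:
            raise ScenarioFormatError("shifts.csv", r, "start_s/end_s", str(exc)) from exc

    bases = []
    for r, row in enumerate(table("bases.csv", ("base_id", "lon", "lat", "name", "region")),
                            start=1):
        try:
            bases.append(Base(row[0], GeoPoint(float(row[1]), float(row[2])), row[3], row[4]))
        except ValueError as exc:
            raise ScenarioFormatError("bases.csv", r, "lon/lat", str(exc)) from exc

    hospitals = []
    if (path / "hospitals.csv").exists():
        for r, row in enumerate(table("hospitals.csv", ("hospital_id", "lon", "lat", "capabilities")),
                                start=1):
            try:
                caps = frozenset(x for x in row[3].split("|") if x.strip())
                hospitals.append(Hospital(row[0], GeoPoint(float(row[1]), float(row[2])), caps))
            except ValueError as exc:
                raise ScenarioFormatError("hospitals.csv", r, "lon/lat", str(exc)) from exc

    communities = []
    geo_file = path / "communities.geojson"
    if geo_file.exists():
        fc = json.loads(geo_file.read_text(encoding="utf-8"))
        for feat in fc.get("features", []):
            props = feat.get("properties", {})
            geom = feat.get("geometry")
            centroid = None
            if geom and geom.get("type") == "Point":
                centroid = GeoPoint(*geom["coordinates"][:2])
                geom = None
            communities.append(Community(str(props.get("community_id", "")),
                                         str(props.get("name", "")), geom, centroid))

    scn = Scenario(incidents=incidents, events=events, units=units, shifts=shifts,
                   bases=bases, hospitals=hospitals, communities=communities,
                   config=config, speed_profiles=profiles, area=raw_cfg.get("area"))
    violations = validate_scenario(scn)
    if violations:
        head = "; ".join(f"{v.entity} {v.entity_id}: {v.message}" for v in violations[:5])
        raise ValueError(
            f"scenario bundle at {path} fails validation ({len(violations)} violations): {head}")
    return scn
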