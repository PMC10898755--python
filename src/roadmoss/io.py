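"""Readers and writers for observation tables, grids and result products.

Observations travel as a flat CSV with one row per tissue sample (site
attributes embedded); grids as CSV or GeoJSON point collections with
distance/side/stratum properties.  Validation errors name the offending row
and field.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import ELEMENTS, Observation, SIDES, SiteRecord
from .synthetic import GridPoint

__all__ = [
    "OBSERVATION_COLUMNS",
    "save_observations",
    "load_dataset",
    "save_grid_csv",
    "load_grid_csv",
    "save_grid_geojson",
    "load_grid_geojson",
]

OBSERVATION_COLUMNS = ["site_id", "easting", "northing", "distance_m", "side",
                       "element", "year", "replicate", "conc_mg_kg"]


def save_observations(path: str | Path, sites: list[SiteRecord],
                      observations: list[Observation]) -> None:
    """Write observations as CSV with site attributes embedded per row."""
    lookup = {s.site_id: s for s in sites}
    rows = []
    for o in observations:
        s = lookup[o.site_id]
        rows.append([s.site_id, s.easting, s.northing, s.distance_to_road, s.side,
                     o.element, o.year, o.replicate_index, o.concentration])
    # %.17g keeps doubles exact under write-then-read
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def load_dataset(path: str | Path) -> tuple[list[SiteRecord], list[Observation]]:
    """Read an observation CSV back into typed, validated records.

    Concentrations are mg/kg dry weight; coordinates planar meters.  Raises
    a ValueError naming the row (1-based data rows) and field on any
    invariant violation.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    sites: dict[str, SiteRecord] = {}
    observations: list[Observation] = []
    seen: set[tuple] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        def fail(field: str, why: str):
            raise ValueError(f"{path}: row {pos}, field {field!r}: {why}")
        if row.side not in SIDES:
            fail("side", f"unknown side {row.side!r}")
        if row.element not in ELEMENTS:
            fail("element", f"unknown element {row.element!r}")
        if not row.conc_mg_kg > 0:
            fail("conc_mg_kg", f"concentration must be > 0 (got {row.conc_mg_kg})")
        if not row.distance_m > 0:
            fail("distance_m", f"distance must be > 0 (got {row.distance_m})")
        sid = str(row.site_id)
        rec = SiteRecord(sid, float(row.easting), float(row.northing),
                         float(row.distance_m), str(row.side))
        if sid in sites:
            prev = sites[sid]
            if (prev.easting, prev.northing) != (rec.easting, rec.northing):
                fail("easting", f"site {sid!r} has inconsistent coordinates")
        else:
            sites[sid] = rec
        key = (sid, row.element, int(row.year), int(row.replicate))
        if key in seen:
            fail("replicate", f"duplicate observation key {key}")
        seen.add(key)
        observations.append(Observation(sid, str(row.element), int(row.year),
                                        int(row.replicate), float(row.conc_mg_kg)))
    return list(sites.values()), observations


GRID_COLUMNS = ["grid_id", "easting", "northing", "distance_m", "side", "stratum"]


def save_grid_csv(path: str | Path, grid: list[GridPoint]) -> None:
    pd.DataFrame(
        [[g.grid_id, g.easting, g.northing, g.distance_to_road, g.side, g.stratum]
         for g in grid], columns=GRID_COLUMNS).to_csv(path, index=False)


def load_grid_csv(path: str | Path) -> list[GridPoint]:
    df = pd.read_csv(path)
    missing = [c for c in GRID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [GridPoint(str(r.grid_id), float(r.easting), float(r.northing),
                      float(r.distance_m), str(r.side), int(r.stratum))
            for r in df.itertuples(index=False)]


def save_grid_geojson(path: str | Path, grid: list[GridPoint],
                      extra: pd.DataFrame | None = None) -> None:
    """GeoJSON point collection; optional per-point properties joined on
    grid_id (e.g. map summaries)."""
    props_by_id: dict[str, dict] = {}
    if extra is not None:
        for row in extra.to_dict(orient="records"):
            props_by_id[str(row["grid_id"])] = {
                k: v for k, v in row.items() if k != "grid_id"}
    features = []
    for g in grid:
        props = {"grid_id": g.grid_id, "distance_m": g.distance_to_road,
                 "side": g.side, "stratum": g.stratum}
        props.update(props_by_id.get(g.grid_id, {}))
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [g.easting, g.northing]},
            "properties": props,
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def load_grid_geojson(path: str | Path) -> list[GridPoint]:
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    grid = []
    for i, feat in enumerate(data["features"], start=1):
        try:
            x, y = feat["geometry"]["coordinates"]
            p = feat["properties"]
            grid.append(GridPoint(str(p["grid_id"]), float(x), float(y),
                                  float(p["distance_m"]), str(p["side"]),
                                  int(p["stratum"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: feature {i}: {exc}") from exc
    return grid
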