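"""File formats: fix/attribute CSVs, GeoJSON layers, ESRI ASCII grids.

All CSVs are UTF-8, comma-separated, "." decimal, with ISO-8601 UTC ("Z")
timestamps.  GeoJSON is written in planar projected metres with the CRS
noted in a top-level property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .errors import SchemaError
from .homerange import HomeRange
from .landscape import (
    CompositionRecord,
    ElevationGrid,
    LandscapeLayers,
    LatitudeMap,
)
from .trajectory import Trajectory

FIX_CSV_COLUMNS = ["animal_id", "timestamp", "x_m", "y_m", "lon", "lat"]
ATTR_CSV_COLUMNS = ["animal_id", "sex", "age_class", "study_area"]


# ---------------------------------------------------------------- fix tables

def write_fixes_csv(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    frames = []
    for traj in trajectories:
        f = traj.fixes.copy()
        f.insert(0, "animal_id", traj.animal_id)
        frames.append(f)
    table = pd.concat(frames, ignore_index=True)
    table["timestamp"] = table["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    table[FIX_CSV_COLUMNS].to_csv(path, index=False)


def read_fixes_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FIX_CSV_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: fix table missing columns {missing}")
    table["timestamp"] = pd.to_datetime(table["timestamp"], utc=True)
    return table


def write_attributes_csv(attributes: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ATTR_CSV_COLUMNS if c in attributes.columns]
    attributes[cols].to_csv(path, index=False)


def read_attributes_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ATTR_CSV_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: attribute table missing columns {missing}")
    return table


def trajectories_from_fixes(
    fixes: pd.DataFrame, attributes: pd.DataFrame
) -> list[Trajectory]:
    """Split a long fix table into per-animal trajectories with attributes."""
    attrs = attributes.set_index("animal_id")
    out = []
    for animal_id, group in fixes.groupby("animal_id", sort=True):
        if animal_id not in attrs.index:
            raise SchemaError(f"no attribute row for animal {animal_id!r}")
        a = attrs.loc[animal_id]
        out.append(
            Trajectory(
                animal_id=str(animal_id),
                sex=a["sex"],
                age_class=a["age_class"],
                study_area=a["study_area"],
                fixes=group.drop(columns="animal_id")
                .sort_values("timestamp")
                .reset_index(drop=True),
            )
        )
    return out


@dataclass
class FixTableReport:
    errors: list[str]
    fix_counts: dict[str, int]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_fix_table(path: str | Path) -> FixTableReport:
    """Schema and consistency checks on a fix CSV.

    Verifies required columns, timestamp parseability (offending rows are
    listed with their 1-based line numbers), and per-animal strictly
    increasing, duplicate-free timestamps.  Returns per-animal fix counts.
    """
    errors: list[str] = []
    table = pd.read_csv(path)
    missing = [c for c in FIX_CSV_COLUMNS if c not in table.columns]
    if missing:
        return FixTableReport([f"missing columns: {missing}"], {})
    parsed = pd.to_datetime(table["timestamp"], utc=True, errors="coerce", format="ISO8601")
    for idx in np.flatnonzero(parsed.isna().to_numpy()):
        errors.append(f"line {idx + 2}: unparseable timestamp {table['timestamp'].iloc[idx]!r}")
    table = table.assign(_ts=parsed)
    counts: dict[str, int] = {}
    for animal_id, g in table.groupby("animal_id", sort=True):
        counts[str(animal_id)] = len(g)
        ts = g["_ts"].dropna()
        if ts.duplicated().any():
            errors.append(f"animal {animal_id}: duplicated timestamps")
        elif not ts.is_monotonic_increasing:
            errors.append(f"animal {animal_id}: timestamps not increasing")
    for col in ("x_m", "y_m"):
        bad = ~np.isfinite(pd.to_numeric(table[col], errors="coerce"))
        for idx in np.flatnonzero(bad.to_numpy()):
            errors.append(f"line {idx + 2}: non-numeric {col}")
    return FixTableReport(errors, counts)


# ------------------------------------------------------------------ GeoJSON

def write_landscape_geojson(layers: LandscapeLayers, path: str | Path) -> None:
    features = []
    for cls, geoms in layers.class_polygons.items():
        for g in geoms:
            features.append(
                {"type": "Feature", "properties": {"class": cls}, "geometry": mapping(g)}
            )
    for name, g in layers.zone_polygons.items():
        features.append(
            {"type": "Feature", "properties": {"class": f"zone:{name}"}, "geometry": mapping(g)}
        )
    doc = {
        "type": "FeatureCollection",
        "crs_note": "planar projected metres (synthetic)",
        "features": features,
    }
    if layers.latitude_map is not None:
        doc["latitude_map"] = {
            "lat0": layers.latitude_map.lat0,
            "metres_per_degree": layers.latitude_map.metres_per_degree,
        }
    Path(path).write_text(json.dumps(doc))


def read_landscape_geojson(path: str | Path, elevation: ElevationGrid | None = None) -> LandscapeLayers:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    class_polygons: dict[str, list] = {}
    zone_polygons: dict[str, object] = {}
    for feat in doc.get("features", []):
        cls = feat.get("properties", {}).get("class")
        if cls is None:
            raise SchemaError(f"{path}: feature without a 'class' property")
        geom = shape(feat["geometry"])
        if cls.startswith("zone:"):
            zone_polygons[cls.split(":", 1)[1]] = geom
        else:
            class_polygons.setdefault(cls, []).append(geom)
    lm = doc.get("latitude_map")
    latitude_map = (
        LatitudeMap(lm["lat0"], lm.get("metres_per_degree", 111320.0)) if lm else None
    )
    # order zone bands south -> north by their centroid y
    zone_polygons = dict(
        sorted(zone_polygons.items(), key=lambda kv: kv[1].centroid.y)
    )
    return LandscapeLayers(
        class_polygons=class_polygons,
        zone_polygons=zone_polygons,
        elevation=elevation,
        latitude_map=latitude_map,
    )


def write_home_ranges_geojson(ranges: Iterable[HomeRange], path: str | Path) -> None:
    features = []
    for hr in ranges:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "animal_id": hr.animal_id,
                    "estimator": hr.estimator,
                    "level": hr.level,
                    "k": hr.k,
                    "area_km2": hr.area_km2,
                },
                "geometry": mapping(hr.geometry),
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs_note": "planar projected metres (synthetic)",
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_home_ranges_geojson(path: str | Path) -> list[HomeRange]:
    doc = json.loads(Path(path).read_text())
    out = []
    for feat in doc.get("features", []):
        p = feat.get("properties", {})
        geom = shape(feat["geometry"])
        out.append(
            HomeRange(
                animal_id=p["animal_id"],
                estimator=p["estimator"],
                level=float(p["level"]),
                k=p.get("k"),
                geometry=geom,
                area_km2=float(p.get("area_km2", geom.area / 1e6)),
            )
        )
    return out


# ------------------------------------------------------------- ESRI ASCII

def write_esri_ascii(grid: ElevationGrid, path: str | Path) -> None:
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.xll:.3f}\n"
        f"yllcorner {grid.yll:.3f}\n"
        f"cellsize {grid.cellsize:.3f}\n"
        f"NODATA_value {grid.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt="%.2f")


def read_esri_ascii(path: str | Path) -> ElevationGrid:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    return ElevationGrid(
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        values=values,
        nodata=header.get("nodata_value", -9999.0),
    )


# ----------------------------------------------------------------- tables

def write_area_table_csv(ranges: Iterable[HomeRange], path: str | Path) -> None:
    """Per-animal area table (animal, estimator, level, k, area)."""
    rows = [
        {
            "animal_id": hr.animal_id,
            "estimator": hr.estimator,
            "level": hr.level,
            "k": hr.k if hr.k is not None else "",
            "area_km2": hr.area_km2,
        }
        for hr in ranges
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_composition_csv(records: Iterable[CompositionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "prop_agriculture": r.prop_agriculture,
                "prop_settlement": r.prop_settlement,
                "mean_elevation_m": r.mean_elevation_m,
                "centroid_latitude": r.centroid_latitude,
                "zone": r.zone,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_config_echo(config: object, path: str | Path) -> None:
    """Flat key=value echo of a dataclass-style configuration."""
    lines = []
    for key, val in vars(config).items():
        lines.append(f"{key}={val!r}")
    Path(path).write_text("\n".join(lines) + "\n")
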