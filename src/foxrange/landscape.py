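"""Landscape composition of home ranges.

Given a home-range polygon and vector/raster landscape layers this module
computes the covariates of the size analysis: proportion of the range in
agriculture and in human settlement (polygon intersection, with settlement
taking precedence where the classes would overlap), mean elevation (zonal
statistics on a grid, or length-weighted elevation contours), centroid
latitude, and the vegetation zone containing the centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .errors import (
    DegenerateGeometryError,
    ZonalStatisticsError,
    ZoneAssignmentError,
)


@dataclass
class ElevationGrid:
    """ESRI-ASCII-style elevation raster.

    ``values`` is (nrows, ncols) with row 0 the northernmost row;
    ``xll``/``yll`` are the lower-left *corner* coordinates in metres.
    """

    xll: float
    yll: float
    cellsize: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cellsize <= 0:
            raise DegenerateGeometryError("grid cell size must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """x centres (ncols,) and y centres (nrows, north to south)."""
        xs = self.xll + self.cellsize * (np.arange(self.ncols) + 0.5)
        ys = self.yll + self.cellsize * (np.arange(self.nrows)[::-1] + 0.5)
        return xs, ys


@dataclass
class LatitudeMap:
    """Affine projected-y -> latitude mapping for the synthetic planar world."""

    lat0: float  # latitude at y = 0
    metres_per_degree: float = 111320.0

    def to_latitude(self, y: float | np.ndarray):
        return self.lat0 + np.asarray(y, dtype=float) / self.metres_per_degree

    def to_y(self, lat: float | np.ndarray):
        return (np.asarray(lat, dtype=float) - self.lat0) * self.metres_per_degree


@dataclass
class LandscapeLayers:
    """Vector land-cover classes, vegetation zones and elevation."""

    class_polygons: dict[str, list[BaseGeometry]]
    zone_polygons: dict[str, BaseGeometry]  # insertion order: south -> north
    elevation: ElevationGrid | None = None
    contours: list[tuple[float, BaseGeometry]] | None = None
    latitude_map: LatitudeMap | None = None
    _trees: dict[str, STRtree] = field(default_factory=dict, repr=False)

    def tree(self, class_name: str) -> STRtree:
        if class_name not in self._trees:
            self._trees[class_name] = STRtree(self.class_polygons.get(class_name, []))
        return self._trees[class_name]


@dataclass
class CompositionRecord:
    animal_id: str
    prop_agriculture: float
    prop_settlement: float
    mean_elevation_m: float
    centroid_latitude: float
    zone: str


def _class_intersection(polygon: BaseGeometry, layers: LandscapeLayers, class_name: str) -> BaseGeometry:
    geoms = layers.class_polygons.get(class_name, [])
    if not geoms:
        return Point()  # empty geometry
    tree = layers.tree(class_name)
    hits = tree.query(polygon)
    if len(hits) == 0:
        return Point()
    return polygon.intersection(unary_union([geoms[i] for i in hits]))


def proportion_in_class(polygon: BaseGeometry, layers: LandscapeLayers, class_name: str) -> float:
    """Fraction of the home-range area covered by a land-cover class.

    Where agriculture and settlement polygons would overlap, settlement
    wins: agriculture is only counted outside the settlement class.
    """
    if polygon.area <= 0.0:
        raise DegenerateGeometryError(
            "class proportion undefined for a zero-area home range"
        )
    inter = _class_intersection(polygon, layers, class_name)
    area = inter.area
    if class_name == "agriculture" and area > 0.0:
        overlap = _class_intersection(inter, layers, "settlement")
        area -= overlap.area
    return area / polygon.area


def mean_elevation_zonal(polygon: BaseGeometry, grid: ElevationGrid) -> float:
    """Mean of grid values whose cell centres fall inside the polygon.

    Boundary-inclusive (a centre on the polygon edge counts).  Raises if no
    centre is inside — use a finer grid or the contour method.
    """
    xs, ys = grid.cell_centres()
    minx, miny, maxx, maxy = polygon.bounds
    ci = np.where((xs >= minx - grid.cellsize) & (xs <= maxx + grid.cellsize))[0]
    ri = np.where((ys >= miny - grid.cellsize) & (ys <= maxy + grid.cellsize))[0]
    if len(ci) == 0 or len(ri) == 0:
        raise ZonalStatisticsError("polygon lies entirely outside the elevation grid")
    gx, gy = np.meshgrid(xs[ci], ys[ri])
    pts = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
    inside = shapely.covers(polygon, pts).reshape(gx.shape)
    if not inside.any():
        raise ZonalStatisticsError(
            "no grid cell centre inside the polygon; refine the grid or use "
            "the contour method"
        )
    vals = grid.values[np.ix_(ri, ci)][inside]
    vals = vals[vals != grid.nodata]
    if len(vals) == 0:
        raise ZonalStatisticsError("only NODATA cells inside the polygon")
    return float(vals.mean())


def grid_value_at(grid: ElevationGrid, x: float, y: float) -> float:
    """Value of the grid cell containing (x, y) (nearest cell at the edge)."""
    col = int(np.clip((x - grid.xll) / grid.cellsize, 0, grid.ncols - 1))
    row_from_south = int(np.clip((y - grid.yll) / grid.cellsize, 0, grid.nrows - 1))
    val = float(grid.values[grid.nrows - 1 - row_from_south, col])
    if val == grid.nodata:
        raise ZonalStatisticsError(f"NODATA at ({x:.0f}, {y:.0f})")
    return val


def mean_elevation_contours(
    polygon: BaseGeometry, contours: list[tuple[float, BaseGeometry]]
) -> float:
    """Length-weighted mean elevation of contour segments clipped to the polygon."""
    total_len = 0.0
    weighted = 0.0
    for elev, line in contours:
        clipped = polygon.intersection(line)
        if clipped.is_empty:
            continue
        total_len += clipped.length
        weighted += elev * clipped.length
    if total_len <= 0.0:
        raise ZonalStatisticsError("no elevation contour intersects the polygon")
    return weighted / total_len


def centroid_latitude(polygon: BaseGeometry, latitude_map: LatitudeMap) -> float:
    """Latitude of the area-weighted centroid (of the union, for multi-part ranges)."""
    if polygon.area <= 0.0:
        raise DegenerateGeometryError("centroid latitude undefined for zero-area polygon")
    return float(latitude_map.to_latitude(polygon.centroid.y))


def assign_zone(point: Point, zone_polygons: dict[str, BaseGeometry]) -> str:
    """Vegetation zone containing the point; shared boundaries go south.

    ``zone_polygons`` must be ordered south to north; the first (most
    southern) zone covering the point wins, so a centroid exactly on a zone
    border is assigned to the southernmost of the touching zones.
    """
    for name, poly in zone_polygons.items():
        if poly.covers(point):
            return name
    raise ZoneAssignmentError(f"point {point.wkt} lies in no vegetation zone")


def compose_home_range(
    animal_id: str,
    polygon: BaseGeometry,
    layers: LandscapeLayers,
    elevation_method: str = "zonal",
) -> CompositionRecord:
    """All composition covariates of one home range in a single record."""
    if elevation_method == "zonal":
        if layers.elevation is None:
            raise ZonalStatisticsError("layers carry no elevation grid")
        try:
            elev = mean_elevation_zonal(polygon, layers.elevation)
        except ZonalStatisticsError:
            # range smaller than a grid cell: sample the nearest cell at the
            # centroid instead of failing the whole composition
            elev = grid_value_at(layers.elevation, polygon.centroid.x, polygon.centroid.y)
    elif elevation_method == "contours":
        if not layers.contours:
            raise ZonalStatisticsError("layers carry no elevation contours")
        elev = mean_elevation_contours(polygon, layers.contours)
    else:
        raise ValueError(f"unknown elevation method {elevation_method!r}")
    lat = centroid_latitude(polygon, layers.latitude_map)
    zone = assign_zone(polygon.centroid, layers.zone_polygons)
    return CompositionRecord(
        animal_id=animal_id,
        prop_agriculture=proportion_in_class(polygon, layers, "agriculture"),
        prop_settlement=proportion_in_class(polygon, layers, "settlement"),
        mean_elevation_m=elev,
        centroid_latitude=lat,
        zone=zone,
    )
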