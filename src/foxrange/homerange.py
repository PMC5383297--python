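"""Home-range estimators: percent-MCP and LoCoH-k isopleths.

Both estimators work in projected planar metres and report areas in km^2.
The minimum convex polygon (MCP) at level p keeps the ceil(p*n) fixes
nearest the arithmetic-mean centroid of all fixes and takes their convex
hull.  LoCoH-k builds, for every fix, the convex hull of that fix and its
k-1 nearest neighbours, then unions hulls in order of increasing area until
the union covers the target fraction of fixes — a nonparametric estimator
that hugs hard-edged range boundaries far more closely than the MCP.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import DomainError, InsufficientDataError
from .trajectory import Trajectory

M2_PER_KM2 = 1.0e6


@dataclass
class Hull:
    """A convex hull with its vertices (CCW), area in m^2 and a degeneracy flag."""

    vertices: np.ndarray
    area_m2: float
    degenerate: bool

    @property
    def geometry(self) -> BaseGeometry:
        if not self.degenerate:
            return Polygon(self.vertices)
        if len(self.vertices) >= 2:
            return LineString(self.vertices)
        return Point(self.vertices[0])


@dataclass
class HomeRange:
    animal_id: str
    estimator: str  # "MCP" or "LoCoH-k"
    level: float
    k: int | None
    geometry: BaseGeometry
    area_km2: float
    degenerate: bool = False


@dataclass
class AreaObservationCurve:
    """100% MCP area as a function of monitoring duration (30-day steps)."""

    animal_id: str
    durations: np.ndarray  # days
    areas_km2: np.ndarray
    degenerate: np.ndarray  # bool per window


def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points: np.ndarray) -> Hull:
    """Convex hull by the monotone-chain construction.

    Collinear or too-few input yields a degenerate zero-area hull (the
    extreme points), flagged rather than raised: downstream estimators
    propagate the flag.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return Hull(pts, 0.0, True)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def half(chain_pts):
        chain: list[np.ndarray] = []
        for p in chain_pts:
            while len(chain) >= 2 and _cross(chain[-2], chain[-1], p) <= 0.0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(pts)
    upper = half(pts[::-1])
    verts = np.array(lower[:-1] + upper[:-1])
    if len(verts) < 3:
        # all points collinear: keep the two extremes
        return Hull(np.array([pts[0], pts[-1]]), 0.0, True)
    x, y = verts[:, 0], verts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return Hull(verts, float(area), False)


def mcp(points: np.ndarray, level: float = 1.0, animal_id: str = "") -> HomeRange:
    """Percent minimum convex polygon.

    Retains the ceil(level*n) points nearest the arithmetic-mean centroid of
    *all* points (fixed centroid, single pass; distance ties broken by the
    earlier fix, i.e. input order) and returns the hull of the retained set.
    """
    pts = np.asarray(points, dtype=float)
    if not 0.0 < level <= 1.0:
        raise DomainError(f"isopleth level must be in (0, 1], got {level}")
    n = len(pts)
    if n < 3:
        hull = convex_hull(pts)
        return HomeRange(animal_id, "MCP", level, None, hull.geometry, 0.0, True)
    m = math.ceil(level * n)
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1)
    keep = np.argsort(d, kind="stable")[:m]
    hull = convex_hull(pts[np.sort(keep)])
    return HomeRange(
        animal_id,
        "MCP",
        level,
        None,
        hull.geometry,
        hull.area_m2 / M2_PER_KM2,
        hull.degenerate,
    )


def choose_k(n_fixes: int) -> int:
    """Number of neighbours for LoCoH-k: round-half-up of sqrt(n), floored at 3."""
    if n_fixes < 9:
        raise DomainError(
            f"LoCoH-k needs at least 9 fixes (k would fall below 3), got {n_fixes}"
        )
    return max(3, int(math.floor(math.sqrt(n_fixes) + 0.5)))


def _local_hull_geometries(pts: np.ndarray, k: int) -> list[BaseGeometry]:
    """Per-root local hulls, sorted by (area ascending, root index)."""
    n = len(pts)
    # pairwise squared distances; n is at most a few thousand fixes
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    idx = np.arange(n)
    entries: list[tuple[float, int, BaseGeometry]] = []
    for i in range(n):
        nbrs = np.lexsort((idx, d2[i]))[:k]  # ties by ascending point index
        hull = convex_hull(pts[nbrs])
        entries.append((hull.area_m2, i, hull.geometry))
    entries.sort(key=lambda e: (e[0], e[1]))
    return [geom for _, _, geom in entries]


def locoh_isopleths(
    points: np.ndarray,
    k: int,
    levels: tuple[float, ...] = (0.9, 0.95, 1.0),
    animal_id: str = "",
) -> dict[float, HomeRange]:
    """LoCoH-k home ranges at several isopleth levels in one pass.

    Local hulls (each root point plus its k-1 nearest Euclidean neighbours,
    distance ties by point index) are sorted by ascending area and unioned
    until the union covers at least ceil(level*n) of the input points,
    boundary-inclusive.  Because every level uses a prefix of the same
    sorted hull list, isopleths are nested by construction.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if not 3 <= k <= n:
        raise DomainError(f"k must be in [3, n={n}], got {k}")
    for level in levels:
        if not 0.0 < level <= 1.0:
            raise DomainError(f"isopleth level must be in (0, 1], got {level}")
    geoms = _local_hull_geometries(pts, k)
    point_geoms = shapely.points(pts)

    cache: dict[int, tuple[BaseGeometry, int]] = {}

    def union_and_coverage(m: int) -> tuple[BaseGeometry, int]:
        if m not in cache:
            u = unary_union(geoms[:m])
            cache[m] = (u, int(shapely.covers(u, point_geoms).sum()))
        return cache[m]

    out: dict[float, HomeRange] = {}
    for level in levels:
        target = math.ceil(level * n)
        lo, hi = 1, n
        while lo < hi:
            mid = (lo + hi) // 2
            if union_and_coverage(mid)[1] >= target:
                hi = mid
            else:
                lo = mid + 1
        union, covered = union_and_coverage(lo)
        degenerate = union.area <= 0.0
        if degenerate:
            warnings.warn(
                f"{animal_id or 'LoCoH-k'}: all local hulls degenerate "
                "(duplicate-heavy input); zero-area home range",
                stacklevel=2,
            )
        if covered < target:
            raise DomainError(
                f"{animal_id}: LoCoH union of all hulls covers {covered} < {target} points"
            )
        out[level] = HomeRange(
            animal_id, "LoCoH-k", level, k, union, union.area / M2_PER_KM2, degenerate
        )
    return out


def locoh_k(points: np.ndarray, k: int, level: float = 0.9, animal_id: str = "") -> HomeRange:
    """LoCoH-k home range at a single isopleth level."""
    return locoh_isopleths(points, k, (level,), animal_id)[level]


def area_observation_curve(traj: Trajectory, increment_days: float = 30.0) -> AreaObservationCurve:
    """100% MCP area on all fixes within d days of the first, d = 30, 60, ...

    Nested point sets make the curve non-decreasing; a window with fewer
    than 3 fixes is flagged degenerate with zero area.
    """
    t = traj.t_days
    span = t[-1]
    if span < increment_days:
        raise InsufficientDataError(
            f"{traj.animal_id}: monitoring span {span:.1f} d shorter than one "
            f"{increment_days:.0f}-day increment"
        )
    xy = traj.xy
    durations, areas, flags = [], [], []
    d = increment_days
    while d <= span + 1e-9:
        sub = xy[t <= d]
        hr = mcp(sub, 1.0, traj.animal_id)
        durations.append(d)
        areas.append(hr.area_km2)
        flags.append(hr.degenerate)
        d += increment_days
    return AreaObservationCurve(
        traj.animal_id, np.array(durations), np.array(areas), np.array(flags)
    )


def asymptote_fraction(curve: AreaObservationCurve, at_day: float, ref_day: float) -> float:
    """area(at_day) / area(ref_day) — how much of the eventual range is seen early."""
    def lookup(day: float) -> float:
        hit = np.isclose(curve.durations, day)
        if not hit.any():
            raise DomainError(f"day {day} not on the {curve.animal_id} curve grid")
        return float(curve.areas_km2[hit][0])

    ref = lookup(ref_day)
    if ref <= 0.0:
        raise DomainError(f"{curve.animal_id}: zero reference area at day {ref_day}")
    return lookup(at_day) / ref
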