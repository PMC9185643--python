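"""Survey-route planning: polygon tessellation, zigzag ordering, sub-routes, mission I/O.

Pipeline: a field polygon (WGS-84 vertex ring) is projected into a local
tangent plane anchored at the bounding box's bottom-left corner; the plane is
tiled with camera footprints on a regular grid; tiles are kept when their
center or any corner lies inside the polygon (modified ray-casting inclusion
rule); kept tiles are visited in a boustrophedon/zigzag order (columns
left-to-right, alternating up/down); tile centers become survey waypoints.
Long missions are split into battery-safe sub-routes by inserting go-home
waypoints whenever continuing to the next waypoint and returning home would
exceed a range budget d_max. Missions export to a versioned JSON schema or
the QGC WPL 110 plain-text dialect understood by Mission-Planner-class
ground stations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

from .camera import Footprint
from .errors import (
    EmptyRouteError,
    InvalidInputError,
    ParseError,
    UnreachableWaypointError,
)
from .geo import (
    MODE_CORRECTED,
    WGS84_MEAN,
    EarthModel,
    GeoPoint,
    LocalOffset,
    advance_point,
    haversine_distance,
    initial_bearing,
    point_to_offset,
)

__all__ = [
    "SurveyPolygon",
    "Tile",
    "Waypoint",
    "RoutePlan",
    "point_in_polygon",
    "keep_tile",
    "tessellate",
    "order_zigzag",
    "build_route",
    "insert_gohome",
    "export_route",
    "import_route",
    "load_polygon_geojson",
    "plan_survey",
]

KIND_SURVEY = "survey"
KIND_GO_HOME = "go_home"

# MAVLink command ids used in the WPL dialect
_MAV_CMD_NAV_WAYPOINT = 16
_MAV_CMD_NAV_RETURN_TO_LAUNCH = 20
_WPL_HEADER = "QGC WPL 110"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SurveyPolygon:
    """Ordered WGS-84 vertex ring of the field area (implicit closure).

    Must have >= 3 vertices, no duplicate consecutive vertices, and no
    self-intersections.
    """

    vertices: tuple[GeoPoint, ...]
    name: str = ""
    description: str = ""

    def __post_init__(self):
        verts = tuple(self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) >= 2 and verts[0] == verts[-1]:
            raise InvalidInputError(
                "ring closure is implicit; drop the repeated final vertex"
            )
        if len(verts) < 3:
            raise InvalidInputError(f"polygon needs >= 3 vertices, got {len(verts)}")
        for a, b in zip(verts, verts[1:] + verts[:1]):
            if a == b:
                raise InvalidInputError(f"duplicate consecutive vertex {a}")
        ring = [(p.lon, p.lat) for p in verts]
        if abs(_shoelace(ring)) == 0.0:
            raise InvalidInputError("polygon has zero area")
        if _self_intersects(ring):
            raise InvalidInputError("polygon is self-intersecting")


@dataclass(frozen=True)
class Tile:
    """One camera footprint placed on the survey grid.

    ``local_ij`` are integer grid coordinates (column i, row j); ``corners``
    is the axis-aligned footprint rectangle around ``center``, ordered
    (SW, SE, NE, NW).
    """

    center: GeoPoint
    corners: tuple[GeoPoint, GeoPoint, GeoPoint, GeoPoint]
    local_ij: tuple[int, int]
    local_center: tuple[float, float] = (0.0, 0.0)  # meters in the planning plane


@dataclass(frozen=True)
class Waypoint:
    location: GeoPoint
    altitude: float  # meters AGL
    wait_time: float = 0.0  # seconds of hover at the waypoint
    heading: float = 0.0  # degrees in [0, 360)
    kind: str = KIND_SURVEY

    def __post_init__(self):
        if not self.altitude > 0:
            raise InvalidInputError(f"altitude must be > 0, got {self.altitude}")
        if self.wait_time < 0:
            raise InvalidInputError(f"wait_time must be >= 0, got {self.wait_time}")
        if self.kind not in (KIND_SURVEY, KIND_GO_HOME):
            raise InvalidInputError(f"unknown waypoint kind {self.kind!r}")
        object.__setattr__(self, "heading", self.heading % 360.0)


@dataclass(frozen=True)
class RoutePlan:
    """An ordered mission: waypoints, launch/return point, and metadata."""

    waypoints: tuple[Waypoint, ...]
    home: GeoPoint
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "waypoints", tuple(self.waypoints))
        if not self.waypoints:
            raise EmptyRouteError("a route needs at least one waypoint")
        for w in self.waypoints:
            if w.kind == KIND_GO_HOME and w.location != self.home:
                raise InvalidInputError(
                    f"go_home waypoint at {w.location} is not at home {self.home}"
                )

    @property
    def survey_waypoints(self) -> tuple[Waypoint, ...]:
        return tuple(w for w in self.waypoints if w.kind == KIND_SURVEY)

    def total_length(self, earth: EarthModel = WGS84_MEAN) -> float:
        """Flown ground distance in meters, home -> ... -> final return home."""
        pts = [self.home] + [w.location for w in self.waypoints] + [self.home]
        return sum(haversine_distance(a, b, earth) for a, b in zip(pts, pts[1:]))


# ---------------------------------------------------------------------------
# planar helpers


def _shoelace(ring: list[tuple[float, float]]) -> float:
    area = 0.0
    n = len(ring)
    for k in range(n):
        x1, y1 = ring[k]
        x2, y2 = ring[(k + 1) % n]
        area += x1 * y2 - x2 * y1
    return area / 2.0


def _segments_properly_intersect(p, q, r, s) -> bool:
    """True if open segments pq and rs cross (shared endpoints don't count)."""

    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    o1, o2 = orient(p, q, r), orient(p, q, s)
    o3, o4 = orient(r, s, p), orient(r, s, q)
    return (o1 * o2 < 0) and (o3 * o4 < 0)


def _self_intersects(ring: list[tuple[float, float]]) -> bool:
    n = len(ring)
    edges = [(ring[k], ring[(k + 1) % n]) for k in range(n)]
    for a in range(n):
        for b in range(a + 1, n):
            if b == a + 1 or (a == 0 and b == n - 1):
                continue  # adjacent edges share a vertex
            if _segments_properly_intersect(*edges[a], *edges[b]):
                return True
    return False


# ---------------------------------------------------------------------------
# inclusion and tessellation


def point_in_polygon(p: tuple[float, float], ring: list[tuple[float, float]]) -> bool:
    """Even-odd ray-casting inclusion test in a planar metric frame.

    Casts a horizontal ray from ``p`` toward +x and counts proper edge
    crossings: odd means inside. Edges are treated half-open (the strict
    ``y > py`` test), so every boundary point gets a deterministic answer:
    lower/left boundary points are inside, upper/right are outside, and a
    point shared by two polygons tiling the plane is claimed by exactly one.
    """
    if len(ring) < 3:
        raise InvalidInputError(f"ring needs >= 3 vertices, got {len(ring)}")
    if _shoelace(ring) == 0.0:
        raise InvalidInputError("degenerate ring (zero area)")
    px, py = p
    inside = False
    n = len(ring)
    for k in range(n):
        x1, y1 = ring[k]
        x2, y2 = ring[(k + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x2 + (py - y2) * (x1 - x2) / (y1 - y2)
            if px < x_cross:
                inside = not inside
    return inside


def _tile_test_points(cx: float, cy: float, fp: Footprint):
    hx, hy = fp.d_fov_x / 2.0, fp.d_fov_y / 2.0
    corners = [(cx - hx, cy - hy), (cx + hx, cy - hy), (cx + hx, cy + hy), (cx - hx, cy + hy)]
    return (cx, cy), corners


def keep_tile(
    center: tuple[float, float], fp: Footprint, ring: list[tuple[float, float]]
) -> bool:
    """Keep a tile if its center or any of its 4 corners lies inside the ring.

    The plain center-only rule leaves gaps at the polygon boundary; admitting
    tiles with any vertex inside completes the coverage.
    """
    c, corners = _tile_test_points(center[0], center[1], fp)
    return point_in_polygon(c, ring) or any(point_in_polygon(q, ring) for q in corners)


def tessellate(
    poly: SurveyPolygon,
    fp: Footprint,
    step: LocalOffset,
    earth: EarthModel = WGS84_MEAN,
    mode: str = MODE_CORRECTED,
) -> list[Tile]:
    """Fill the polygon with footprint tiles, bottom-to-top and left-to-right.

    The grid is anchored at the bounding box's bottom-left corner: the first
    candidate tile has its bottom-left corner on that reference point, and
    subsequent centers advance by ``step`` (footprint times the step
    fraction). Tiles passing :func:`keep_tile` are returned sorted by grid
    coordinates (i, j).

    Ring coordinates are snapped to 1 um before tiling so the half-open
    boundary rule is not defeated by the rounding noise of the
    degree-to-meter round trip (a nominal 120 m side otherwise projects to
    120.0000000001 m and boundary corners test "just inside").
    """
    if not (0 < step.dx <= fp.d_fov_x and 0 < step.dy <= fp.d_fov_y):
        raise InvalidInputError(
            f"step {step} must be positive and <= footprint ({fp}) componentwise"
        )
    snap_m = 1e-6
    ref = GeoPoint(min(p.lat for p in poly.vertices), min(p.lon for p in poly.vertices))
    ring = []
    for p in poly.vertices:
        off = point_to_offset(p, ref, earth, mode)
        ring.append((round(off.dx / snap_m) * snap_m, round(off.dy / snap_m) * snap_m))
    width = max(x for x, _ in ring)
    height = max(y for _, y in ring)

    hx, hy = fp.d_fov_x / 2.0, fp.d_fov_y / 2.0
    n_i = int(math.floor(width / step.dx)) + 2
    n_j = int(math.floor(height / step.dy)) + 2
    tiles: list[Tile] = []
    for i in range(n_i):
        cx = hx + i * step.dx
        for j in range(n_j):
            cy = hy + j * step.dy
            if not keep_tile((cx, cy), fp, ring):
                continue
            _, corners_local = _tile_test_points(cx, cy, fp)
            center = advance_point(ref, LocalOffset(cx, cy), earth, mode)
            corners = tuple(
                advance_point(ref, LocalOffset(qx, qy), earth, mode)
                for qx, qy in corners_local
            )
            tiles.append(Tile(center, corners, (i, j), (cx, cy)))
    if not tiles:
        raise EmptyRouteError("no tile center or corner falls inside the polygon")
    tiles.sort(key=lambda t: t.local_ij)
    return tiles


def order_zigzag(tiles: list[Tile]) -> list[Tile]:
    """Serpentine visiting order: columns left->right, alternating up/down.

    The first visited column is swept bottom-to-top, the next top-to-bottom,
    and so on (Up, Right, Down, Right, ...). Empty input returns empty.
    """
    if not tiles:
        return []
    columns: dict[int, list[Tile]] = {}
    for t in tiles:
        columns.setdefault(t.local_ij[0], []).append(t)
    ordered: list[Tile] = []
    for k, i in enumerate(sorted(columns)):
        col = sorted(columns[i], key=lambda t: t.local_ij[1], reverse=(k % 2 == 1))
        ordered.extend(col)
    return ordered


# ---------------------------------------------------------------------------
# route assembly


def build_route(
    tiles_ordered: list[Tile],
    altitude: float,
    wait_time: float = 0.0,
    home: GeoPoint | None = None,
    metadata: dict | None = None,
) -> RoutePlan:
    """One survey waypoint per tile center, constant altitude and wait time.

    Heading is the bearing of the incoming leg (0 deg for the first
    waypoint). ``home`` defaults to the first waypoint's location.
    """
    if not tiles_ordered:
        raise EmptyRouteError("cannot build a route from zero tiles")
    waypoints = []
    prev: GeoPoint | None = None
    for t in tiles_ordered:
        heading = 0.0 if prev is None else initial_bearing(prev, t.center)
        waypoints.append(
            Waypoint(t.center, altitude=altitude, wait_time=wait_time, heading=heading)
        )
        prev = t.center
    home = home if home is not None else waypoints[0].location
    return RoutePlan(tuple(waypoints), home=home, metadata=dict(metadata or {}))


def insert_gohome(
    route: RoutePlan, d_max: float, earth: EarthModel = WGS84_MEAN
) -> RoutePlan:
    """Split a mission into battery-safe sub-routes by inserting go-home stops.

    Scanning waypoints in order, at waypoint w_i the risk of continuing is
    r = d(w_i, w_{i+1}) + d(w_{i+1}, home): the 2-D ground distance to reach
    the next waypoint plus the straight-line return home from there. If
    r > d_max a go-home waypoint is inserted after w_i (the UAV returns for a
    battery change and resumes toward w_{i+1}). Afterwards every flown leg
    a -> b satisfies d(a, b) + d(b, home) <= d_max.

    Raises :class:`UnreachableWaypointError` if any single waypoint cannot be
    reached from home and returned from within d_max (2 d(home, w) > d_max).
    """
    if d_max <= 0:
        raise InvalidInputError(f"d_max must be positive, got {d_max}")
    home = route.home
    d_home = {}
    for idx, w in enumerate(route.waypoints):
        if w.kind != KIND_SURVEY:
            continue
        d = haversine_distance(home, w.location, earth)
        d_home[idx] = d
        if 2.0 * d > d_max:
            raise UnreachableWaypointError(
                f"waypoint {idx} at {w.location}: round trip from home is "
                f"{2.0 * d:.1f} m > d_max {d_max:.1f} m"
            )
    survey = [(idx, w) for idx, w in enumerate(route.waypoints) if w.kind == KIND_SURVEY]
    out: list[Waypoint] = []
    for k, (idx, w) in enumerate(survey):
        out.append(w)
        if k + 1 < len(survey):
            nxt_idx, nxt = survey[k + 1]
            risk = haversine_distance(w.location, nxt.location, earth) + d_home[nxt_idx]
            if risk > d_max:
                out.append(
                    Waypoint(
                        home,
                        altitude=w.altitude,
                        wait_time=0.0,
                        heading=initial_bearing(w.location, home),
                        kind=KIND_GO_HOME,
                    )
                )
    return RoutePlan(tuple(out), home=home, metadata=dict(route.metadata))


def plan_survey(
    poly: SurveyPolygon,
    cam,
    gsd: float,
    overlap=None,
    wait_time: float = 5.0,
    home: GeoPoint | None = None,
    d_max: float | None = None,
    earth: EarthModel = WGS84_MEAN,
    mode: str = MODE_CORRECTED,
) -> RoutePlan:
    """End-to-end planning: polygon + camera + GSD -> zigzag mission.

    Convenience wrapper over flight_height -> ground_footprint ->
    step_distances -> tessellate -> order_zigzag -> build_route, optionally
    followed by :func:`insert_gohome` when ``d_max`` is given.
    """
    from .camera import OverlapSpec, flight_height, ground_footprint, step_distances

    overlap = overlap or OverlapSpec()
    h = flight_height(gsd, cam)
    fp = ground_footprint(h, cam)
    step = step_distances(fp, overlap)
    tiles = order_zigzag(tessellate(poly, fp, step, earth, mode))
    meta = {
        "gsd_m_per_px": gsd,
        "overlap": {"ox": overlap.ox, "oy": overlap.oy},
        "camera": getattr(cam, "name", "camera"),
        "polygon": poly.name,
    }
    route = build_route(tiles, altitude=h, wait_time=wait_time, home=home, metadata=meta)
    if d_max is not None and math.isfinite(d_max):
        route = insert_gohome(route, d_max, earth)
    return route


# ---------------------------------------------------------------------------
# mission I/O


def _fmt(x: float) -> str:
    return repr(float(x))


def export_route(route: RoutePlan, path, format: str = "json") -> None:
    """Write a mission file: ``json`` (versioned schema) or ``wpl`` (QGC WPL 110).

    The WPL dialect is one NAV_WAYPOINT row per survey waypoint (hover time in
    param1, heading in param4) and a RETURN_TO_LAUNCH row per go-home
    waypoint. It carries no mission metadata; the JSON dialect is lossless.
    """
    if format == "json":
        doc = {
            "schema": "agrisurvey-mission/1",
            "home": {"lat": route.home.lat, "lon": route.home.lon},
            "metadata": route.metadata,
            "waypoints": [
                {
                    "lat": w.location.lat,
                    "lon": w.location.lon,
                    "alt_m": w.altitude,
                    "wait_s": w.wait_time,
                    "heading_deg": w.heading,
                    "kind": w.kind,
                }
                for w in route.waypoints
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
    elif format == "wpl":
        lines = [_WPL_HEADER]
        for seq, w in enumerate(route.waypoints):
            cmd = (
                _MAV_CMD_NAV_WAYPOINT
                if w.kind == KIND_SURVEY
                else _MAV_CMD_NAV_RETURN_TO_LAUNCH
            )
            fields = [
                str(seq),
                "1" if seq == 0 else "0",  # current
                "3",  # MAV_FRAME_GLOBAL_RELATIVE_ALT
                str(cmd),
                _fmt(w.wait_time),  # param1: hover delay, s
                "0",
                "0",
                _fmt(w.heading),  # param4: yaw
                _fmt(w.location.lat),
                _fmt(w.location.lon),
                _fmt(w.altitude),
                "1",  # autocontinue
            ]
            lines.append("\t".join(fields))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise InvalidInputError(f"unknown mission format {format!r}")


def import_route(path, format: str = "json") -> RoutePlan:
    """Read a mission file written by :func:`export_route` (inverse on its output).

    For WPL, home is recovered from the first RETURN_TO_LAUNCH row when
    present, else taken as the first waypoint's location (the format itself
    stores no home record). A ``QGC WPL`` header with a version other than
    110 raises a warning and is parsed best-effort.
    """
    if format == "json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as e:
                raise ParseError(str(e.msg), line=e.lineno) from None
        try:
            home = GeoPoint(doc["home"]["lat"], doc["home"]["lon"])
            wps = tuple(
                Waypoint(
                    GeoPoint(r["lat"], r["lon"]),
                    altitude=r["alt_m"],
                    wait_time=r["wait_s"],
                    heading=r["heading_deg"],
                    kind=r["kind"],
                )
                for r in doc["waypoints"]
            )
        except (KeyError, TypeError) as e:
            raise ParseError(f"missing or malformed field: {e}") from None
        return RoutePlan(wps, home=home, metadata=dict(doc.get("metadata", {})))
    elif format == "wpl":
        with open(path) as fh:
            lines = fh.read().splitlines()
        if not lines or not lines[0].strip():
            raise ParseError("empty mission file", line=1)
        header = lines[0].strip()
        if not header.startswith("QGC WPL"):
            raise ParseError(f"not a QGC WPL file (header {header!r})", line=1)
        if header != _WPL_HEADER:
            warnings.warn(
                f"expected '{_WPL_HEADER}' header, got '{header}'; parsing best-effort",
                stacklevel=2,
            )
        rows = []
        for lineno, raw in enumerate(lines[1:], start=2):
            if not raw.strip():
                continue
            parts = raw.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"expected 12 tab-separated fields, got {len(parts)}", line=lineno
                )
            try:
                cmd = int(parts[3])
                wait_s = float(parts[4])
                heading = float(parts[7])
                lat, lon, alt = float(parts[8]), float(parts[9]), float(parts[10])
            except ValueError as e:
                raise ParseError(str(e), line=lineno) from None
            kind = KIND_GO_HOME if cmd == _MAV_CMD_NAV_RETURN_TO_LAUNCH else KIND_SURVEY
            rows.append((GeoPoint(lat, lon), alt, wait_s, heading, kind))
        if not rows:
            raise ParseError("mission file has a header but no waypoint rows", line=2)
        home = next((loc for loc, *_ , kind in rows if kind == KIND_GO_HOME), rows[0][0])
        wps = tuple(
            Waypoint(loc, altitude=alt, wait_time=wait_s, heading=hdg, kind=kind)
            for loc, alt, wait_s, hdg, kind in rows
        )
        return RoutePlan(wps, home=home)
    else:
        raise InvalidInputError(f"unknown mission format {format!r}")


def load_polygon_geojson(path) -> SurveyPolygon:
    """Read a survey polygon from a GeoJSON file (Polygon, Feature or
    single-feature FeatureCollection). Coordinates are (lon, lat) per the
    GeoJSON convention; holes (additional rings) are rejected."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ParseError(str(e.msg), line=e.lineno) from None
    props = {}
    geom = doc
    if doc.get("type") == "FeatureCollection":
        feats = doc.get("features", [])
        if len(feats) != 1:
            raise ParseError(
                f"expected exactly one feature, found {len(feats)}"
            )
        geom = feats[0].get("geometry", {})
        props = feats[0].get("properties") or {}
    elif doc.get("type") == "Feature":
        geom = doc.get("geometry", {})
        props = doc.get("properties") or {}
    if geom.get("type") != "Polygon":
        raise ParseError(f"expected a Polygon geometry, got {geom.get('type')!r}")
    rings = geom.get("coordinates", [])
    if not rings:
        raise ParseError("Polygon has no rings")
    if len(rings) > 1:
        raise ParseError(
            f"Polygon has {len(rings) - 1} hole ring(s); holes are not supported"
        )
    ring = rings[0]
    if len(ring) >= 2 and ring[0] == ring[-1]:
        ring = ring[:-1]
    verts = tuple(GeoPoint(lat=c[1], lon=c[0]) for c in ring)
    return SurveyPolygon(
        verts,
        name=str(props.get("name", "")),
        description=str(props.get("description", "")),
    )
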