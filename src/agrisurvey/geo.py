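"""Geodesic primitives for survey planning.

The route planner works in a local tangent plane (meters east/north of a
reference point) and converts metric offsets back to latitude/longitude
increments with the small-displacement approximation

    dlat = (180 / (pi R)) * dy
    dlon = (180 / (pi R)) * dx        (literal mode)
    dlon = (180 / (pi R)) * dx / cos(lat_ref)   (corrected mode, default)

The literal mode reproduces the equator-only formula some field tools use;
at nonzero latitude it compresses east-west spacing by cos(lat), so the
corrected mode is the default. Both modes are valid only for offsets small
relative to the earth radius (documented <= 50 km).

Great-circle distances use the haversine formula on a sphere of mean radius
6,371,000 m (configurable via :class:`EarthModel`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError, PolarRegionError

__all__ = [
    "GeoPoint",
    "LocalOffset",
    "EarthModel",
    "haversine_distance",
    "offset_to_increment",
    "advance_point",
    "point_to_offset",
    "initial_bearing",
]

#: Mode in which Eq.-style longitude increments ignore the cos(lat) factor.
MODE_LITERAL = "literal"
#: Mode dividing the longitude increment by cos(lat_ref); default.
MODE_CORRECTED = "corrected"

_POLAR_LIMIT_DEG = 89.9


@dataclass(frozen=True)
class GeoPoint:
    """A WGS-84-style geographic point, degrees. ``lat`` in [-90, 90], ``lon`` in [-180, 180)."""

    lat: float
    lon: float

    def __post_init__(self):
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise InvalidInputError(f"non-finite coordinates: ({self.lat}, {self.lon})")
        if not -90.0 <= self.lat <= 90.0:
            raise InvalidInputError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon < 180.0:
            # normalise instead of refusing: 180 -> -180, 361 -> 1, etc.
            object.__setattr__(self, "lon", ((self.lon + 180.0) % 360.0) - 180.0)


@dataclass(frozen=True)
class LocalOffset:
    """Metric offset in a local tangent plane: ``dx`` meters east, ``dy`` meters north."""

    dx: float
    dy: float

    def __post_init__(self):
        if not (math.isfinite(self.dx) and math.isfinite(self.dy)):
            raise InvalidInputError(f"non-finite offset: ({self.dx}, {self.dy})")

    @property
    def norm(self) -> float:
        return math.hypot(self.dx, self.dy)


@dataclass(frozen=True)
class EarthModel:
    """Spherical earth, radius ``R`` in meters (default: mean radius)."""

    R: float = 6_371_000.0

    def __post_init__(self):
        if not (math.isfinite(self.R) and self.R > 0):
            raise InvalidInputError(f"earth radius must be positive, got {self.R}")


WGS84_MEAN = EarthModel()


def haversine_distance(p1: GeoPoint, p2: GeoPoint, earth: EarthModel = WGS84_MEAN) -> float:
    """Great-circle distance between two points, meters.

    d = 2 R asin( sqrt( sin^2(dphi/2) + cos(phi1) cos(phi2) sin^2(dlam/2) ) )
    """
    phi1, lam1 = math.radians(p1.lat), math.radians(p1.lon)
    phi2, lam2 = math.radians(p2.lat), math.radians(p2.lon)
    s = (
        math.sin((phi2 - phi1) / 2.0) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2.0) ** 2
    )
    # clamp: rounding can push s a hair past 1 for near-antipodal pairs
    return 2.0 * earth.R * math.asin(min(1.0, math.sqrt(s)))


def offset_to_increment(
    offset: LocalOffset,
    ref: GeoPoint,
    earth: EarthModel = WGS84_MEAN,
    mode: str = MODE_CORRECTED,
) -> tuple[float, float]:
    """Convert a metric offset at ``ref`` into (dlat, dlon) degree increments.

    Valid for offsets small relative to the earth radius (<= 50 km). In
    corrected mode the longitude increment is divided by cos(ref.lat), which
    fails within 0.1 deg of the poles.
    """
    if mode not in (MODE_LITERAL, MODE_CORRECTED):
        raise InvalidInputError(f"unknown mode {mode!r}")
    k = 180.0 / (math.pi * earth.R)
    dlat = k * offset.dy
    dlon = k * offset.dx
    if mode == MODE_CORRECTED:
        if abs(ref.lat) >= _POLAR_LIMIT_DEG:
            raise PolarRegionError(
                f"cos(lat) correction undefined this close to the pole (lat={ref.lat})"
            )
        dlon /= math.cos(math.radians(ref.lat))
    return dlat, dlon


def advance_point(
    p: GeoPoint,
    offset: LocalOffset,
    earth: EarthModel = WGS84_MEAN,
    mode: str = MODE_CORRECTED,
) -> GeoPoint:
    """Return ``p`` displaced by ``offset`` meters (east, north)."""
    dlat, dlon = offset_to_increment(offset, p, earth, mode)
    return GeoPoint(p.lat + dlat, p.lon + dlon)


def point_to_offset(
    p: GeoPoint,
    ref: GeoPoint,
    earth: EarthModel = WGS84_MEAN,
    mode: str = MODE_CORRECTED,
) -> LocalOffset:
    """Inverse of :func:`advance_point`: metric offset of ``p`` relative to ``ref``."""
    if mode not in (MODE_LITERAL, MODE_CORRECTED):
        raise InvalidInputError(f"unknown mode {mode!r}")
    k = math.pi * earth.R / 180.0
    dy = (p.lat - ref.lat) * k
    dx = (p.lon - ref.lon) * k
    if mode == MODE_CORRECTED:
        if abs(ref.lat) >= _POLAR_LIMIT_DEG:
            raise PolarRegionError(
                f"cos(lat) correction undefined this close to the pole (lat={ref.lat})"
            )
        dx *= math.cos(math.radians(ref.lat))
    return LocalOffset(dx, dy)


def initial_bearing(p1: GeoPoint, p2: GeoPoint) -> float:
    """Initial great-circle bearing from ``p1`` to ``p2``, degrees in [0, 360).

    Returns 0.0 for coincident points.
    """
    phi1, phi2 = math.radians(p1.lat), math.radians(p2.lat)
    dlam = math.radians(p2.lon - p1.lon)
    y = math.sin(dlam) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    if y == 0.0 and x == 0.0:
        return 0.0
    return math.degrees(math.atan2(y, x)) % 360.0
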