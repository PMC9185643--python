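import json
import math

import numpy as np
import pytest
import shapely.geometry as sgeom

import agrisurvey as ag
from agrisurvey.camera import Footprint
from agrisurvey.errors import (
    EmptyRouteError,
    InvalidInputError,
    ParseError,
    UnreachableWaypointError,
)
from agrisurvey.geo import GeoPoint, LocalOffset, advance_point, haversine_distance
from agrisurvey.routeplan import (
    KIND_GO_HOME,
    KIND_SURVEY,
    RoutePlan,
    SurveyPolygon,
    Waypoint,
    build_route,
    export_route,
    import_route,
    insert_gohome,
    keep_tile,
    load_polygon_geojson,
    order_zigzag,
    point_in_polygon,
    tessellate,
)
from conftest import random_concave_ring, winding_number_inside

UNIT_SQUARE = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]


class TestPointInPolygon:
    def test_center_of_unit_square_is_inside(self):
        assert point_in_polygon((0.5, 0.5), UNIT_SQUARE)

    def test_point_beyond_square_is_outside(self):
        assert not point_in_polygon((1.5, 0.5), UNIT_SQUARE)

    def test_half_open_boundary_is_lower_left_inclusive(self):
        assert point_in_polygon((0.0, 0.5), UNIT_SQUARE)  # left edge
        assert point_in_polygon((0.5, 0.0), UNIT_SQUARE)  # bottom edge
        assert not point_in_polygon((1.0, 0.5), UNIT_SQUARE)  # right edge
        assert not point_in_polygon((0.5, 1.0), UNIT_SQUARE)  # top edge

    def test_degenerate_zero_area_ring_rejected(self):
        with pytest.raises(InvalidInputError):
            point_in_polygon((0.0, 0.0), [(0, 0), (1, 1), (2, 2)])

    def test_matches_winding_number_oracle_on_concave_polygon(self):
        rng = np.random.default_rng(3)
        ring = random_concave_ring(rng, n_vertices=12)
        boundary = sgeom.Polygon(ring).exterior
        checked = 0
        for _ in range(2000):
            p = (rng.uniform(-70, 70), rng.uniform(-70, 70))
            if boundary.distance(sgeom.Point(p)) < 1e-9:
                continue
            assert point_in_polygon(p, ring) == winding_number_inside(p, ring)
            checked += 1
        assert checked > 1900

    def test_matches_shapely_on_interior_points(self):
        rng = np.random.default_rng(5)
        ring = random_concave_ring(rng, n_vertices=16)
        poly = sgeom.Polygon(ring)
        for _ in range(500):
            p = (rng.uniform(-70, 70), rng.uniform(-70, 70))
            if poly.exterior.distance(sgeom.Point(p)) < 1e-9:
                continue
            assert point_in_polygon(p, ring) == poly.contains(sgeom.Point(p))


class TestKeepTile:
    fp = Footprint(2.0, 2.0)
    big = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]

    def test_fully_inside_tile_is_kept(self):
        assert keep_tile((5.0, 5.0), self.fp, self.big)

    def test_fully_outside_tile_is_dropped(self):
        assert not keep_tile((20.0, 20.0), self.fp, self.big)

    def test_corner_inside_center_outside_is_kept(self):
        # center just right of the square, SW corner still inside
        assert not point_in_polygon((10.5, 5.0), self.big)
        assert keep_tile((10.5, 5.0), self.fp, self.big)


class TestTessellate:
    def brute_force_count(self, poly, fp, step):
        """Independent enumeration oracle: shapely inclusion with an
        epsilon shift emulating the lower-left-inclusive half-open rule."""
        from agrisurvey.geo import point_to_offset

        ref = GeoPoint(min(p.lat for p in poly.vertices), min(p.lon for p in poly.vertices))
        ring = []
        for p in poly.vertices:
            off = point_to_offset(p, ref)
            ring.append((round(off.dx, 6), round(off.dy, 6)))
        sh = sgeom.Polygon(ring)
        eps = 1e-9
        inside = lambda x, y: sh.contains(sgeom.Point(x + eps, y + eps))
        width = max(x for x, _ in ring)
        height = max(y for _, y in ring)
        hx, hy = fp.d_fov_x / 2, fp.d_fov_y / 2
        count = 0
        for i in range(int(width / step.dx) + 3):
            for j in range(int(height / step.dy) + 3):
                cx, cy = hx + i * step.dx, hy + j * step.dy
                pts = [(cx, cy), (cx - hx, cy - hy), (cx + hx, cy - hy),
                       (cx + hx, cy + hy), (cx - hx, cy + hy)]
                if any(inside(x, y) for x, y in pts):
                    count += 1
        return count

    def test_rectangle_yields_exactly_50_tiles(self, rect_polygon):
        tiles = tessellate(rect_polygon, Footprint(20, 12), LocalOffset(20, 12))
        assert len(tiles) == 50
        assert {t.local_ij for t in tiles} == {(i, j) for i in range(5) for j in range(10)}
        assert len(tiles) == self.brute_force_count(
            rect_polygon, Footprint(20, 12), LocalOffset(20, 12)
        )

    def test_half_step_count_matches_brute_force(self, rect_polygon):
        fp, step = Footprint(20, 12), LocalOffset(10, 6)
        tiles = tessellate(rect_polygon, fp, step)
        assert len(tiles) == self.brute_force_count(rect_polygon, fp, step)

    def test_concave_polygon_matches_brute_force(self):
        poly = ag.make_polygon("concave12", 80.0)
        fp, step = Footprint(15, 15), LocalOffset(15, 15)
        tiles = tessellate(poly, fp, step)
        assert len(tiles) == self.brute_force_count(poly, fp, step)

    def test_tiny_triangle_catching_one_corner(self):
        # triangle sits fully inside the footprint area of grid tile (0, 0)
        # and contains that tile's NE corner (20, 12)
        anchor = GeoPoint(40.0, -3.7)
        verts = tuple(
            advance_point(anchor, LocalOffset(dx, dy))
            for dx, dy in [(19.0, 11.0), (23.0, 11.0), (21.0, 14.0)]
        )
        poly = SurveyPolygon(verts)
        tiles = tessellate(poly, Footprint(40, 24), LocalOffset(40, 24))
        assert len(tiles) == 1

    def test_polygon_with_no_kept_tile_raises(self):
        # triangle occupying x + y >= 10 in its own bbox: every grid test
        # point of the oversized footprint (corners at multiples of 200,
        # centers at 100) misses it
        anchor = GeoPoint(40.0, -3.7)
        verts = tuple(
            advance_point(anchor, LocalOffset(dx, dy))
            for dx, dy in [(0.0, 10.0), (10.0, 0.0), (10.0, 10.0)]
        )
        with pytest.raises(EmptyRouteError):
            tessellate(SurveyPolygon(verts), Footprint(200, 200), LocalOffset(200, 200))

    def test_no_overlap_tiles_do_not_intersect(self, rect_polygon):
        tiles = tessellate(rect_polygon, Footprint(20, 12), LocalOffset(20, 12))
        boxes = [
            sgeom.box(t.local_center[0] - 10, t.local_center[1] - 6,
                      t.local_center[0] + 10, t.local_center[1] + 6)
            for t in tiles
        ]
        for a in range(len(boxes)):
            for b in range(a + 1, len(boxes)):
                inter = boxes[a].intersection(boxes[b])
                assert inter.area == pytest.approx(0.0, abs=1e-9)

    def test_full_coverage_at_no_overlap_on_convex_polygons(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            # random convex polygon from a convex hull of random points
            pts = rng.uniform(5, 95, size=(12, 2))
            hull = sgeom.MultiPoint([tuple(p) for p in pts]).convex_hull
            anchor = GeoPoint(40.0, -3.7)
            verts = tuple(
                advance_point(anchor, LocalOffset(x, y))
                for x, y in hull.exterior.coords[:-1]
            )
            poly = SurveyPolygon(verts)
            fp, step = Footprint(14, 10), LocalOffset(14, 10)
            tiles = tessellate(poly, fp, step)
            union = sgeom.MultiPolygon([
                sgeom.box(t.local_center[0] - 7.0, t.local_center[1] - 5.0,
                          t.local_center[0] + 7.0, t.local_center[1] + 5.0)
                for t in tiles
            ]).buffer(1e-9)
            from agrisurvey.geo import point_to_offset

            ref = GeoPoint(min(p.lat for p in poly.vertices), min(p.lon for p in poly.vertices))
            local = sgeom.Polygon(
                [(point_to_offset(p, ref).dx, point_to_offset(p, ref).dy) for p in poly.vertices]
            )
            # the center-or-corner rule can miss a sliver that crosses a tile
            # edge between two corners, so coverage is near-total, not exact
            uncovered = local.difference(union)
            assert uncovered.area < 1e-3 * local.area


class TestZigzag:
    def make_tiles(self, ijs):
        anchor = GeoPoint(40.0, -3.7)
        return [
            ag.Tile(anchor, (anchor,) * 4, ij, (float(ij[0]), float(ij[1])))
            for ij in ijs
        ]

    def test_two_by_two_grid_order(self):
        tiles = self.make_tiles([(0, 0), (0, 1), (1, 0), (1, 1)])
        assert [t.local_ij for t in order_zigzag(tiles)] == [(0, 0), (0, 1), (1, 1), (1, 0)]

    def test_single_column_is_strictly_increasing(self):
        tiles = self.make_tiles([(0, j) for j in (3, 0, 2, 1)])
        assert [t.local_ij for t in order_zigzag(tiles)] == [(0, j) for j in range(4)]

    def test_empty_in_empty_out(self):
        assert order_zigzag([]) == []

    def test_full_grid_consecutive_tiles_differ_in_one_axis(self, rect_polygon):
        tiles = order_zigzag(tessellate(rect_polygon, Footprint(20, 12), LocalOffset(20, 12)))
        assert tiles[0].local_ij == (0, 0)  # bottom-left start
        for a, b in zip(tiles, tiles[1:]):
            di = abs(a.local_ij[0] - b.local_ij[0])
            dj = abs(a.local_ij[1] - b.local_ij[1])
            assert (di, dj) in {(1, 0), (0, 1)}

    def test_ragged_grid_columns_non_decreasing_and_monotone(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            ijs = {(int(i), int(j)) for i, j in rng.integers(0, 8, size=(30, 2))}
            ordered = order_zigzag(self.make_tiles(sorted(ijs)))
            assert {t.local_ij for t in ordered} == ijs
            cols = [t.local_ij[0] for t in ordered]
            assert cols == sorted(cols)
            # within a column the sweep is monotone and moves only in j
            for a, b in zip(ordered, ordered[1:]):
                if a.local_ij[0] == b.local_ij[0]:
                    assert a.local_ij[1] != b.local_ij[1]


class TestBuildRoute:
    def test_fifty_waypoints_at_80_meters(self, route_50):
        assert len(route_50.waypoints) == 50
        assert all(w.altitude == 80.0 for w in route_50.waypoints)
        assert all(w.kind == KIND_SURVEY for w in route_50.waypoints)

    def test_wait_time_propagates_to_every_waypoint(self, route_50):
        assert all(w.wait_time == 5.0 for w in route_50.waypoints)

    def test_default_home_is_first_waypoint(self, route_50):
        assert route_50.home == route_50.waypoints[0].location
        assert haversine_distance(route_50.home, route_50.waypoints[0].location) == 0.0

    def test_heading_follows_leg_direction(self, route_50):
        # first column is flown due north: headings ~0 after the first point
        assert route_50.waypoints[0].heading == 0.0
        assert route_50.waypoints[1].heading == pytest.approx(0.0, abs=0.01)
        # the hop to column 2 is due east
        assert route_50.waypoints[10].heading == pytest.approx(90.0, abs=0.1)

    def test_empty_tiles_rejected(self):
        with pytest.raises(EmptyRouteError):
            build_route([], altitude=50.0)


def route_from_offsets(offsets, altitude=30.0):
    """Route with home at the anchor and waypoints at metric offsets."""
    home = GeoPoint(40.0, -3.7)
    wps = [
        Waypoint(advance_point(home, LocalOffset(dx, dy)), altitude=altitude)
        for dx, dy in offsets
    ]
    return RoutePlan(tuple(wps), home=home)


def gohome_scan_oracle(locations, home, d_max):
    """Linear-scan reference: indices i such that a go-home follows w_i."""
    d = lambda a, b: haversine_distance(a, b)
    out = []
    for i in range(len(locations) - 1):
        if d(locations[i], locations[i + 1]) + d(locations[i + 1], home) > d_max:
            out.append(i)
    return out


class TestInsertGohome:
    def test_infinite_budget_leaves_route_unchanged(self, route_50):
        assert insert_gohome(route_50, float("inf")).waypoints == route_50.waypoints

    def test_shuttling_line_positions_match_scan_oracle(self):
        # waypoints alternating 400 m east/west of home: each crossing leg is
        # ~800 m, so continuing plus returning (~1200 m) exceeds the 1000 m
        # budget while every waypoint stays individually reachable (800 m
        # round trip)
        route = route_from_offsets(
            [((-1) ** k * 400.0, 10.0 * k) for k in range(6)]
        )
        d_max = 1000.0
        split = insert_gohome(route, d_max)
        got = [
            sum(1 for w in split.waypoints[:k] if w.kind == KIND_SURVEY) - 1
            for k, w in enumerate(split.waypoints)
            if w.kind == KIND_GO_HOME
        ]
        locs = [w.location for w in route.waypoints]
        assert got == gohome_scan_oracle(locs, route.home, d_max)
        assert len(got) == 5  # every crossing is too risky to fly direct

    def test_two_long_crossings_give_three_subroutes(self):
        # two ~800 m crossings followed by a short hop: exactly two go-home
        # stops, i.e. a mission flown in three sub-routes
        route = route_from_offsets(
            [(-400.0, 0.0), (400.0, 0.0), (-400.0, 60.0), (-350.0, 60.0)]
        )
        d_max = 1100.0
        split = insert_gohome(route, d_max)
        kinds = [w.kind for w in split.waypoints]
        assert kinds.count(KIND_GO_HOME) == 2
        assert kinds == [
            KIND_SURVEY, KIND_GO_HOME, KIND_SURVEY, KIND_GO_HOME,
            KIND_SURVEY, KIND_SURVEY,
        ]
        pts = [split.home] + [w.location for w in split.waypoints]
        for a, b in zip(pts, pts[1:]):
            assert (
                haversine_distance(a, b) + haversine_distance(b, split.home)
                <= d_max + 1e-6
            )

    def test_random_routes_satisfy_leg_plus_return_bound(self):
        rng = np.random.default_rng(9)
        home = GeoPoint(40.0, -3.7)
        for trial in range(20):
            n = int(rng.integers(3, 25))
            wps = tuple(
                Waypoint(
                    advance_point(
                        home,
                        LocalOffset(float(rng.uniform(-400, 400)), float(rng.uniform(-400, 400))),
                    ),
                    altitude=30.0,
                )
                for _ in range(n)
            )
            route = RoutePlan(wps, home=home)
            reach = 2.0 * max(haversine_distance(home, w.location) for w in wps)
            d_max = float(rng.uniform(reach, 2.5 * reach))
            split = insert_gohome(route, d_max)
            pts = [home] + [w.location for w in split.waypoints]
            for a, b in zip(pts, pts[1:]):
                assert haversine_distance(a, b) + haversine_distance(b, home) <= d_max + 1e-6
            # insertion points agree with the linear-scan oracle
            got = [
                sum(1 for w in split.waypoints[:k] if w.kind == KIND_SURVEY) - 1
                for k, w in enumerate(split.waypoints)
                if w.kind == KIND_GO_HOME
            ]
            locs = [w.location for w in wps]
            assert got == gohome_scan_oracle(locs, home, d_max)

    def test_unreachable_waypoint_is_named(self):
        route = route_from_offsets([(0.0, 0.0), (200.0, 0.0), (600.0, 0.0)])
        with pytest.raises(UnreachableWaypointError, match="waypoint 2"):
            insert_gohome(route, 900.0)  # 600 m out: 1200 m round trip


class TestMissionIO:
    def test_json_roundtrip_is_field_for_field(self, route_50, tmp_path):
        p = tmp_path / "m.json"
        export_route(route_50, p, "json")
        assert import_route(p, "json") == route_50

    def test_wpl_roundtrip_preserves_waypoints_and_home(self, route_50, tmp_path):
        p = tmp_path / "m.wpl"
        export_route(route_50, p, "wpl")
        back = import_route(p, "wpl")
        assert back.waypoints == route_50.waypoints
        assert back.home == route_50.home

    def test_wpl_has_header_plus_one_row_per_waypoint(self, route_50, tmp_path):
        p = tmp_path / "m.wpl"
        export_route(route_50, p, "wpl")
        lines = p.read_text().splitlines()
        assert lines[0] == "QGC WPL 110"
        assert len(lines) == 51

    def test_gohome_becomes_return_to_launch_row(self, tmp_path):
        split = insert_gohome(
            route_from_offsets([((-1) ** k * 400.0, 10.0 * k) for k in range(4)]),
            1000.0,
        )
        n_home = sum(1 for w in split.waypoints if w.kind == KIND_GO_HOME)
        assert n_home >= 1
        p = tmp_path / "m.wpl"
        export_route(split, p, "wpl")
        rows = p.read_text().splitlines()[1:]
        rtl = [r for r in rows if r.split("\t")[3] == "20"]
        assert len(rtl) == n_home
        back = import_route(p, "wpl")
        assert back.waypoints == split.waypoints
        assert back.home == split.home

    def test_older_wpl_version_warns_but_parses(self, route_50, tmp_path):
        p = tmp_path / "m.wpl"
        export_route(route_50, p, "wpl")
        text = p.read_text().replace("QGC WPL 110", "QGC WPL 109", 1)
        p.write_text(text)
        with pytest.warns(UserWarning, match="109"):
            back = import_route(p, "wpl")
        assert back.waypoints == route_50.waypoints

    def test_empty_file_is_a_parse_error(self, tmp_path):
        p = tmp_path / "empty.wpl"
        p.write_text("")
        with pytest.raises(ParseError):
            import_route(p, "wpl")

    def test_malformed_wpl_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.wpl"
        p.write_text("QGC WPL 110\n1\t2\t3\n")
        with pytest.raises(ParseError, match="line 2"):
            import_route(p, "wpl")

    def test_unknown_format_rejected(self, route_50, tmp_path):
        with pytest.raises(InvalidInputError):
            export_route(route_50, tmp_path / "m.kml", "kml")


class TestPolygonValidation:
    def anchor_pts(self, offsets):
        anchor = GeoPoint(40.0, -3.7)
        return tuple(advance_point(anchor, LocalOffset(dx, dy)) for dx, dy in offsets)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(InvalidInputError):
            SurveyPolygon(self.anchor_pts([(0, 0), (10, 0)]))

    def test_symmetric_bowtie_has_zero_signed_area(self):
        with pytest.raises(InvalidInputError, match="zero area"):
            SurveyPolygon(self.anchor_pts([(0, 0), (10, 10), (10, 0), (0, 10)]))

    def test_self_intersection_rejected(self):
        # asymmetric crossing ring with nonzero signed area
        with pytest.raises(InvalidInputError, match="self-intersect"):
            SurveyPolygon(self.anchor_pts([(0, 0), (12, 0), (0, 10), (6, 14)]))

    def test_duplicate_consecutive_vertex_rejected(self):
        pts = self.anchor_pts([(0, 0), (10, 0), (10, 10)])
        with pytest.raises(InvalidInputError, match="duplicate"):
            SurveyPolygon((pts[0], pts[0], pts[1], pts[2]))


class TestGeoJSON:
    def write(self, tmp_path, coords, holes=None, wrapper="feature"):
        rings = [coords]
        if holes:
            rings += holes
        geom = {"type": "Polygon", "coordinates": rings}
        if wrapper == "feature":
            doc = {"type": "Feature", "properties": {"name": "field"}, "geometry": geom}
        else:
            doc = geom
        p = tmp_path / "poly.geojson"
        p.write_text(json.dumps(doc))
        return p

    def test_lon_lat_order_and_name(self, tmp_path, rect_polygon):
        coords = [[v.lon, v.lat] for v in rect_polygon.vertices]
        coords.append(coords[0])  # GeoJSON rings close explicitly
        poly = load_polygon_geojson(self.write(tmp_path, coords))
        assert poly.vertices == rect_polygon.vertices
        assert poly.name == "field"

    def test_holes_rejected_with_clear_error(self, tmp_path, rect_polygon):
        coords = [[v.lon, v.lat] for v in rect_polygon.vertices]
        coords.append(coords[0])
        hole = [[-3.6999, 40.0001], [-3.6998, 40.0001], [-3.6998, 40.0002], [-3.6999, 40.0001]]
        path = self.write(tmp_path, coords, holes=[hole])
        with pytest.raises(ParseError, match="hole"):
            load_polygon_geojson(path)
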