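import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import agrisurvey as ag

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def demo_camera():
    """8 mm lens, 3 um pitch, 4000x3000 px: gsd 0.03 m/px -> 80 m altitude."""
    return ag.CAMERA_CATALOGUE["demo-8mm"]


@pytest.fixture(scope="session")
def rect_polygon():
    """100 m x 120 m rectangle anchored at (40 N, 3.7 W)."""
    return ag.make_polygon("rectangle", 100.0)


@pytest.fixture(scope="session")
def scene():
    """Noiseless default scene plus its ground truth."""
    spec = ag.default_scene_spec(seed=7)
    cube, truth = ag.make_scene(spec)
    return spec, cube, truth


@pytest.fixture(scope="session")
def reflectance_cube(scene):
    spec, cube, _ = scene
    refl, _ = ag.calibrate(cube, spec.panel_specs())
    return refl


@pytest.fixture(scope="session")
def route_50(rect_polygon, demo_camera):
    """50-waypoint zigzag over the rectangle (footprint 20 x 12 m, no overlap)."""
    from agrisurvey.camera import Footprint
    from agrisurvey.geo import LocalOffset
    from agrisurvey.routeplan import build_route, order_zigzag, tessellate

    tiles = order_zigzag(tessellate(rect_polygon, Footprint(20, 12), LocalOffset(20, 12)))
    return build_route(
        tiles,
        altitude=80.0,
        wait_time=5.0,
        metadata={"gsd_m_per_px": 0.03, "camera": demo_camera.name},
    )


def winding_number_inside(p, ring):
    """Independent inclusion oracle: signed-angle winding number.

    Sums the turn angle subtended at p by each edge; |total| ~ 2 pi for
    interior points and ~ 0 for exterior ones. Unrelated to the ray-casting
    crossing count it cross-checks.
    """
    px, py = p
    total = 0.0
    n = len(ring)
    for k in range(n):
        x1, y1 = ring[k]
        x2, y2 = ring[(k + 1) % n]
        v1 = (x1 - px, y1 - py)
        v2 = (x2 - px, y2 - py)
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        dot = v1[0] * v2[0] + v1[1] * v2[1]
        total += np.arctan2(cross, dot)
    return abs(total) > np.pi


def random_concave_ring(rng, n_vertices=12, radius=60.0):
    """Star-like concave planar ring with randomized radii/rotation."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    # enforce minimum angular separation to avoid degenerate slivers
    angles = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False) + rng.uniform(
        -0.15, 0.15, n_vertices
    )
    radii = rng.uniform(0.35 * radius, radius, n_vertices)
    return [(r * np.cos(a), r * np.sin(a)) for a, r in zip(angles, radii)]
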