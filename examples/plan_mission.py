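"""Plan a zigzag survey mission over a 100 m x 120 m field.

Builds a rectangular field polygon, derives the flight altitude from the
target ground sampling distance (GSD), tessellates the field with camera
footprints, orders the tiles in a boustrophedon sweep, and exports the
mission as a Mission-Planner-compatible QGC WPL 110 file.
"""

from agrisurvey import CAMERA_CATALOGUE, OverlapSpec, export_route, make_polygon, plan_survey

cam = CAMERA_CATALOGUE["demo-8mm"]  # 8 mm lens, 3 um pixels, 4000 x 3000 px
poly = make_polygon("rectangle", 100.0)  # 100 m x 120 m at (40 N, 3.7 W)

route = plan_survey(
    poly,
    cam,
    gsd=0.005,  # 5 mm/pixel -> 13.3 m altitude
    overlap=OverlapSpec(0.8, 0.8),  # 20% image overlap both ways
    wait_time=5.0,  # hover 5 s per waypoint for the exposure
)
export_route(route, "mission.wpl", format="wpl")

print(f"waypoints:     {len(route.waypoints)}")
print(f"altitude:      {route.waypoints[0].altitude:.1f} m AGL")
print(f"total length:  {route.total_length():.0f} m (incl. launch and return)")
print("wrote mission.wpl (QGC WPL 110, load it in Mission Planner)")
# The waypoint count reflects the tessellation: each waypoint is the center
# of one camera footprint, so the field is photographed wall to wall with
# the requested overlap.
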