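"""Plan 360-degree camera coverage of a vineyard.

Prints how many detector modules a full circle needs for each camera's
horizontal field of view (detection range 300 m), and checks whether a
flock at a given bearing/distance falls inside a camera's sector.
"""

from flockwatch import CameraSpec, detectors_for_full_circle, recommended_detectors, sector_covers

cameras = {
    "Sony IMX477R, min zoom (44.6° FOV)": CameraSpec(horizontal_fov=44.6),
    "Sony IMX477R, max zoom (21.8° FOV)": CameraSpec(horizontal_fov=21.8),
    "Arducam IMX179AF, fixed (64.5° FOV)": CameraSpec(horizontal_fov=64.5),
}
for name, spec in cameras.items():
    print(f"{name}: 360/FOV = {detectors_for_full_circle(spec)} "
          f"-> {recommended_detectors(spec)} modules")

spec = CameraSpec(horizontal_fov=44.6)
for bearing, dist in [(10.0, 250.0), (10.0, 301.0), (30.0, 250.0)]:
    covered = sector_covers(spec, camera_bearing=0.0, target_bearing=bearing,
                            target_distance=dist)
    print(f"flock at bearing {bearing:5.1f}°, {dist:5.0f} m -> covered: {covered}")

print(
    "\n360/FOV is the fractional camera count for a full panorama; a flock is\n"
    "covered when it is within half the FOV of the camera bearing and within\n"
    "the 300 m detection range (both bounds inclusive)."
)
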