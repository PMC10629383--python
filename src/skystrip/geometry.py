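"""Camera-to-ground geometry for tilted aerial frames.

Projects pinhole rays onto the sea-level plane z = 0, builds image-footprint
polygons, measures forward-/side-lap and minimum-bounding widths, dissolves
per-camera coverage, cuts coverage by transect segments, schedules capture
intervals for a target forward-lap, and computes observer effective areas
and zone-centre sighting positions.

Conventions
-----------
* World frame: easting (x), northing (y), up (z); ground is z = 0.
* Azimuth: degrees clockwise from north.
* Rotation order (camera ray outward): azimuth, then pitch, then roll, then
  camera mount tilt — tilt and roll rotate about the along-track axis, pitch
  about the across-track axis. Positive tilt/roll swing the view to
  starboard; positive pitch (nose up) swings it backward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.geometry.polygon import orient
from shapely.ops import transform as shp_transform
from shapely.ops import unary_union


class HorizonError(ValueError):
    """A pixel ray does not intersect the ground plane in front of the camera."""


class PoseError(ValueError):
    """Invalid camera pose (e.g. non-positive altitude)."""


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with a rigid mount tilt about the along-track axis.

    `sensor_width` is across-track, `sensor_height` along-track (metres);
    `pixels` is (cols, rows); `mount_tilt` is signed degrees, positive
    toward starboard.
    """

    focal_length: float
    sensor_width: float
    sensor_height: float
    pixels: tuple[int, int]
    mount_tilt: float = 0.0

    def __post_init__(self) -> None:
        if self.focal_length <= 0:
            raise ValueError("focal_length must be > 0")
        if abs(self.mount_tilt) >= 90:
            raise ValueError("|mount_tilt| must be < 90 deg")

    @property
    def centre_pixel(self) -> tuple[float, float]:
        return (self.pixels[0] / 2.0, self.pixels[1] / 2.0)


@dataclass(frozen=True)
class Pose:
    """Aircraft pose at capture time: position (e, n, altitude) and attitude."""

    easting: float
    northing: float
    altitude: float
    pitch: float = 0.0
    roll: float = 0.0
    azimuth: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.altitude <= 0:
            raise PoseError("altitude must be > 0")


@dataclass(frozen=True)
class ImageFootprint:
    """Ground quadrilateral of one frame, with pose provenance."""

    image_id: str
    camera_id: str
    corners: tuple[tuple[float, float], ...]
    polygon: Polygon
    capture_time: float
    gsd_centre: float


def _ray_body(camera: CameraModel, pixel: tuple[float, float]) -> np.ndarray:
    """Pixel ray in the body frame (forward, right, down), unit length."""
    cols, rows = camera.pixels
    cx, cy = camera.centre_pixel
    # sensor offsets in metres; row index increases backward along track
    xi = (pixel[0] - cx) * camera.sensor_width / cols  # across-track, +right
    eta = (cy - pixel[1]) * camera.sensor_height / rows  # along-track, +fwd
    d = np.array([eta, xi, camera.focal_length])
    return d / np.linalg.norm(d)


def _rot_forward(angle_deg: float) -> np.ndarray:
    """Rotation about the along-track (forward) axis; +angle sends down->right."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[1, 0, 0], [0, c, s], [0, -s, c]])


def _rot_right(angle_deg: float) -> np.ndarray:
    """Rotation about the across-track (right) axis; +angle sends down->backward."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, 0, -s], [0, 1, 0], [s, 0, c]])


def _ray_world(pose: Pose, camera: CameraModel, pixel: tuple[float, float]) -> np.ndarray:
    """Pixel ray in world (east, north, up) after azimuth->pitch->roll->tilt."""
    d = _ray_body(camera, pixel)
    d = _rot_forward(camera.mount_tilt) @ d
    d = _rot_forward(pose.roll) @ d
    d = _rot_right(pose.pitch) @ d
    az = math.radians(pose.azimuth)
    fwd, right, down = d
    east = fwd * math.sin(az) + right * math.cos(az)
    north = fwd * math.cos(az) - right * math.sin(az)
    return np.array([east, north, -down])


def project_pixel_to_ground(
    pose: Pose, camera: CameraModel, pixel: tuple[float, float]
) -> tuple[float, float]:
    """Intersect the ray through `pixel` with the ground plane z = 0."""
    if pose.altitude <= 0:
        raise PoseError("altitude must be > 0")
    d = _ray_world(pose, camera, pixel)
    if d[2] >= -1e-12:
        raise HorizonError(
            f"pixel {pixel} ray points at or above the horizon (dz={d[2]:.3g})"
        )
    t = pose.altitude / (-d[2])
    return (pose.easting + t * d[0], pose.northing + t * d[1])


def image_footprint(
    pose: Pose, camera: CameraModel, image_id: str = "", camera_id: str = ""
) -> ImageFootprint:
    """Project the four sensor corners; corners returned counter-clockwise."""
    cols, rows = camera.pixels
    corner_px = [(0, 0), (cols, 0), (cols, rows), (0, rows)]
    corners = [project_pixel_to_ground(pose, camera, px) for px in corner_px]
    poly = Polygon(corners)
    if not poly.is_valid or poly.area <= 0:
        raise HorizonError("projected corners do not form a simple polygon")
    poly = orient(poly, sign=1.0)
    corners = tuple(poly.exterior.coords)[:-1]

    # across-track GSD from centre-pixel neighbour projection; this is the
    # direction stretched by the mount tilt (1/cos^2 at the frame centre)
    cx, cy = camera.centre_pixel
    centre = np.array(project_pixel_to_ground(pose, camera, (cx, cy)))
    right = np.array(project_pixel_to_ground(pose, camera, (cx + 1, cy)))
    gsd = float(np.linalg.norm(right - centre))
    return ImageFootprint(
        image_id=image_id,
        camera_id=camera_id,
        corners=corners,
        polygon=poly,
        capture_time=pose.time,
        gsd_centre=gsd,
    )


def forward_overlap(fp_a: ImageFootprint | Polygon, fp_b: ImageFootprint | Polygon) -> float:
    """area(a ∩ b) / area(a) for two consecutive same-camera frames."""
    a = fp_a.polygon if isinstance(fp_a, ImageFootprint) else fp_a
    b = fp_b.polygon if isinstance(fp_b, ImageFootprint) else fp_b
    if a.area <= 0:
        raise ValueError("degenerate footprint")
    return a.intersection(b).area / a.area


def side_overlap(union_cam1: Polygon, union_cam2: Polygon) -> float:
    """Overlap area divided by per-camera coverage area (mean of the two)."""
    if union_cam1.is_empty or union_cam2.is_empty:
        raise ValueError("empty coverage polygon")
    inter = union_cam1.intersection(union_cam2).area
    per_camera = 0.5 * (union_cam1.area + union_cam2.area)
    return inter / per_camera


def min_bounding_width(footprint: ImageFootprint | Polygon) -> float:
    """Longer side of the minimum-area bounding rectangle (rotating calipers)."""
    poly = footprint.polygon if isinstance(footprint, ImageFootprint) else footprint
    if poly.is_empty or poly.area <= 0:
        raise ValueError("degenerate polygon")
    rect = shapely.minimum_rotated_rectangle(poly)
    pts = np.asarray(rect.exterior.coords)[:4]
    sides = np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1)[:2]
    return float(max(sides))


def dissolve_coverage(footprints: Sequence[ImageFootprint | Polygon]) -> tuple[Polygon, float]:
    """Union of footprints: double-covered ground counted once."""
    if not footprints:
        raise ValueError("need at least one footprint")
    polys = [f.polygon if isinstance(f, ImageFootprint) else f for f in footprints]
    merged = unary_union(polys)
    return merged, merged.area


def cut_by_segments(
    coverage,
    origin: tuple[float, float],
    heading_deg: float,
    boundaries: Sequence[float],
) -> list[float]:
    """Areas of `coverage` between successive chainage boundaries.

    Chainage is measured from `origin` along `heading_deg`; boundaries must
    be strictly increasing and define len(boundaries) - 1 segments cut by
    lines perpendicular to the transect.
    """
    bounds = list(boundaries)
    if len(bounds) < 2:
        raise ValueError("need at least two boundaries")
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("boundaries must be strictly increasing")
    az = math.radians(heading_deg)
    u = np.array([math.sin(az), math.cos(az)])  # along-track unit
    # rotate coverage into a frame where chainage is the x axis
    coords_fn = lambda x, y: (  # noqa: E731
        u[0] * (np.asarray(x) - origin[0]) + u[1] * (np.asarray(y) - origin[1]),
        -u[1] * (np.asarray(x) - origin[0]) + u[0] * (np.asarray(y) - origin[1]),
    )
    local = shp_transform(coords_fn, coverage)
    big = 1e9
    return [
        local.intersection(box(b1, -big, b2, big)).area
        for b1, b2 in zip(bounds, bounds[1:])
    ]


def schedule_capture_interval(
    altitude: float,
    focal_length: float,
    sensor_height: float,
    forward_lap: float,
    ground_speed: float,
) -> float:
    """Seconds between captures for a prescribed forward-lap fraction."""
    if ground_speed <= 0:
        raise ValueError("ground_speed must be > 0")
    if not 0.0 <= forward_lap < 1.0:
        raise ValueError("forward_lap must be in [0, 1)")
    along_track = altitude * sensor_height / focal_length
    return along_track * (1.0 - forward_lap) / ground_speed


def observer_effective_area(
    segment_length: float,
    mean_altitude: float,
    strip_widths: tuple[float, float] = (206.0, 203.0),
    target_altitude: float = 152.0,
) -> float:
    """Altitude-fraction-corrected area sampled by the observer team (m^2)."""
    if segment_length <= 0:
        raise ValueError("segment_length must be > 0")
    if mean_altitude <= 0:
        raise ValueError("mean_altitude must be > 0")
    return (mean_altitude / target_altitude) * segment_length * sum(strip_widths)


def map_observer_sighting(
    call_time: float,
    side: str,
    zone: int,
    track_times: np.ndarray,
    track_east: np.ndarray,
    track_north: np.ndarray,
    inner_edge: float = 148.0,
    zone_width: float = 50.0,
    altitude_fraction: float = 1.0,
) -> tuple[float, float]:
    """Ground point at the centre of the called zone, abeam the aircraft.

    Zone k spans [inner_edge + k*zone_width, inner_edge + (k+1)*zone_width)
    from the flight line at target altitude; the lateral offset scales with
    the altitude fraction. `side` is 'port' (left of track) or 'starboard'.
    """
    t = np.asarray(track_times, dtype=float)
    if not (t[0] <= call_time <= t[-1]):
        raise ValueError("call time outside track time span")
    if zone < 0:
        raise ValueError("zone index must be >= 0")
    if side not in ("port", "starboard"):
        raise ValueError("side must be 'port' or 'starboard'")
    e = float(np.interp(call_time, t, np.asarray(track_east, dtype=float)))
    n = float(np.interp(call_time, t, np.asarray(track_north, dtype=float)))
    # heading from the local track direction
    i = int(np.searchsorted(t, call_time, side="right"))
    i = min(max(i, 1), len(t) - 1)
    de = track_east[i] - track_east[i - 1]
    dn = track_north[i] - track_north[i - 1]
    norm = math.hypot(de, dn)
    if norm == 0:
        raise ValueError("track is stationary at call time")
    fwd = (de / norm, dn / norm)
    right = (fwd[1], -fwd[0])
    offset = (inner_edge + zone_width * zone + zone_width / 2.0) * altitude_fraction
    sign = 1.0 if side == "starboard" else -1.0
    return (e + sign * offset * right[0], n + sign * offset * right[1])


def nadir_footprint_area(
    altitude: float, sensor_width: float, sensor_height: float, focal_length: float
) -> float:
    """Closed-form nadir footprint area H^2 * ws * hs / f^2 (oracle helper)."""
    return altitude**2 * sensor_width * sensor_height / focal_length**2
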