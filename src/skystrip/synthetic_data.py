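"""Synthetic dual-platform surveys with known ground truth.

Generates transect layouts, clustered animal groups with zero-truncated
heavy-tailed sizes, per-image telemetry, per-occasion Bernoulli detections
for both platforms, and piecewise-constant environmental covariates, then
writes the canonical CSV tables every downstream stage consumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from skystrip.config import SurveyConfig
from skystrip.geometry import (
    CameraModel,
    Pose,
    image_footprint,
    schedule_capture_interval,
)


@dataclass
class TruthRecord:
    """One generated animal group: centroid, member points, size, availability."""

    group_id: int
    centroid: tuple[float, float]
    members: list[tuple[float, float]] = field(default_factory=list)
    available: dict[str, bool] = field(default_factory=dict)

    @property
    def true_group_size(self) -> int:
        return len(self.members)


def generate_transect_layout(config: SurveyConfig) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Parallel south-to-north centrelines spaced `transect_spacing` apart.

    Transect i runs along easting = i * spacing from northing 0 to
    transect_length. Deterministic for a fixed config.
    """
    if config.n_transects < 1:
        raise ValueError("n_transects must be >= 1")
    return [
        ((i * config.transect_spacing, 0.0), (i * config.transect_spacing, config.transect_length))
        for i in range(config.n_transects)
    ]


def zt_poisson_sizes(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    """Zero-truncated Poisson draws by inversion of the truncated CDF."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    u = rng.uniform(size=n)
    # P(Y <= k | Y >= 1) = (F(k) - F(0)) / (1 - F(0))
    from scipy.stats import poisson

    p0 = poisson.cdf(0, lam)
    return poisson.ppf(p0 + u * (1.0 - p0), lam).astype(int)


def zt_negbin_sizes(
    rng: np.random.Generator, size: float, mean: float, n: int
) -> np.ndarray:
    """Zero-truncated negative binomial draws (inversion), NB mean before truncation."""
    if size <= 0 or mean <= 0:
        raise ValueError("size and mean must be > 0")
    from scipy.stats import nbinom

    p = size / (size + mean)
    u = rng.uniform(size=n)
    p0 = nbinom.cdf(0, size, p)
    return nbinom.ppf(p0 + u * (1.0 - p0), size, p).astype(int)


def generate_groups(
    config: SurveyConfig,
    density_by_stratum: Sequence[tuple[tuple[float, float, float, float], float]] | float,
    group_size_law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int | None = None,
) -> list[TruthRecord]:
    """Poisson-process group centroids with clustered member points.

    `density_by_stratum` is either a single intensity (groups per km^2,
    applied to the bounding box of the transect layout padded by 500 m) or a
    list of ((e_min, e_max, n_min, n_max), intensity) strata. Member points
    are scattered uniformly in a disc of radius `config.group_cluster_radius`
    so a 200 m chain rule keeps generated groups intact.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if group_size_law is None:
        group_size_law = lambda r, n: zt_negbin_sizes(  # noqa: E731
            r, config.group_size_dispersion, config.group_size_mean, n
        )

    if isinstance(density_by_stratum, (int, float)):
        pad = 500.0
        e_max = (config.n_transects - 1) * config.transect_spacing + pad
        strata = [((-pad, e_max, -pad, config.transect_length + pad), float(density_by_stratum))]
    else:
        strata = [(tuple(bbox), float(d)) for bbox, d in density_by_stratum]
    if any(d < 0 for _, d in strata):
        raise ValueError("densities must be >= 0")

    records: list[TruthRecord] = []
    gid = 0
    for (e0, e1, n0, n1), dens in strata:
        area_km2 = (e1 - e0) * (n1 - n0) / 1e6
        n_groups = rng.poisson(dens * area_km2)
        if n_groups == 0:
            continue
        cents = np.column_stack(
            [rng.uniform(e0, e1, n_groups), rng.uniform(n0, n1, n_groups)]
        )
        sizes = group_size_law(rng, n_groups)
        for c, s in zip(cents, sizes):
            s = int(max(s, 1))
            theta = rng.uniform(0, 2 * np.pi, s)
            r = config.group_cluster_radius * np.sqrt(rng.uniform(size=s))
            members = [
                (float(c[0] + ri * np.cos(ti)), float(c[1] + ri * np.sin(ti)))
                for ri, ti in zip(r, theta)
            ]
            avail = {
                "observer": bool(rng.uniform() < config.availability),
                "imagery": bool(rng.uniform() < config.availability),
            }
            records.append(TruthRecord(gid, (float(c[0]), float(c[1])), members, avail))
            gid += 1
    return records


def generate_telemetry(
    config: SurveyConfig, seed: int | None = None
) -> pd.DataFrame:
    """Per-image poses along each transect for both cameras.

    Capture times follow the forward-lap schedule; pitch/roll are
    Normal(0, attitude_sigma), azimuth is the transect heading plus crab
    noise, altitude is nominal plus Normal(0, altitude_sigma). Both cameras
    fire simultaneously at each epoch.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    interval = schedule_capture_interval(
        config.drone_altitude,
        config.camera_focal_length,
        config.sensor_height,
        config.target_forward_lap,
        config.ground_speed,
    )
    rows = []
    img = 0
    for t_idx, (start, end) in enumerate(generate_transect_layout(config)):
        length = math.hypot(end[0] - start[0], end[1] - start[1])
        heading = math.degrees(math.atan2(end[0] - start[0], end[1] - start[1])) % 360
        n_caps = int(length / (config.ground_speed * interval)) + 1
        crab = rng.normal(0, config.crab_sigma) if config.crab_sigma > 0 else 0.0
        for k in range(n_caps):
            t = k * interval
            chain = config.ground_speed * t
            e = start[0] + (end[0] - start[0]) * chain / length
            n = start[1] + (end[1] - start[1]) * chain / length
            alt = config.drone_altitude + (
                rng.normal(0, config.altitude_sigma) if config.altitude_sigma > 0 else 0.0
            )
            pitch = rng.normal(0, config.attitude_sigma) if config.attitude_sigma > 0 else 0.0
            roll = rng.normal(0, config.attitude_sigma) if config.attitude_sigma > 0 else 0.0
            for cam_id in ("north", "south"):
                rows.append(
                    dict(
                        image_id=f"T{t_idx}_{cam_id[0].upper()}{k:05d}",
                        camera_id=cam_id,
                        transect_id=t_idx,
                        time=t_idx * 1e5 + t,
                        easting=e,
                        northing=n,
                        altitude=alt,
                        pitch=pitch,
                        roll=roll,
                        azimuth=(heading + crab) % 360,
                        chainage=chain,
                    )
                )
                img += 1
    return pd.DataFrame(rows)


def _cameras(config: SurveyConfig) -> dict[str, CameraModel]:
    """Two cameras tilted in opposite directions about the along-track axis."""
    base = dict(
        focal_length=config.camera_focal_length,
        sensor_width=config.sensor_width,
        sensor_height=config.sensor_height,
        pixels=config.sensor_pixels,
    )
    return {
        "north": CameraModel(mount_tilt=+config.mount_tilt, **base),
        "south": CameraModel(mount_tilt=-config.mount_tilt, **base),
    }


def ground_to_pixel(
    pose: Pose, camera: CameraModel, point: tuple[float, float]
) -> tuple[float, float] | None:
    """Pixel coordinates of a ground point, or None if outside the frame."""
    from skystrip.geometry import _rot_forward, _rot_right

    az = math.radians(pose.azimuth)
    d_world = np.array(
        [point[0] - pose.easting, point[1] - pose.northing, -pose.altitude]
    )
    fwd = d_world[0] * math.sin(az) + d_world[1] * math.cos(az)
    right = d_world[0] * math.cos(az) - d_world[1] * math.sin(az)
    d_body = np.array([fwd, right, -d_world[2]])
    d_cam = _rot_forward(camera.mount_tilt).T @ (
        _rot_forward(pose.roll).T @ (_rot_right(pose.pitch).T @ d_body)
    )
    if d_cam[2] <= 0:
        return None
    eta = d_cam[0] / d_cam[2] * camera.focal_length  # along-track (m on sensor)
    xi = d_cam[1] / d_cam[2] * camera.focal_length  # across-track
    cols, rows = camera.pixels
    col = cols / 2.0 + xi * cols / camera.sensor_width
    row = rows / 2.0 - eta * rows / camera.sensor_height
    if 0 <= col <= cols and 0 <= row <= rows:
        return (float(col), float(row))
    return None


@dataclass
class PlatformSpec:
    """Forward-model detection parameters for one platform."""

    platform: str  # 'observer' or 'imagery'
    p_occasions: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.p_occasions):
            raise ValueError("occasion probabilities must be in [0, 1]")


def generate_detections(
    truth: Sequence[TruthRecord],
    platform_spec: PlatformSpec,
    config: SurveyConfig,
    telemetry: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bernoulli thinning of available individuals inside the covered region.

    Observer occasions are (front, back) seats per side; each available
    individual inside a strip is detected by occasion i with probability
    p_i, producing one call row per detecting occasion with zone and
    time-abeam. Imagery occasions are reviewers; each detecting reviewer
    yields one row per frame whose footprint contains the individual.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    layout = generate_transect_layout(config)
    p = platform_spec.p_occasions
    rows: list[dict] = []

    if platform_spec.platform == "observer":
        frac = 1.0  # strips are defined at ground scale here
        gap_half = config.observer_gap / 2.0 * frac
        widths = config.observer_strip_widths
        det_id = 0
        for rec in truth:
            if not rec.available.get("observer", True):
                continue
            for m_idx, (me, mn) in enumerate(rec.members):
                # nearest transect; sideways offset from its centreline
                t_idx = int(
                    np.argmin([abs(me - s[0][0]) for s in layout])
                )
                cl = layout[t_idx][0][0]
                off = me - cl
                if not (0.0 <= mn <= config.transect_length):
                    continue
                side = "port" if off < 0 else "starboard"
                width = widths[0] if side == "port" else widths[1]
                a = abs(off)
                if not (gap_half <= a <= gap_half + width):
                    continue
                zone = int((a - gap_half) // 50.0)
                t_abeam = t_idx * 1e5 + mn / config.ground_speed
                hist = rng.uniform(size=len(p)) < np.asarray(p)
                for occ, det in enumerate(hist):
                    if det:
                        rows.append(
                            dict(
                                detection_id=det_id,
                                truth_group_id=rec.group_id,
                                member_index=m_idx,
                                transect_id=t_idx,
                                side=side,
                                seat="front" if occ == 0 else "back",
                                zone=zone,
                                time_abeam=t_abeam,
                                group_size=rec.true_group_size,
                                easting=me,
                                northing=mn,
                            )
                        )
                        det_id += 1
        return pd.DataFrame(
            rows,
            columns=[
                "detection_id", "truth_group_id", "member_index", "transect_id",
                "side", "seat", "zone", "time_abeam", "group_size",
                "easting", "northing",
            ],
        )

    if platform_spec.platform != "imagery":
        raise ValueError("platform must be 'observer' or 'imagery'")
    if telemetry is None:
        raise ValueError("imagery detections need telemetry")
    cams = _cameras(config)
    # pre-compute poses once
    poses = [
        (
            r.image_id,
            r.camera_id,
            r.transect_id,
            Pose(r.easting, r.northing, r.altitude, r.pitch, r.roll, r.azimuth, r.time),
        )
        for r in telemetry.itertuples()
    ]
    det_id = 0
    for rec in truth:
        if not rec.available.get("imagery", True):
            continue
        for m_idx, (me, mn) in enumerate(rec.members):
            # frames plausibly containing the point (cheap prefilter)
            containing = []
            for image_id, cam_id, t_idx, pose in poses:
                if abs(pose.easting - me) > 600 or abs(pose.northing - mn) > 400:
                    continue
                px = ground_to_pixel(pose, cams[cam_id], (me, mn))
                if px is not None:
                    containing.append((image_id, cam_id, t_idx, px))
            if not containing:
                continue
            hist = rng.uniform(size=len(p)) < np.asarray(p)
            for occ, det in enumerate(hist):
                if not det:
                    continue
                for image_id, cam_id, t_idx, (col, row) in containing:
                    rows.append(
                        dict(
                            detection_id=det_id,
                            truth_group_id=rec.group_id,
                            member_index=m_idx,
                            reviewer_id=occ + 1,
                            image_id=image_id,
                            camera_id=cam_id,
                            transect_id=t_idx,
                            pixel_col=col,
                            pixel_row=row,
                            easting=me,
                            northing=mn,
                            certainty="certain",
                            calf=False,
                        )
                    )
                    det_id += 1
    return pd.DataFrame(
        rows,
        columns=[
            "detection_id", "truth_group_id", "member_index", "reviewer_id",
            "image_id", "camera_id", "transect_id", "pixel_col", "pixel_row",
            "easting", "northing", "certainty", "calf",
        ],
    )


def generate_environment(
    config: SurveyConfig, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Visibility runs, sea-state track, per-image glitter, per-transect okta.

    Visibility is piecewise constant along each transect with exponential
    (memoryless) run lengths of mean `visibility_mean_run`; sea state is
    attached to 1 Hz track fixes; glitter scores {0..3} go to north-camera
    images only; okta is drawn per transect.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    vis_rows, track_rows, cloud_rows = [], [], []
    for t_idx in range(config.n_transects):
        # visibility runs
        chain = 0.0
        while chain < config.transect_length:
            run = rng.exponential(config.visibility_mean_run)
            run = max(run, 50.0)
            end = min(chain + run, config.transect_length)
            vis_rows.append(
                dict(
                    transect_id=t_idx,
                    start_chainage=chain,
                    end_chainage=end,
                    visibility=int(rng.integers(1, 5)),
                )
            )
            chain = end
        # 1 Hz track with sea state held between ~2 min updates
        n_fix = int(config.transect_length / config.ground_speed) + 1
        sea = float(rng.choice(config.sea_state_levels))
        glitter_obs = int(rng.integers(0, 4))
        for k in range(n_fix):
            if k % 120 == 0 and k > 0:
                sea = float(rng.choice(config.sea_state_levels))
                glitter_obs = int(rng.integers(0, 4))
            chain_k = min(k * config.ground_speed, config.transect_length)
            vals = dict(
                transect_id=t_idx,
                time=t_idx * 1e5 + k,
                chainage=chain_k,
                easting=t_idx * config.transect_spacing,
                northing=chain_k,
                sea_state=sea,
                glitter_observer=glitter_obs,
            )
            track_rows.append(vals)
        cloud_rows.append(
            dict(transect_id=t_idx, okta=int(rng.choice(config.cloud_okta_choices)))
        )
    return {
        "visibility": pd.DataFrame(vis_rows),
        "track": pd.DataFrame(track_rows),
        "cloud": pd.DataFrame(cloud_rows),
    }


def glitter_for_images(
    telemetry: pd.DataFrame, config: SurveyConfig, seed: int | None = None
) -> pd.DataFrame:
    """Ordinal glitter score {0..3} for each north-camera image."""
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    north = telemetry[telemetry.camera_id == "north"]
    return pd.DataFrame(
        dict(
            image_id=north.image_id.to_numpy(),
            transect_id=north.transect_id.to_numpy(),
            chainage=north.chainage.to_numpy(),
            glitter=rng.integers(0, 4, size=len(north)),
        )
    )


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    rows = []
    for rec in truth:
        for i, (e, n) in enumerate(rec.members):
            rows.append(
                dict(
                    group_id=rec.group_id,
                    member_index=i,
                    easting=e,
                    northing=n,
                    centroid_e=rec.centroid[0],
                    centroid_n=rec.centroid[1],
                    true_group_size=rec.true_group_size,
                    available_observer=rec.available.get("observer", True),
                    available_imagery=rec.available.get("imagery", True),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group_id", "member_index", "easting", "northing", "centroid_e",
            "centroid_n", "true_group_size", "available_observer",
            "available_imagery",
        ],
    )


def transects_geojson(config: SurveyConfig) -> dict:
    """Transect centrelines as a GeoJSON FeatureCollection (planar CRS)."""
    feats = []
    for i, (start, end) in enumerate(generate_transect_layout(config)):
        feats.append(
            {
                "type": "Feature",
                "properties": {"transect_id": i},
                "geometry": {"type": "LineString", "coordinates": [list(start), list(end)]},
            }
        )
    return {
        "type": "FeatureCollection",
        "metadata": {"crs": "local planar metres"},
        "features": feats,
    }


def simulate_survey(config: SurveyConfig, seed: int | None = None, out_dir=None) -> dict:
    """Generate a full synthetic survey; optionally write the canonical tables.

    Returns a dict of DataFrames: images, detections (imagery), calls
    (observer), track, cloud, visibility, glitter, truth.
    """
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(master)
    sub = rng.integers(0, 2**31 - 1, size=6)
    truth = generate_groups(config, config.group_density_per_km2, seed=int(sub[0]))
    telemetry = generate_telemetry(config, seed=int(sub[1]))
    env = generate_environment(config, seed=int(sub[2]))
    glitter = glitter_for_images(telemetry, config, seed=int(sub[3]))
    calls = generate_detections(
        truth, PlatformSpec("observer", config.observer_p), config, seed=int(sub[4])
    )
    dets = generate_detections(
        truth,
        PlatformSpec("imagery", config.reviewer_p),
        config,
        telemetry=telemetry,
        seed=int(sub[5]),
    )
    tables = {
        "images": telemetry,
        "detections": dets,
        "calls": calls,
        "track": env["track"],
        "cloud": env["cloud"],
        "visibility": env["visibility"],
        "glitter": glitter,
        "truth": truth_to_frame(truth),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "transects.geojson", "w") as fh:
            json.dump(transects_geojson(config), fh)
        config.to_yaml(out / "config.yaml")
    return tables
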