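"""Survey configuration shared by all stages.

All lengths are metres in a local planar frame (easting/northing), the sea
surface is the plane z = 0, and angles are degrees unless noted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class SurveyConfig:
    """Parameters of a dual-platform strip-transect survey.

    Defaults follow the reference survey design: parallel transects 4.6 km
    apart; two observer strips of 206 m (port) and 203 m (starboard) with a
    296 m gap at the 152 m target altitude; a two-camera drone imaging rig
    (50 mm lens, 23.2 x 15.4 mm sensor, 6016 x 4000 px, each camera tilted
    11.5 deg from vertical in opposite directions) flown at 396 or 427 m
    with a 40% forward-lap target.
    """

    transect_spacing: float = 4600.0
    transect_length: float = 10_000.0
    n_transects: int = 2
    observer_strip_widths: tuple[float, float] = (206.0, 203.0)
    observer_gap: float = 296.0
    observer_target_altitude: float = 152.0
    drone_altitude: float = 396.0
    camera_focal_length: float = 0.050
    sensor_width: float = 0.0232
    sensor_height: float = 0.0154
    sensor_pixels: tuple[int, int] = (6016, 4000)
    mount_tilt: float = 11.5
    target_forward_lap: float = 0.40
    ground_speed: float = 30.87  # 60 kn
    seed: int = 0

    # synthetic-data knobs (not part of the physical survey design)
    group_density_per_km2: float = 0.5
    group_cluster_radius: float = 60.0
    group_size_mean: float = 1.6
    group_size_dispersion: float = 0.8
    availability: float = 1.0
    attitude_sigma: float = 2.0
    altitude_sigma: float = 3.0
    crab_sigma: float = 2.0
    observer_p: tuple[float, float] = (0.74, 0.81)
    reviewer_p: tuple[float, ...] = (0.917, 0.979, 0.802)
    visibility_mean_run: float = 5000.0
    sea_state_levels: tuple[int, ...] = (0, 1, 2, 3)
    cloud_okta_choices: tuple[int, ...] = (0, 1, 5, 6, 7, 8)

    def __post_init__(self) -> None:
        for name in (
            "transect_spacing",
            "transect_length",
            "observer_gap",
            "observer_target_altitude",
            "drone_altitude",
            "camera_focal_length",
            "sensor_width",
            "sensor_height",
            "ground_speed",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_transects < 1:
            raise ValueError("n_transects must be >= 1")
        if any(w <= 0 for w in self.observer_strip_widths):
            raise ValueError("observer strip widths must be > 0")
        if not 0.0 <= self.target_forward_lap < 1.0:
            raise ValueError("target_forward_lap must be in [0, 1)")
        if not 0.0 <= self.mount_tilt < 45.0:
            raise ValueError("mount_tilt must be in [0, 45)")

    @property
    def altitude_fraction(self) -> float:
        return self.drone_altitude / self.observer_target_altitude

    @classmethod
    def from_yaml(cls, path) -> "SurveyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("observer_strip_widths", "sensor_pixels", "observer_p",
                    "reviewer_p", "sea_state_levels", "cloud_okta_choices"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def default_config(**overrides) -> SurveyConfig:
    return SurveyConfig(**overrides)
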