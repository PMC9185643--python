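"""Camera/optics model: flight altitude, ground footprint and tile steps.

A nadir-pointing pinhole camera at altitude H images a ground rectangle

    D_fov_x = 2 H tan(beta/2),   D_fov_y = 2 H tan(alpha/2)

where beta/alpha are the horizontal/vertical full field-of-view angles,
tan(beta/2) = sensor_width / (2 F_l). The altitude that achieves a target
ground sampling distance (GSD, meters of ground per pixel) is

    H_f = GSD * F_l / pixel_pitch

with focal length F_l and pixel pitch both in mm. These two relations are
consistent: at H_f the footprint equals GSD times the pixel counts exactly.

Tile-to-tile step distances are footprint times a step fraction O in (0, 1]:
O = 1 means adjacent tiles touch with no overlap, O = 0.2 means an 80%
overlap between successive images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import InvalidInputError
from .geo import LocalOffset

__all__ = [
    "CameraModel",
    "Footprint",
    "OverlapSpec",
    "flight_height",
    "ground_footprint",
    "step_distances",
    "CAMERA_CATALOGUE",
]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: focal length (mm), pixel pitch (mm/px), sensor pixels."""

    focal_length: float  # mm
    pixel_pitch: float  # mm per pixel
    n_px_x: int
    n_px_y: int
    name: str = "camera"

    def __post_init__(self):
        for label, v in (
            ("focal_length", self.focal_length),
            ("pixel_pitch", self.pixel_pitch),
            ("n_px_x", self.n_px_x),
            ("n_px_y", self.n_px_y),
        ):
            if not (v > 0 and math.isfinite(v)):
                raise InvalidInputError(f"{label} must be positive, got {v}")

    @property
    def sensor_width(self) -> float:
        """Sensor width in mm (pixel pitch x horizontal pixel count)."""
        return self.pixel_pitch * self.n_px_x

    @property
    def sensor_height(self) -> float:
        """Sensor height in mm."""
        return self.pixel_pitch * self.n_px_y

    @property
    def beta(self) -> float:
        """Horizontal full field-of-view angle, radians, in (0, pi)."""
        return 2.0 * math.atan(self.sensor_width / (2.0 * self.focal_length))

    @property
    def alpha(self) -> float:
        """Vertical full field-of-view angle, radians, in (0, pi)."""
        return 2.0 * math.atan(self.sensor_height / (2.0 * self.focal_length))

    @classmethod
    def from_dict(cls, cfg: dict) -> "CameraModel":
        """Build from a config mapping.

        Accepts either ``pixel_pitch_mm`` directly or ``sensor_width_mm`` (pitch
        is then sensor_width / n_px_x). Keys: focal_length_mm, pixel_pitch_mm |
        sensor_width_mm, n_px_x, n_px_y, name.
        """
        try:
            focal = float(cfg["focal_length_mm"])
            n_px_x = int(cfg["n_px_x"])
            n_px_y = int(cfg["n_px_y"])
        except KeyError as e:
            raise InvalidInputError(f"camera config missing key {e.args[0]!r}") from None
        if "pixel_pitch_mm" in cfg:
            pitch = float(cfg["pixel_pitch_mm"])
        elif "sensor_width_mm" in cfg:
            pitch = float(cfg["sensor_width_mm"]) / n_px_x
        else:
            raise InvalidInputError(
                "camera config needs 'pixel_pitch_mm' or 'sensor_width_mm'"
            )
        return cls(focal, pitch, n_px_x, n_px_y, name=str(cfg.get("name", "camera")))

    @classmethod
    def from_file(cls, path: str | Path) -> "CameraModel":
        """Load a camera definition from a YAML (or JSON) key-value file."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise InvalidInputError(f"camera file {path} is not a key-value mapping")
        return cls.from_dict(cfg)


@dataclass(frozen=True)
class Footprint:
    """Ground rectangle imaged from one exposure: extents in meters."""

    d_fov_x: float
    d_fov_y: float

    def __post_init__(self):
        if not (self.d_fov_x > 0 and self.d_fov_y > 0):
            raise InvalidInputError("footprint extents must be positive")


@dataclass(frozen=True)
class OverlapSpec:
    """Step fractions along x and y: 1 = no overlap, 0.2 = 80% image overlap."""

    ox: float = 1.0
    oy: float = 1.0

    def __post_init__(self):
        for label, v in (("ox", self.ox), ("oy", self.oy)):
            if not (0.0 < v <= 1.0):
                raise InvalidInputError(f"{label} must be in (0, 1], got {v}")

    @property
    def overlap_x(self) -> float:
        """Image overlap fraction along x (1 - step fraction)."""
        return 1.0 - self.ox

    @property
    def overlap_y(self) -> float:
        return 1.0 - self.oy


def flight_height(gsd: float, cam: CameraModel) -> float:
    """Altitude (m AGL) achieving the target GSD (m/pixel): ``gsd * F_l / pitch``."""
    if not (gsd > 0 and math.isfinite(gsd)):
        raise InvalidInputError(f"gsd must be positive, got {gsd}")
    return gsd * cam.focal_length / cam.pixel_pitch


def ground_footprint(h: float, cam: CameraModel) -> Footprint:
    """Ground footprint at altitude ``h`` meters."""
    if not (h > 0 and math.isfinite(h)):
        raise InvalidInputError(f"altitude must be positive, got {h}")
    return Footprint(
        d_fov_x=2.0 * h * math.tan(cam.beta / 2.0),
        d_fov_y=2.0 * h * math.tan(cam.alpha / 2.0),
    )


def step_distances(fp: Footprint, ov: OverlapSpec) -> LocalOffset:
    """Center-to-center displacement between adjacent tiles, meters."""
    return LocalOffset(dx=fp.d_fov_x * ov.ox, dy=fp.d_fov_y * ov.oy)


#: Small built-in catalogue of example cameras (values typical of the class of
#: sensor, for demos and fixtures; not manufacturer-certified).
CAMERA_CATALOGUE: dict[str, CameraModel] = {
    # 8 mm lens, 3 um pitch: the worked example (gsd 0.03 m/px -> 80 m altitude)
    "demo-8mm": CameraModel(8.0, 0.003, 4000, 3000, name="demo-8mm"),
    # Parrot-Sequoia-like narrow-band multispectral head
    "sequoia-like-ms": CameraModel(3.98, 0.00375, 1280, 960, name="sequoia-like-ms"),
    # generic 1-inch RGB mapping camera
    "rgb-1inch": CameraModel(10.4, 0.0024, 5472, 3648, name="rgb-1inch"),
}
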