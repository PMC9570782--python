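"""Imaging-sonar geometry: spherical beams, critical points, pixel-to-world.

An imaging sonar reports echoes on a 2-D fan: range along one axis, azimuth
along the other.  The elevation angle of a return is not observable, so the
sonar image is treated as a vertical slice through the scene — every pixel's
3-D point shares the device's y-coordinate.  The world frame follows the
device convention: origin at ``[0, d, 0]`` where ``d`` is the device depth,
x along the pond, z downward in the image row direction.

Angles are stored in radians; the JSON config accepts degrees under keys with
an explicit ``_deg`` suffix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry_stereo import PixelCoord, Point3D

__all__ = [
    "SonarGeometry",
    "EulerRotation",
    "GeometryInfeasibleError",
    "spherical_to_cartesian",
    "project_to_sonar_plane",
    "critical_point_local",
    "local_to_world",
    "sonar_pixel_to_3d",
    "pixel_physical_size",
]


class GeometryInfeasibleError(ValueError):
    """Tilt/spread/azimuth combination puts the critical point off the sphere."""


@dataclass(frozen=True)
class SonarGeometry:
    """Physical configuration of the imaging sonar.

    Parameters
    ----------
    tilt : float
        Downward tilt of the transducer, radians, in [0, pi/2).
    spread : float
        Angular width of the beam fan, radians, >= 0.
    pixel_width, pixel_height : float
        Physical footprint of one sonar-image pixel, cm.
    device_position : tuple of float
        (xS, yS, zS) of the transducer in the world frame, cm.  yS defaults
        to 0 under the ``[0, d, 0]`` world-origin convention.
    device_depth : float
        Submersion depth d of the transducer, cm.
    image_shape : tuple of int or None
        (cols, rows) of the sonar image, used for pixel bounds checks.
    """

    tilt: float = 0.0
    spread: float = 0.0
    pixel_width: float = 1.0
    pixel_height: float = 1.0
    device_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    device_depth: float = 0.0
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.pixel_width <= 0 or self.pixel_height <= 0:
            raise ValueError("pixel size must be positive")
        if not (0 <= self.tilt < math.pi / 2):
            raise ValueError(f"tilt must lie in [0, pi/2), got {self.tilt}")
        if self.spread < 0:
            raise ValueError(f"spread must be non-negative, got {self.spread}")

    @classmethod
    def from_json(cls, path: str | Path) -> "SonarGeometry":
        """Build from config keys tilt_deg, spread_deg, pond_length_cm,
        pond_width_cm, image_cols, image_rows, device_x_cm, device_depth_cm."""
        with open(path) as fh:
            cfg = json.load(fh)
        return cls.from_config(cfg)

    @classmethod
    def from_config(cls, cfg: dict) -> "SonarGeometry":
        cols = int(cfg["image_cols"])
        rows = int(cfg["image_rows"])
        w, h = pixel_physical_size(
            (float(cfg["pond_length_cm"]), float(cfg["pond_width_cm"])), (cols, rows)
        )
        return cls(
            tilt=math.radians(float(cfg.get("tilt_deg", 0.0))),
            spread=math.radians(float(cfg.get("spread_deg", 0.0))),
            pixel_width=w,
            pixel_height=h,
            device_position=(float(cfg.get("device_x_cm", 0.0)), 0.0, 0.0),
            device_depth=float(cfg.get("device_depth_cm", 0.0)),
            image_shape=(cols, rows),
        )


@dataclass(frozen=True)
class EulerRotation:
    """Roll/pitch/yaw Euler angles; composed as R = Rz(yaw) Ry(pitch) Rx(roll)."""

    roll: float = 0.0
    pitch: float = 0.0
    yaw: float = 0.0

    def matrix(self) -> np.ndarray:
        cr, sr = math.cos(self.roll), math.sin(self.roll)
        cp, sp = math.cos(self.pitch), math.sin(self.pitch)
        cy, sy = math.cos(self.yaw), math.sin(self.yaw)
        rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
        ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
        rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1]])
        return rz @ ry @ rx


def spherical_to_cartesian(r: float, azimuth: float, elevation: float) -> Point3D:
    """(r, theta, phi) -> (r cos(theta) cos(phi), r sin(theta) cos(phi), r sin(phi))."""
    if r < 0:
        raise ValueError(f"range must be non-negative, got {r}")
    ce = math.cos(elevation)
    return Point3D(
        r * math.cos(azimuth) * ce,
        r * math.sin(azimuth) * ce,
        r * math.sin(elevation),
    )


def project_to_sonar_plane(r: float, azimuth: float) -> tuple[float, float]:
    """Project a beam return onto the sonar image plane, discarding elevation.

    Returns the in-plane coordinates ``(r cos(theta), r sin(theta))``.
    """
    if r < 0:
        raise ValueError(f"range must be non-negative, got {r}")
    return (r * math.cos(azimuth), r * math.sin(azimuth))


def critical_point_local(r_cp: float, theta_cp: float, geometry: SonarGeometry) -> Point3D:
    """Locate the critical (shortest-range reflection) point of a beam.

    In the sonar's local frame the beam tilted by ``t`` with spread ``s``
    first strikes the target at

        x = r sqrt(1 - sin^2((t+s)/2) - sin^2(theta)),
        y = r sin(theta),
        z = r sin((t+s)/2).

    Raises
    ------
    GeometryInfeasibleError
        If the radicand is negative (no real intersection).
    """
    if r_cp < 0:
        raise ValueError(f"range must be non-negative, got {r_cp}")
    half = (geometry.tilt + geometry.spread) / 2.0
    radicand = 1.0 - math.sin(half) ** 2 - math.sin(theta_cp) ** 2
    if radicand < 0:
        raise GeometryInfeasibleError(
            f"tilt+spread {half * 2:.4f} rad with azimuth {theta_cp:.4f} rad "
            "leaves no real critical point"
        )
    return Point3D(
        r_cp * math.sqrt(radicand),
        r_cp * math.sin(theta_cp),
        r_cp * math.sin(half),
    )


def local_to_world(
    point: Point3D, rotation: EulerRotation, geometry: SonarGeometry
) -> Point3D:
    """Map a sonar-local point into world coordinates: device + R @ point."""
    world = np.asarray(geometry.device_position, dtype=float) + rotation.matrix() @ point.to_array()
    return Point3D.from_array(world)


def sonar_pixel_to_3d(pixel: PixelCoord, geometry: SonarGeometry) -> Point3D:
    """World 3-D coordinates of a sonar-image pixel.

    The image column runs opposite to the world x-axis from the device at
    ``xS``, and the row measures depth: ``(xS - u*w, yS, v*h)``.

    Raises
    ------
    IndexError
        If the geometry carries an image shape and the pixel lies outside it.
    """
    if geometry.image_shape is not None:
        cols, rows = geometry.image_shape
        if not (0 <= pixel.u <= cols and 0 <= pixel.v <= rows):
            raise IndexError(
                f"pixel ({pixel.u}, {pixel.v}) outside sonar image {cols}x{rows}"
            )
    xs, ys, _ = geometry.device_position
    return Point3D(
        xs - pixel.u * geometry.pixel_width,
        ys,
        pixel.v * geometry.pixel_height,
    )


def pixel_physical_size(
    pond_extent: tuple[float, float], image_shape: tuple[int, int]
) -> tuple[float, float]:
    """Physical footprint (w, h) in cm of one sonar pixel.

    ``pond_extent`` is (length_cm, width_cm); ``image_shape`` is (cols, rows).
    """
    length_cm, width_cm = pond_extent
    cols, rows = image_shape
    if length_cm <= 0 or width_cm <= 0 or cols <= 0 or rows <= 0:
        raise ZeroDivisionError("pond extent and image shape must be positive")
    return (length_cm / cols, width_cm / rows)
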