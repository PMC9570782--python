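"""Stereo disparity and triangulation on rectified image pairs.

A rectified stereo pair places corresponding scene points on the same image
row, so matching reduces to a one-dimensional search along the row.  Depth
follows from the disparity ``d`` (left column minus right column) through the
pinhole relation ``z = f * b / d`` with focal length ``f`` (pixels) and
baseline ``b`` (cm between camera centres).

Pixel convention throughout the package: ``(u, v) = (column, row)``, 0-based,
origin at the top-left corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "PixelCoord",
    "Point3D",
    "EpipolarViolationError",
    "DegenerateDepthError",
    "compute_disparity",
    "find_correspondence",
    "triangulate",
    "project_to_pixel",
]


class EpipolarViolationError(ValueError):
    """Left/right pixels sit on different rectified rows."""


class DegenerateDepthError(ValueError):
    """Disparity is zero or negative; depth is undefined."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters of the (rectified) stereo rig.

    Parameters
    ----------
    f : float
        Focal length in pixels.
    cx, cy : float
        Principal point in pixels.
    baseline : float
        Distance between the left and right camera centres in cm.
    """

    f: float
    cx: float
    cy: float
    baseline: float

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError(f"focal length must be positive, got {self.f}")
        if self.baseline <= 0:
            raise ValueError(f"baseline must be positive, got {self.baseline}")

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraIntrinsics":
        """Load intrinsics from a JSON file with keys f_px, cx, cy, baseline_cm."""
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(
            f=float(cfg["f_px"]),
            cx=float(cfg["cx"]),
            cy=float(cfg["cy"]),
            baseline=float(cfg["baseline_cm"]),
        )


@dataclass(frozen=True)
class PixelCoord:
    """Image pixel: ``u`` = column, ``v`` = row (0-based, origin top-left)."""

    u: float
    v: float

    def __post_init__(self) -> None:
        if self.u < 0 or self.v < 0:
            raise ValueError(f"pixel coordinates must be non-negative, got ({self.u}, {self.v})")


@dataclass(frozen=True)
class Point3D:
    """3D point in cm; components must be finite."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError(f"non-finite 3D point ({self.x}, {self.y}, {self.z})")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Point3D":
        x, y, z = np.asarray(a, dtype=float).ravel()
        return cls(x, y, z)


def compute_disparity(
    left_pixel: PixelCoord,
    right_pixel: PixelCoord,
    epipolar_tol: float = 0.0,
) -> float:
    """Disparity of a correspondence: left column minus right column.

    Raises
    ------
    EpipolarViolationError
        If the two pixels differ in row by more than ``epipolar_tol``.
    """
    if abs(left_pixel.v - right_pixel.v) > epipolar_tol:
        raise EpipolarViolationError(
            f"rows differ ({left_pixel.v} vs {right_pixel.v}) beyond tolerance {epipolar_tol}"
        )
    return left_pixel.u - right_pixel.u


def find_correspondence(
    left_image: np.ndarray,
    right_image: np.ndarray,
    left_pixel: PixelCoord,
    search_range: int = 64,
    window: int = 11,
) -> PixelCoord:
    """Block-matching correspondence search along the rectified row.

    A square window of odd side ``window`` centred on ``left_pixel`` is slid
    along the same row of the right image over disparities ``0..search_range``
    (rightward shifts of the scene, i.e. leftward moves of the right-image
    column).  The candidate minimising the sum of absolute differences wins;
    ties break toward the smallest disparity.

    Raises
    ------
    IndexError
        If the window around ``left_pixel`` does not fit inside the image.
    """
    left = np.asarray(left_image, dtype=float)
    right = np.asarray(right_image, dtype=float)
    if left.shape != right.shape:
        raise ValueError(f"image shapes differ: {left.shape} vs {right.shape}")
    if window % 2 != 1 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")

    u, v = int(round(left_pixel.u)), int(round(left_pixel.v))
    half = window // 2
    rows, cols = left.shape
    if not (half <= v < rows - half and half <= u < cols - half):
        raise IndexError(
            f"window of side {window} around pixel ({u}, {v}) exceeds image bounds {left.shape}"
        )

    patch = left[v - half : v + half + 1, u - half : u + half + 1]
    best_d = None
    best_cost = np.inf
    for d in range(0, search_range + 1):
        uc = u - d
        if uc - half < 0:
            break
        cand = right[v - half : v + half + 1, uc - half : uc + half + 1]
        cost = float(np.abs(patch - cand).sum())
        if cost < best_cost:  # strict: ties keep the smaller disparity
            best_cost = cost
            best_d = d
    if best_d is None:
        raise IndexError("search range leaves no valid candidate window")
    return PixelCoord(u - best_d, v)


def triangulate(
    left_pixel: PixelCoord,
    disparity: float,
    intrinsics: CameraIntrinsics,
) -> Point3D:
    """Back-project a left-image pixel with known disparity to camera 3D.

    ``z = f*b/d``; ``x = (u - cx) z / f``; ``y = (v - cy) z / f`` (cm).

    Raises
    ------
    DegenerateDepthError
        If disparity is not strictly positive.
    """
    if disparity <= 0:
        raise DegenerateDepthError(f"disparity must be positive, got {disparity}")
    z = intrinsics.f * intrinsics.baseline / disparity
    x = (left_pixel.u - intrinsics.cx) * z / intrinsics.f
    y = (left_pixel.v - intrinsics.cy) * z / intrinsics.f
    return Point3D(x, y, z)


def project_to_pixel(point: Point3D, intrinsics: CameraIntrinsics) -> tuple[float, float]:
    """Forward pinhole projection of a camera-frame point onto the left image.

    Returns raw ``(u, v)`` floats, which may fall outside the image bounds.
    """
    if point.z <= 0:
        raise DegenerateDepthError(f"point depth must be positive, got {point.z}")
    u = intrinsics.f * point.x / point.z + intrinsics.cx
    v = intrinsics.f * point.y / point.z + intrinsics.cy
    return (u, v)
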