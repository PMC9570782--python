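"""Opti-acoustic extrinsic calibration and overlap detection.

The sonar and the stereo rig observe the same markers (A, B, C, D per frame)
and each produces 3-D coordinates for them in its own frame.  A rigid
transform (rotation R, translation T) mapping sonar points into the optical
frame is estimated in closed form by orthogonal Procrustes: subtract the
centroids, take the SVD of the cross-covariance, and correct a possible
reflection.  The estimate minimises the mean squared residual

    L = (1/M) sum_ij || X_O,ij - (R X_S,ij + T) ||^2

over all points of all calibration frames.  With the transform in hand, the
region of the pond both sensors see is found by mapping sonar points into
the optical frame, keeping those that fall inside the camera's view frustum,
and bounding the surviving points in sonar pixel space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry_sonar import SonarGeometry
from .geometry_stereo import CameraIntrinsics, PixelCoord, Point3D

__all__ = [
    "RigidTransform",
    "MatchedPointSet",
    "OverlapResult",
    "RankDeficiencyError",
    "solve_transform",
    "fusion_loss",
    "apply_transform",
    "detect_overlap",
]


class RankDeficiencyError(ValueError):
    """Marker configuration is collinear/degenerate; rotation unrecoverable."""


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation mapping sonar 3-D coordinates to optical ones."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        T = np.asarray(self.translation, dtype=float).ravel()
        if R.shape != (3, 3) or T.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", T)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()},
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


@dataclass
class MatchedPointSet:
    """Corresponding sonar/optical 3-D marker points from one video frame."""

    sonar_points: Sequence[Point3D]
    optical_points: Sequence[Point3D]
    frame_id: int = 0

    def __post_init__(self) -> None:
        if len(self.sonar_points) != len(self.optical_points):
            raise ValueError("sonar and optical point lists must have equal length")
        if len(self.sonar_points) < 3:
            raise ValueError("need at least 3 matched points per frame")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        s = np.array([p.to_array() for p in self.sonar_points])
        o = np.array([p.to_array() for p in self.optical_points])
        return s, o


@dataclass
class OverlapResult:
    """Sonar points seen by both sensors plus their sonar-image bounding box."""

    overlapped_points: list[Point3D] = field(default_factory=list)
    x_lu: PixelCoord | None = None
    x_rb: PixelCoord | None = None

    @property
    def empty(self) -> bool:
        return len(self.overlapped_points) == 0


def _stack_matches(matches: Sequence[MatchedPointSet]) -> tuple[np.ndarray, np.ndarray]:
    if len(matches) == 0:
        raise ValueError("matches must be non-empty")
    sonar = np.vstack([m.arrays()[0] for m in matches])
    optical = np.vstack([m.arrays()[1] for m in matches])
    return sonar, optical


def solve_transform(
    matches: Sequence[MatchedPointSet], allow_scale: bool = False
) -> RigidTransform:
    """Closed-form least-squares rigid transform from matched 3-D point sets.

    Kabsch/Umeyama: centre both clouds, SVD the cross-covariance H = S~^T O~,
    set R = V diag(1, 1, det(V U^T)) U^T, T = o_bar - R s_bar.  With
    ``allow_scale`` a single isotropic scale is estimated too (similarity
    transform); the result is then re-orthonormalised into the returned
    rotation with the scale folded into a scaled rotation, so the default
    rigid path should be preferred unless the sensors disagree on scale.

    Raises
    ------
    RankDeficiencyError
        If the point configuration is collinear (cross-covariance rank < 2).
    """
    sonar, optical = _stack_matches(matches)
    s_bar = sonar.mean(axis=0)
    o_bar = optical.mean(axis=0)
    sc = sonar - s_bar
    oc = optical - o_bar
    H = sc.T @ oc
    U, sing, Vt = np.linalg.svd(H)
    # Collinear markers leave the rotation about the line unconstrained.
    if np.sum(sing > max(sing) * 1e-9) < 2:
        raise RankDeficiencyError("marker points are collinear or coincident")
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    if allow_scale:
        var_s = (sc ** 2).sum() / len(sc)
        scale = float((sing * np.diag(D)).sum() / (len(sc) * var_s))
        T = o_bar - scale * R @ s_bar
        return ScaledRigidTransform(R, T, scale)
    T = o_bar - R @ s_bar
    return RigidTransform(R, T)


@dataclass(frozen=True)
class ScaledRigidTransform(RigidTransform):
    """Similarity variant: optical = scale * R @ sonar + T."""

    scale: float = 1.0


def apply_transform(
    points: Sequence[Point3D], transform: RigidTransform
) -> list[Point3D]:
    """Map each point through R @ p + T (times scale for similarity)."""
    scale = getattr(transform, "scale", 1.0)
    arr = np.array([p.to_array() for p in points])
    if arr.size == 0:
        return []
    out = scale * arr @ transform.rotation.T + transform.translation
    return [Point3D.from_array(row) for row in out]


def fusion_loss(
    transform: RigidTransform, matches: Sequence[MatchedPointSet]
) -> float:
    """Mean squared residual (cm^2) of the transform over all matched points."""
    sonar, optical = _stack_matches(matches)
    scale = getattr(transform, "scale", 1.0)
    pred = scale * sonar @ transform.rotation.T + transform.translation
    return float(np.mean(np.sum((optical - pred) ** 2, axis=1)))


def detect_overlap(
    sonar_points: Sequence[Point3D],
    transform: RigidTransform,
    intrinsics: CameraIntrinsics,
    image_shape: tuple[int, int],
    geometry: SonarGeometry,
) -> OverlapResult:
    """Find the sonar points also visible to the optical camera.

    Each sonar-frame point is mapped into the optical frame; it is kept when
    its depth is positive and its pinhole projection lands inside the optical
    image of shape ``image_shape`` = (cols, rows).  Kept points are mapped
    back to sonar pixels by inverting the pixel-to-world relation
    (``u = (xS - x)/w``, ``v = z/h``) and the min/max corners of those pixels
    form the crop box.

    Returns an empty :class:`OverlapResult` (no corners) when nothing
    overlaps; that is a signal, not an error.
    """
    if len(sonar_points) == 0:
        raise ValueError("sonar_points must be non-empty")
    cols, rows = image_shape
    arr = np.array([p.to_array() for p in sonar_points])
    scale = getattr(transform, "scale", 1.0)
    cam = scale * arr @ transform.rotation.T + transform.translation
    z = cam[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = intrinsics.f * cam[:, 0] / z + intrinsics.cx
        v = intrinsics.f * cam[:, 1] / z + intrinsics.cy
    keep = (z > 0) & (u >= 0) & (u < cols) & (v >= 0) & (v < rows)
    if not keep.any():
        return OverlapResult()

    kept = arr[keep]
    xs = geometry.device_position[0]
    su = (xs - kept[:, 0]) / geometry.pixel_width
    sv = kept[:, 2] / geometry.pixel_height
    if geometry.image_shape is not None:
        scols, srows = geometry.image_shape
        su = np.clip(su, 0, scols)
        sv = np.clip(sv, 0, srows)
    return OverlapResult(
        overlapped_points=[Point3D.from_array(row) for row in kept],
        x_lu=PixelCoord(float(su.min()), float(sv.min())),
        x_rb=PixelCoord(float(su.max()), float(sv.max())),
    )
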