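"""Detector contracts with deterministic classical fallbacks.

The metric pipelines need three perception primitives: instance masks of
individual fish (for the length pipeline), a semantic mask of the feeding
fish school, and a gathering/dispersing decision per frame.  In deployment
these come from learned models (instance segmentation, a U-Net, a frame
classifier); here each is a contract — any callable with the right signature
plugs in — plus a deterministic intensity-based fallback, so every
downstream computation is exercisable without trained weights.

Fallback heuristics rest on the physics of feeding imagery: a gathered
school grabbing pellets produces one large bright connected blob near the
surface, while a dispersed school leaves only sparse faint specks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import measure, morphology

__all__ = [
    "InstanceMask",
    "FrameStack",
    "FishRegionFrame",
    "build_frame_stack",
    "classify_gathering_fallback",
    "segment_fish_region_fallback",
    "load_external_masks",
    "accuracy_from_confusion",
]


@dataclass
class InstanceMask:
    """Boolean pixel mask of a single detected fish instance."""

    mask: np.ndarray
    frame_id: int = 0
    instance_id: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("instance mask must be a 2-D grid")
        if not self.mask.any():
            raise ValueError("instance mask must contain at least one pixel")


@dataclass
class FrameStack:
    """Five temporally aligned frames: target, two before, two after."""

    frames: np.ndarray  # (5, rows, cols)
    target_index: int

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.shape[0] != 5:
            raise ValueError("a frame stack holds exactly 5 frames")

    @property
    def target(self) -> np.ndarray:
        return self.frames[2]


@dataclass
class FishRegionFrame:
    """Segmented fish-school region with the source pixel values."""

    region: np.ndarray  # boolean mask
    values: np.ndarray  # grayscale source frame
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=bool)
        self.values = np.asarray(self.values)
        if self.region.shape != self.values.shape:
            raise ValueError("region mask and value grid shapes differ")

    @property
    def empty(self) -> bool:
        return not self.region.any()


def build_frame_stack(frames: Sequence[np.ndarray], target_index: int) -> FrameStack:
    """Stack the target frame with its two predecessors and two successors.

    Raises
    ------
    IndexError
        If fewer than two frames exist on either side of the target.
    """
    n = len(frames)
    if not (2 <= target_index <= n - 3):
        raise IndexError(
            f"target {target_index} needs two frames on each side in a {n}-frame video"
        )
    stack = np.stack([np.asarray(frames[i]) for i in range(target_index - 2, target_index + 3)])
    return FrameStack(stack, target_index)


def classify_gathering_fallback(
    stack: FrameStack,
    intensity_threshold: float = 0.25,
    area_threshold: float = 0.02,
) -> bool:
    """Heuristic gathering/dispersing decision on the target frame.

    True when the fraction of pixels brighter than
    ``intensity_threshold * g_max`` exceeds ``area_threshold``.  An all-zero
    frame is always dispersing.
    """
    if not (0 < intensity_threshold < 1 and 0 < area_threshold < 1):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    target = np.asarray(stack.target, dtype=float)
    g_max = target.max()
    if g_max <= 0:
        return False
    bright_fraction = float((target > intensity_threshold * g_max).mean())
    return bright_fraction > area_threshold


def segment_fish_region_fallback(
    stack: FrameStack,
    intensity_threshold: float = 0.25,
    min_blob_px: int = 25,
) -> FishRegionFrame:
    """Threshold-and-clean segmentation of the fish school in the target frame.

    Pixels above ``intensity_threshold * g_max`` are candidates; blobs below
    ``min_blob_px`` pixels are dropped; a 3x3 morphological closing bridges
    speckle gaps; the largest 8-connected component survives.  An empty
    region (no blob passes) is a signal, not an error.
    """
    if not (0 < intensity_threshold < 1):
        raise ValueError("intensity_threshold must lie strictly in (0, 1)")
    target = np.asarray(stack.target, dtype=float)
    g_max = target.max()
    region = np.zeros(target.shape, dtype=bool)
    if g_max > 0:
        candidate = target > intensity_threshold * g_max
        # drop blobs of fewer than min_blob_px pixels (max_size is inclusive)
        candidate = morphology.remove_small_objects(
            candidate, max_size=min_blob_px - 1, connectivity=2
        )
        candidate = morphology.closing(candidate, footprint=np.ones((3, 3), dtype=bool))
        labels = measure.label(candidate, connectivity=2)
        if labels.max() > 0:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            region = labels == sizes.argmax()
    return FishRegionFrame(region=region, values=target, frame_id=stack.target_index)


def load_external_masks(path: str | Path, frame_shape: tuple[int, int] | None = None) -> list[InstanceMask]:
    """Read instance masks produced by an external detector.

    ``path`` may be a labelled PNG (0 = background, k = instance k) or a
    directory of per-instance binary PNGs.  All masks are validated against
    ``frame_shape`` (rows, cols) when given.

    Raises
    ------
    ValueError
        If a mask's shape disagrees with ``frame_shape``.
    """
    import imageio.v3 as iio

    path = Path(path)
    masks: list[InstanceMask] = []
    if path.is_dir():
        for i, f in enumerate(sorted(path.glob("*.png"))):
            arr = np.asarray(iio.imread(f))
            _check_shape(arr, frame_shape, f)
            if (arr > 0).any():
                masks.append(InstanceMask(arr > 0, instance_id=i))
    else:
        labels = np.asarray(iio.imread(path))
        _check_shape(labels, frame_shape, path)
        for i in np.unique(labels):
            if i == 0:
                continue
            masks.append(InstanceMask(labels == i, instance_id=int(i)))
    return masks


def _check_shape(arr: np.ndarray, frame_shape: tuple[int, int] | None, src) -> None:
    if frame_shape is not None and arr.shape != tuple(frame_shape):
        raise ValueError(f"mask {src} has shape {arr.shape}, expected {frame_shape}")


def accuracy_from_confusion(confusion: np.ndarray) -> float:
    """Classification accuracy = trace / total of a square confusion matrix."""
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix must have positive total count")
    return float(np.trace(c) / total)
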