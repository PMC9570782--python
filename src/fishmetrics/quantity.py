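"""Net-cage fish-quantity estimation from feeding-frame sonar video.

When the school gathers at the surface to grab feed pellets it fills an
irregular prism that a slant sonar beam (angle theta to the water plane)
slices through.  From the segmented fish region F of a gathering frame:

    density    delta = sum(g(x), x in F) / (g_max * |F|)
    footprint  A     = |F| * dx * dy * cos(theta)        (cm^2)
    depth      d     = y_max * dy * sin(theta)           (cm)
    volume     V     = A * d                             (cm^3)
    count      n     = V * delta / V_fish

with ``V_fish = l * (l/2) * (l/2)`` the cuboid volume of an average fish of
length ``l`` cm, and ``y_max`` the bottom row of the region counted from the
image top (0-based row index + 1).  Per-frame counts over all gathering
frames are summarised by mean, standard deviation and normal-approximation
intervals mean +/- z*std with z = 1 (68 %) and 1.96 (95 %).

A sonar-derived total is split across species in proportion to per-species
counts from the optical camera (two-mode counting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .detectors import (
    FishRegionFrame,
    FrameStack,
    build_frame_stack,
    classify_gathering_fallback,
    segment_fish_region_fallback,
)

__all__ = [
    "QuantityEstimate",
    "QuantitySummary",
    "CountAllocation",
    "fish_density",
    "region_area_depth",
    "fish_volume",
    "estimate_quantity",
    "estimate_frame",
    "run_quantity_pipeline",
    "allocate_two_mode_counts",
]


@dataclass
class QuantityEstimate:
    """Per-frame count with the intermediate physical quantities."""

    n_fish: float
    volume: float  # V, cm^3
    density: float  # delta, dimensionless in [0, 1]
    area: float  # A, cm^2
    school_depth: float  # d, cm
    frame_id: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.density <= 1.0 + 1e-12):
            raise ValueError(f"density must lie in [0, 1], got {self.density}")
        if self.area < 0 or self.school_depth < 0 or self.n_fish < 0:
            raise ValueError("area, depth and count must be non-negative")


@dataclass
class QuantitySummary:
    """Across-frame aggregate of gathering-frame estimates."""

    estimates: list[QuantityEstimate]
    mean: float
    std: float
    ci68: tuple[float, float]
    ci95: tuple[float, float]

    @classmethod
    def from_estimates(cls, estimates: Sequence[QuantityEstimate]) -> "QuantitySummary":
        counts = np.array([e.n_fish for e in estimates])
        mean = float(counts.mean())
        std = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
        return cls(
            estimates=list(estimates),
            mean=mean,
            std=std,
            ci68=(mean - std, mean + std),
            ci95=(mean - 1.96 * std, mean + 1.96 * std),
        )


@dataclass
class CountAllocation:
    """Sonar total split across fish types by optical detection shares."""

    counts: dict
    sonar_total: float
    optical_counts: dict
    optical_total: float


def fish_density(region: FishRegionFrame) -> float:
    """Mean region pixel value normalised by the region maximum.

    delta = sum(g(x), x in F) / (g_max * |F|), a packing-fraction proxy.
    """
    if region.empty:
        raise ValueError("fish region is empty")
    vals = np.asarray(region.values, dtype=float)[region.region]
    g_max = vals.max()
    if g_max <= 0:
        return 0.0
    return float(vals.sum() / (g_max * vals.size))


def region_area_depth(
    region: FishRegionFrame, dx: float, dy: float, theta: float
) -> tuple[float, float]:
    """Sea-plane footprint A (cm^2) and school depth d (cm) of the region.

    A = |F| dx dy cos(theta); d = y_max dy sin(theta) with y_max the bottom
    row of the region counted from the top (0-based index + 1).
    """
    if region.empty:
        raise ValueError("fish region is empty")
    if not (0 <= theta < np.pi / 2):
        raise ValueError(f"beam angle must lie in [0, pi/2), got {theta}")
    n_px = int(region.region.sum())
    y_max = int(np.nonzero(region.region.any(axis=1))[0].max()) + 1
    area = n_px * dx * dy * np.cos(theta)
    depth = y_max * dy * np.sin(theta)
    return (float(area), float(depth))


def fish_volume(l_fish: float) -> float:
    """Cuboid volume l * (l/2) * (l/2) (cm^3) around one fish of length l."""
    if l_fish <= 0:
        raise ValueError(f"fish length must be positive, got {l_fish}")
    return l_fish * (l_fish / 2.0) * (l_fish / 2.0)


def estimate_quantity(volume: float, density: float, v_fish: float) -> float:
    """Fish count n = V * delta / V_fish (real-valued; round on output only)."""
    if v_fish <= 0:
        raise ValueError(f"per-fish volume must be positive, got {v_fish}")
    return volume * density / v_fish


def estimate_frame(
    region: FishRegionFrame, dx: float, dy: float, theta: float, l_fish: float
) -> QuantityEstimate:
    """Run the density -> area/depth -> volume -> count chain on one region."""
    delta = fish_density(region)
    area, depth = region_area_depth(region, dx, dy, theta)
    volume = area * depth
    n = estimate_quantity(volume, delta, fish_volume(l_fish))
    return QuantityEstimate(
        n_fish=n,
        volume=volume,
        density=delta,
        area=area,
        school_depth=depth,
        frame_id=region.frame_id,
    )


def run_quantity_pipeline(
    frames: Sequence[np.ndarray],
    dx: float,
    dy: float,
    theta: float,
    l_fish: float,
    classifier: Callable[[FrameStack], bool] | None = None,
    segmenter: Callable[[FrameStack], FishRegionFrame] | None = None,
) -> QuantitySummary | None:
    """Estimate the cage population from a feeding video.

    For every frame with two neighbours on each side: build the 5-frame
    stack, classify gathering vs dispersing, and on gathering frames segment
    the school and run the count chain.  ``classifier`` and ``segmenter``
    default to the intensity fallbacks; any callable with the same signature
    (e.g. a learned model, or ground-truth callbacks in simulation) plugs in.

    Returns ``None`` when no gathering frame is found (a signal, not an
    error).
    """
    if len(frames) < 5:
        raise ValueError(f"pipeline needs >= 5 frames, got {len(frames)}")
    classify = classifier if classifier is not None else classify_gathering_fallback
    segment = segmenter if segmenter is not None else segment_fish_region_fallback

    estimates: list[QuantityEstimate] = []
    for t in range(2, len(frames) - 2):
        stack = build_frame_stack(frames, t)
        if not classify(stack):
            continue
        region = segment(stack)
        if region.empty:
            continue
        estimates.append(estimate_frame(region, dx, dy, theta, l_fish))
    if not estimates:
        return None
    return QuantitySummary.from_estimates(estimates)


def allocate_two_mode_counts(
    sonar_total: float,
    optical_counts: Mapping[str, float],
    integer: bool = False,
) -> CountAllocation:
    """Split a sonar total count across types by optical detection shares.

    C_i = C_sonar * c_i / c_total.  With ``integer=True`` counts are rounded
    by the largest-remainder method so they sum exactly to the (rounded)
    sonar total.

    Raises
    ------
    ValueError
        If no optical detections exist (c_total = 0).
    """
    if any(v < 0 for v in optical_counts.values()):
        raise ValueError("optical counts must be non-negative")
    total = float(sum(optical_counts.values()))
    if total <= 0:
        raise ValueError("no optical detections: cannot allocate by type")
    shares = {k: sonar_total * v / total for k, v in optical_counts.items()}
    if integer:
        target = int(round(sonar_total))
        floors = {k: int(np.floor(s)) for k, s in shares.items()}
        remainder = target - sum(floors.values())
        # hand out leftover units to the largest fractional parts; ties to
        # the smaller key for determinism
        by_frac = sorted(shares, key=lambda k: (-(shares[k] - floors[k]), k))
        for k in by_frac[:remainder]:
            floors[k] += 1
        shares = {k: float(v) for k, v in floors.items()}
    return CountAllocation(
        counts=shares,
        sonar_total=sonar_total,
        optical_counts=dict(optical_counts),
        optical_total=total,
    )
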