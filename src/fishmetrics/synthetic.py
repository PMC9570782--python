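"""Synthetic fixtures with exact ground truth for every pipeline stage.

Nothing here pretends to be a physical acoustic simulation.  Each generator
emulates just the statistical structure the estimators rely on:

* calibration scenes — matched 3-D marker sets related by a known rigid
  transform plus isotropic noise;
* fish populations — Gaussian lengths (truncated at zero) with allometric
  weights ``W = a L^b exp(eta)``, plus the two contamination modes crowded
  sonar imagery produces: *merged* instances (two overlapping fish fused
  into one detection, length = sum of the pair) and *partial* instances
  (truncated fish, 40-70 % of the body cut off);
* instance masks — rasterised elliptical echoes whose farthest-point length
  reproduces the drawn length to within one pixel, with echo intensity
  decaying linearly with range (distant fish blur and fade);
* feeding sequences — gathering frames carrying a bright school region whose
  geometry and pixel values are constructed so the density/area/depth/count
  chain returns the configured true count *exactly*, and dispersing frames
  carrying only sparse specks.

Every generator is a pure function of its :class:`SimConfig` (seed
included): rerunning with the same config is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .detectors import FishRegionFrame, FrameStack, InstanceMask
from .fusion import MatchedPointSet, RigidTransform
from .geometry_stereo import Point3D

__all__ = [
    "SimConfig",
    "FeedingSequence",
    "gen_calibration_scene",
    "gen_population",
    "contaminate_lengths",
    "gen_instance_masks",
    "gen_feeding_sequence",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all generators.

    Population defaults sit in the regime of a market-size culture tank
    (mean fork length ~22 cm, weights ~290 g); cage defaults mirror an
    off-shore net cage holding ~2200 fish scanned by a 20-degree slant beam.
    """

    seed: int = 42

    # population
    n_fish: int = 2000
    mean_length_cm: float = 22.0
    sd_length_cm: float = 2.0
    allometric_a: float = 0.0269
    allometric_b: float = 3.0
    weight_noise_sd: float = 0.10  # lognormal sigma on weights
    table_rows: int = 200

    # contamination of detected instances
    merged_fraction: float = 0.20
    partial_fraction: float = 0.10
    truncation_range: tuple[float, float] = (0.4, 0.7)  # fraction of body removed

    # instance-mask rendering
    mask_frame_shape: tuple[int, int] = (200, 200)  # (rows, cols)
    mask_pixel_size: tuple[float, float] = (0.583, 0.549)  # (w, h) cm

    # net cage / feeding video
    true_count: int = 2200
    l_fish_cm: float = 20.0
    theta_rad: float = math.radians(20.0)
    delta_target: float = 0.5
    cage_frame_shape: tuple[int, int] = (96, 96)  # (rows, cols)
    cage_dx_cm: float = 10.0
    cage_dy_cm: float = 10.0
    n_frames: int = 24
    gathering_prob: float = 0.7
    speckle_sd: float = 0.05

    # calibration
    n_markers: int = 4
    n_calib_frames: int = 10
    marker_noise_sd: float = 0.0


# ---------------------------------------------------------------------------
# calibration scenes
# ---------------------------------------------------------------------------

def _random_rigid_transform(rng: np.random.Generator) -> RigidTransform:
    angles = rng.uniform(-np.pi, np.pi, size=3)
    from .geometry_sonar import EulerRotation

    R = EulerRotation(*angles).matrix()
    T = rng.uniform(-50.0, 50.0, size=3)
    return RigidTransform(R, T)


def gen_calibration_scene(
    config: SimConfig,
) -> tuple[list[MatchedPointSet], RigidTransform]:
    """Matched sonar/optical marker sets under a known rigid transform.

    Sonar-frame marker points are drawn uniformly in a 3 m box; optical
    points are their images under the generator transform plus isotropic
    Gaussian noise of sd ``marker_noise_sd`` cm.
    """
    if config.n_markers < 4 or config.n_calib_frames < 1:
        raise ValueError("need >= 4 markers and >= 1 frame")
    rng = np.random.default_rng(config.seed)
    truth = _random_rigid_transform(rng)
    frames = []
    for fid in range(config.n_calib_frames):
        sonar = rng.uniform(0.0, 300.0, size=(config.n_markers, 3))
        optical = sonar @ truth.rotation.T + truth.translation
        optical = optical + rng.normal(0.0, config.marker_noise_sd, size=optical.shape)
        frames.append(
            MatchedPointSet(
                sonar_points=[Point3D.from_array(p) for p in sonar],
                optical_points=[Point3D.from_array(p) for p in optical],
                frame_id=fid,
            )
        )
    return frames, truth


# ---------------------------------------------------------------------------
# populations and contamination
# ---------------------------------------------------------------------------

def gen_population(config: SimConfig):
    """Draw a fish population: lengths, allometric weights, reference table.

    Lengths are Normal(mean, sd) truncated at zero (negative draws redrawn);
    weights follow ``W = a L^b exp(eta)`` with lognormal noise.  The
    reference table subsamples ``table_rows`` uncontaminated fish.
    """
    from .length_weight import LengthWeightTable

    if config.n_fish < 10:
        raise ValueError("population needs n >= 10")
    rng = np.random.default_rng(config.seed)
    lengths = rng.normal(config.mean_length_cm, config.sd_length_cm, size=config.n_fish)
    while (bad := lengths <= 0).any():  # truncation at zero
        lengths[bad] = rng.normal(config.mean_length_cm, config.sd_length_cm, size=bad.sum())
    noise = rng.normal(0.0, config.weight_noise_sd, size=config.n_fish)
    weights = config.allometric_a * lengths ** config.allometric_b * np.exp(noise)
    rows = min(config.table_rows, config.n_fish)
    idx = rng.choice(config.n_fish, size=rows, replace=False)
    table = LengthWeightTable(lengths[idx], weights[idx])
    return lengths, weights, table


def contaminate_lengths(
    lengths: np.ndarray, config: SimConfig, rng: np.random.Generator | None = None
):
    """Corrupt a vector of true lengths the way crowded-scene detection does.

    A ``merged_fraction`` of instances is replaced by the sum of the instance
    and a random partner (two fish fused into one detection); a
    ``partial_fraction`` is truncated, removing a uniform 40-70 % of the
    body.  Returns ``(instance_lengths, labels)`` with labels in
    {"single", "merged", "partial"} partitioning the instance set.
    """
    if not (0 <= config.merged_fraction + config.partial_fraction < 1):
        raise ValueError("contamination fractions must sum below 1")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    lengths = np.asarray(lengths, dtype=float)
    n = len(lengths)
    n_merged = int(round(config.merged_fraction * n))
    n_partial = int(round(config.partial_fraction * n))
    perm = rng.permutation(n)
    out = lengths.copy()
    labels = np.array(["single"] * n, dtype=object)
    merged_idx = perm[:n_merged]
    partial_idx = perm[n_merged : n_merged + n_partial]
    partners = rng.integers(0, n, size=n_merged)
    out[merged_idx] = lengths[merged_idx] + lengths[partners]
    lo, hi = config.truncation_range
    removed = rng.uniform(lo, hi, size=n_partial)
    out[partial_idx] = lengths[partial_idx] * (1.0 - removed)
    labels[merged_idx] = "merged"
    labels[partial_idx] = "partial"
    return out, labels


# ---------------------------------------------------------------------------
# instance masks
# ---------------------------------------------------------------------------

def _ellipse_pixels(
    center_uv: tuple[float, float],
    length_cm: float,
    angle: float,
    pixel_size: tuple[float, float],
    shape: tuple[int, int],
    aspect: float = 0.25,
    keep_fraction: float = 1.0,
) -> np.ndarray:
    """Rasterise an elliptical echo of physical semi-major length/2.

    Pixels whose physical centre falls inside the ellipse are set; the two
    physical endpoints of the major axis are set explicitly so the
    farthest-point length matches ``length_cm`` to within a pixel.
    ``keep_fraction`` < 1 truncates the body from the +axis end.
    """
    rows, cols = shape
    w, h = pixel_size
    a = length_cm / 2.0
    b = max(a * aspect, min(w, h))
    e1 = np.array([math.cos(angle), math.sin(angle)])
    e2 = np.array([-math.sin(angle), math.cos(angle)])
    cu, cv = center_uv
    du = int(math.ceil(a / w)) + 1
    dv = int(math.ceil(a / h)) + 1
    u0, u1 = max(0, int(cu) - du), min(cols, int(cu) + du + 1)
    v0, v1 = max(0, int(cv) - dv), min(rows, int(cv) + dv + 1)
    uu, vv = np.meshgrid(np.arange(u0, u1), np.arange(v0, v1))
    px = (uu - cu) * w
    py = (vv - cv) * h
    p1 = px * e1[0] + py * e1[1]
    p2 = px * e2[0] + py * e2[1]
    inside = (p1 / a) ** 2 + (p2 / b) ** 2 <= 1.0
    cut = a - (1.0 - keep_fraction) * length_cm
    inside &= p1 <= cut + 1e-12
    mask = np.zeros((rows, cols), dtype=bool)
    mask[v0:v1, u0:u1] = inside
    # pin the axis endpoints (subject to truncation) onto the grid
    for t in (-a, min(a, cut)):
        eu = int(round(cu + t * e1[0] / w))
        ev = int(round(cv + t * e1[1] / h))
        if 0 <= eu < cols and 0 <= ev < rows:
            mask[ev, eu] = True
    return mask


def gen_instance_masks(
    lengths: Sequence[float],
    config: SimConfig,
    seed: int | None = None,
):
    """Render instance masks for a contaminated population.

    Returns ``(masks, instance_lengths, labels)`` where ``instance_lengths``
    are the ground-truth farthest-point lengths the masks encode.  Single
    fish are drawn as one ellipse; merged instances as two ellipses joined
    end to end (extent exceeds both parents); partial instances as a
    truncated ellipse.

    Raises
    ------
    ValueError
        If a fish is too long to place inside the mask frame.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    lengths = np.asarray(lengths, dtype=float)
    inst_lengths, labels = contaminate_lengths(lengths, config, rng)
    rows, cols = config.mask_frame_shape
    w, h = config.mask_pixel_size
    frame_extent = min(cols * w, rows * h)
    masks: list[InstanceMask] = []
    for i, (L_true, L_inst, label) in enumerate(zip(lengths, inst_lengths, labels)):
        if L_inst >= frame_extent:
            raise ValueError(f"fish of length {L_inst:.1f} cm does not fit the frame")
        angle = rng.uniform(0, np.pi)
        extent = max(L_true, L_inst)  # partial masks keep the full-body footprint
        margin_u = extent / w / 2 + 2
        margin_v = extent / h / 2 + 2
        cu = rng.uniform(margin_u, cols - margin_u)
        cv = rng.uniform(margin_v, rows - margin_v)
        if label == "merged":
            # two fish end to end along a gently bent axis
            La = L_true
            Lb = L_inst - L_true
            bend = rng.uniform(-0.3, 0.3)
            e1 = np.array([math.cos(angle), math.sin(angle)])
            ca = (cu - (Lb / 2) * e1[0] / w, cv - (Lb / 2) * e1[1] / h)
            e1b = np.array([math.cos(angle + bend), math.sin(angle + bend)])
            cb = (
                ca[0] + ((La + Lb) / 2) * e1b[0] / w,
                ca[1] + ((La + Lb) / 2) * e1b[1] / h,
            )
            mask = _ellipse_pixels(ca, La, angle, (w, h), (rows, cols)) | _ellipse_pixels(
                cb, Lb, angle + bend, (w, h), (rows, cols)
            )
        elif label == "partial":
            keep = L_inst / L_true
            mask = _ellipse_pixels(
                (cu, cv), L_true, angle, (w, h), (rows, cols), keep_fraction=keep
            )
        else:
            mask = _ellipse_pixels((cu, cv), L_inst, angle, (w, h), (rows, cols))
        masks.append(InstanceMask(mask, instance_id=i))
    return masks, inst_lengths, labels


# ---------------------------------------------------------------------------
# feeding sequences
# ---------------------------------------------------------------------------

@dataclass
class FeedingSequence:
    """A synthetic feeding video with full ground truth.

    ``regions`` maps gathering-frame indices to noise-free
    :class:`FishRegionFrame` objects; feeding the stored region through the
    density/area/depth chain returns ``true_count`` exactly.
    """

    frames: list[np.ndarray]
    gathering: list[bool]
    regions: dict[int, FishRegionFrame]
    true_count: float
    dx: float
    dy: float
    theta: float
    l_fish: float

    def ground_truth_classifier(self, stack: FrameStack) -> bool:
        return self.gathering[stack.target_index]

    def ground_truth_segmenter(self, stack: FrameStack) -> FishRegionFrame:
        region = self.regions.get(stack.target_index)
        if region is None:
            return FishRegionFrame(
                region=np.zeros_like(stack.target, dtype=bool),
                values=np.asarray(stack.target, dtype=float),
                frame_id=stack.target_index,
            )
        return region


def _school_region(
    shape: tuple[int, int],
    n_px: int,
    y_max: int,
    col_offset: int,
) -> np.ndarray:
    """A connected blob of exactly ``n_px`` pixels whose bottom row is y_max - 1."""
    rows, cols = shape
    width = max(int(math.ceil(math.sqrt(n_px))), 1)
    height = int(math.ceil(n_px / width))
    if height >= y_max or width > cols:
        raise ValueError("school region does not fit the frame")
    mask = np.zeros(shape, dtype=bool)
    u0 = min(max(col_offset, 0), cols - width)
    v1 = y_max  # exclusive bottom
    v0 = v1 - height
    mask[v0:v1, u0 : u0 + width] = True
    # trim the excess from the top row so |F| == n_px and y_max is intact
    excess = width * height - n_px
    if excess:
        mask[v0, u0 : u0 + excess] = False
    return mask


def gen_feeding_sequence(config: SimConfig) -> FeedingSequence:
    """Generate a feeding video whose count chain inverts exactly.

    For each gathering frame a school region is placed with its bottom row
    and pixel count jittered around the configuration implied by
    ``delta_target``; the region's pixel values are then solved so that
    density * volume / V_fish equals ``true_count`` exactly (one pixel
    carries the region maximum 1.0, the rest share the value that makes the
    normalised mean come out right).  Dispersing frames carry only sparse
    bright specks.  Speckle noise of sd ``speckle_sd`` is added to the
    emitted frames; the stored ground-truth regions keep the clean values.
    """
    rng = np.random.default_rng(config.seed + 3)
    rows, cols = config.cage_frame_shape
    dx, dy, theta = config.cage_dx_cm, config.cage_dy_cm, config.theta_rad
    from .quantity import fish_volume

    v_fish = fish_volume(config.l_fish_cm)
    need = config.true_count * v_fish  # = V * delta

    base_ymax = int(0.9 * rows)
    flags: list[bool] = []
    for t in range(config.n_frames):
        interior = 2 <= t < config.n_frames - 2
        flags.append(bool(interior and rng.random() < config.gathering_prob))
    if not any(flags):
        flags[config.n_frames // 2] = True

    frames: list[np.ndarray] = []
    regions: dict[int, FishRegionFrame] = {}
    for t, gathering in enumerate(flags):
        frame = np.zeros((rows, cols), dtype=float)
        if gathering:
            y_max = int(base_ymax * rng.uniform(0.9, 1.0))
            depth = y_max * dy * math.sin(theta)
            # pixel count implied by the target density, then jittered
            n_px = int(round(need / (config.delta_target * dx * dy * math.cos(theta) * depth)))
            n_px = max(int(n_px * rng.uniform(0.9, 1.1)), 16)
            area = n_px * dx * dy * math.cos(theta)
            delta = need / (area * depth)
            if not (0 < delta <= 1):
                raise ValueError(
                    f"cage configuration infeasible: implied density {delta:.3f}"
                )
            offset = int(rng.integers(0, cols - int(math.sqrt(n_px)) - 2))
            region = _school_region((rows, cols), n_px, y_max, offset)
            # one pixel at the region max anchors g_max; the others share the
            # value that makes the normalised mean exactly delta
            fill = (delta * n_px - 1.0) / (n_px - 1.0)
            if fill <= 0:
                raise ValueError("region too small to realise the target density")
            frame[region] = fill
            anchor = np.argwhere(region)[0]
            frame[anchor[0], anchor[1]] = 1.0
            regions[t] = FishRegionFrame(region=region, values=frame.copy(), frame_id=t)
        else:
            n_specks = int(0.003 * rows * cols)
            su = rng.integers(0, cols, size=n_specks)
            sv = rng.integers(0, rows, size=n_specks)
            frame[sv, su] = rng.uniform(0.3, 1.0, size=n_specks)
        if config.speckle_sd > 0:
            frame = np.clip(frame + rng.normal(0, config.speckle_sd, frame.shape), 0.0, 1.0)
        frames.append(frame)

    return FeedingSequence(
        frames=frames,
        gathering=flags,
        regions=regions,
        true_count=float(config.true_count),
        dx=dx,
        dy=dy,
        theta=theta,
        l_fish=config.l_fish_cm,
    )
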