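"""Fish length/weight distribution estimation from sonar instance masks.

Instance segmentation on crowded sonar imagery produces three kinds of
detections: genuine single fish, merged blobs of overlapping fish (inflated
length), and partially visible fish (deflated length).  The per-instance
length — the maximum physical distance between any two mask pixels — is
therefore modelled as a Gaussian mixture.  EM fits mixtures with c = 1..5
components, the number of components is chosen by a non-Gaussianity score

    Phi(c) = (1/c) sum_i ( |skew_i| + |kurt_i - 3| )

computed over the samples hard-assigned to each component using that
component's EM mean and standard deviation (a component of true single fish
should look Gaussian, so small Phi is good), and the component with the
largest mixture weight is taken as the single-fish population.  Weights are
then predicted from length by K-nearest-neighbour regression (K = 5) against
a manually measured length-weight reference table.

All lengths are in cm, weights in g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .detectors import InstanceMask

__all__ = [
    "LengthSample",
    "GmmFit",
    "LengthWeightTable",
    "InsufficientDataError",
    "ModelSelectionError",
    "mask_length",
    "fit_gmm",
    "posterior_membership",
    "nongaussianity",
    "select_model",
    "single_fish_component",
    "knn_weight",
    "relative_error",
    "run_length_weight_pipeline",
    "PipelineSummary",
]

MAX_COMPONENTS = 5
EM_TOL = 1e-8
EM_MAX_ITER = 500
EM_RESTARTS = 10
VARIANCE_FLOOR = 1e-6  # cm^2; prevents component collapse onto a point


class InsufficientDataError(ValueError):
    """Fewer samples than the operation needs."""


class ModelSelectionError(RuntimeError):
    """Every candidate component count was disqualified."""


@dataclass(frozen=True)
class LengthSample:
    """One measured instance length (cm)."""

    length: float
    instance_id: int = 0
    frame_id: int = 0

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"length must be non-negative, got {self.length}")


@dataclass
class GmmFit:
    """A fitted univariate Gaussian mixture.

    ``loglik_trace`` records the total log-likelihood after each EM iteration
    of the winning restart; ``phi`` is filled by :func:`nongaussianity` /
    :func:`select_model`.
    """

    c: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    samples: np.ndarray
    responsibilities: np.ndarray
    loglik_trace: np.ndarray
    phi: float = np.nan

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if not (1 <= self.c <= MAX_COMPONENTS):
            raise ValueError(f"component count must lie in 1..{MAX_COMPONENTS}")


@dataclass
class LengthWeightTable:
    """Manually measured (length cm, weight g) reference pairs."""

    lengths: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float).ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.lengths.shape != self.weights.shape:
            raise ValueError("lengths and weights must have equal length")
        if np.any(self.lengths <= 0) or np.any(self.weights <= 0):
            raise ValueError("table entries must be positive")

    def __len__(self) -> int:
        return len(self.lengths)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LengthWeightTable":
        df = pd.read_csv(path)
        return cls(df["length_cm"].to_numpy(), df["weight_g"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"length_cm": self.lengths, "weight_g": self.weights}).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# length measurement
# ---------------------------------------------------------------------------

def mask_length(mask: InstanceMask | np.ndarray, pixel_size: tuple[float, float]) -> float:
    """Maximum physical distance between any two pixels of an instance mask.

    Column and row displacements are scaled independently by the pixel
    footprint ``(w, h)`` cm, so anisotropic sonar pixels are handled.  A
    single-pixel mask has length 0.
    """
    grid = mask.mask if isinstance(mask, InstanceMask) else np.asarray(mask, dtype=bool)
    vs, us = np.nonzero(grid)
    if len(us) == 0:
        raise ValueError("mask is empty")
    if len(us) == 1:
        return 0.0
    w, h = pixel_size
    pts = np.column_stack([us * w, vs * h])
    if len(pts) > 10:
        # The farthest pair lies on the convex hull; qhull fails on
        # degenerate (collinear) sets, where brute force is cheap anyway.
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    diffs = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diffs ** 2).sum(axis=2)).max())


# ---------------------------------------------------------------------------
# EM for a univariate Gaussian mixture
# ---------------------------------------------------------------------------

def _log_density(x: np.ndarray, weights, means, variances) -> np.ndarray:
    """(n, c) matrix of log(w_i * N(x; mu_i, sigma_i^2))."""
    sd = np.sqrt(variances)
    return np.log(weights)[None, :] + norm.logpdf(x[:, None], means[None, :], sd[None, :])


def _em_once(x: np.ndarray, c: int, means0: np.ndarray) -> tuple:
    n = len(x)
    weights = np.full(c, 1.0 / c)
    means = means0.astype(float).copy()
    variances = np.full(c, max(x.var(), VARIANCE_FLOOR))
    trace = []
    prev = -np.inf
    for _ in range(EM_MAX_ITER):
        logp = _log_density(x, weights, means, variances)
        log_norm = np.logaddexp.reduce(logp, axis=1)
        resp = np.exp(logp - log_norm[:, None])
        loglik = float(log_norm.sum())
        trace.append(loglik)
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, VARIANCE_FLOOR)
        if loglik - prev < EM_TOL and np.isfinite(prev):
            break
        prev = loglik
    logp = _log_density(x, weights, means, variances)
    log_norm = np.logaddexp.reduce(logp, axis=1)
    resp = np.exp(logp - log_norm[:, None])
    return weights, means, variances, resp, float(log_norm.sum()), np.array(trace)


def fit_gmm(samples: Sequence[float], c: int, seed: int | None = 0) -> GmmFit:
    """Fit a c-component univariate Gaussian mixture by EM.

    Initialisation is k-means on the lengths with seeded restarts
    (``EM_RESTARTS`` runs, best final log-likelihood kept).  Convergence is a
    log-likelihood change below ``EM_TOL``; variances are floored at
    ``VARIANCE_FLOOR`` cm^2.  For c = 1 this reduces to the sample mean and
    maximum-likelihood (denominator n) variance.

    Raises
    ------
    InsufficientDataError
        If there are fewer samples than components.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if not (1 <= c <= MAX_COMPONENTS):
        raise ValueError(f"c must lie in 1..{MAX_COMPONENTS}, got {c}")
    if len(x) < c:
        raise InsufficientDataError(f"{len(x)} samples cannot support {c} components")

    rng = np.random.default_rng(seed)
    best = None
    n_restarts = 1 if c == 1 else EM_RESTARTS
    for _ in range(n_restarts):
        means0 = _kmeans_1d(x, c, rng)
        result = _em_once(x, c, means0)
        if best is None or result[4] > best[4]:
            best = result
    weights, means, variances, resp, _, trace = best
    order = np.argsort(means)
    return GmmFit(
        c=c,
        weights=weights[order],
        means=means[order],
        variances=variances[order],
        samples=x,
        responsibilities=resp[:, order],
        loglik_trace=trace,
    )


def _kmeans_1d(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded Lloyd's k-means on scalars; returns c centre values."""
    centres = rng.choice(x, size=c, replace=len(np.unique(x)) < c)
    for _ in range(50):
        assign = np.argmin(np.abs(x[:, None] - centres[None, :]), axis=1)
        new = centres.copy()
        for k in range(c):
            members = x[assign == k]
            if len(members):
                new[k] = members.mean()
        if np.allclose(new, centres):
            break
        centres = new
    return centres


def posterior_membership(x: float | np.ndarray, fit: GmmFit) -> np.ndarray:
    """Posterior component probabilities p(G_i | x) for a length value.

    Rows sum to one; the sample belongs to the argmax component.
    """
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    logp = _log_density(xa, fit.weights, fit.means, fit.variances)
    p = np.exp(logp - np.logaddexp.reduce(logp, axis=1)[:, None])
    return p[0] if np.isscalar(x) or np.ndim(x) == 0 else p


def hard_assignments(fit: GmmFit) -> np.ndarray:
    """Component index of each fitted sample (argmax posterior)."""
    return np.argmax(fit.responsibilities, axis=1)


def nongaussianity(fit: GmmFit, samples: Sequence[float] | None = None) -> float:
    """Non-Gaussianity score Phi(c) of a fitted mixture.

    Samples are hard-assigned by posterior argmax; each component contributes
    |standardised skewness| + |kurtosis - 3| computed with the component's EM
    mean and standard deviation (not re-estimated moments).  A component with
    fewer than 4 members cannot support a kurtosis estimate and disqualifies
    the fit (contribution +inf).
    """
    x = fit.samples if samples is None else np.asarray(samples, dtype=float).ravel()
    if samples is None:
        assign = hard_assignments(fit)
    else:
        assign = np.argmax(posterior_membership(x, fit), axis=1)
    total = 0.0
    for i in range(fit.c):
        members = x[assign == i]
        if len(members) < 4:
            return np.inf
        z = (members - fit.means[i]) / np.sqrt(fit.variances[i])
        skew = np.mean(z ** 3)
        kurt = np.mean(z ** 4)
        total += abs(skew) + abs(kurt - 3.0)
    return total / fit.c


def select_model(
    samples: Sequence[float],
    c_range: Sequence[int] = range(1, MAX_COMPONENTS + 1),
    seed: int | None = 0,
) -> GmmFit:
    """Fit mixtures over ``c_range`` and keep the one with minimal Phi(c).

    Ties break toward the smaller component count.

    Raises
    ------
    ModelSelectionError
        If every candidate is disqualified (all Phi infinite).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 5:
        raise InsufficientDataError(f"model selection needs >= 5 samples, got {len(x)}")
    best: GmmFit | None = None
    for c in sorted(c_range):
        try:
            fit = fit_gmm(x, c, seed=seed)
        except InsufficientDataError:
            continue
        fit.phi = nongaussianity(fit)
        if np.isfinite(fit.phi) and (best is None or fit.phi < best.phi):
            best = fit
    if best is None:
        raise ModelSelectionError("no component count produced a valid fit")
    return best


def single_fish_component(fit: GmmFit) -> int:
    """Index of the largest-weight component (ties -> smaller mean)."""
    w = fit.weights
    best = np.flatnonzero(np.isclose(w, w.max()))
    return int(best[np.argmin(fit.means[best])])


# ---------------------------------------------------------------------------
# weight regression and error reporting
# ---------------------------------------------------------------------------

def knn_weight(length: float, table: LengthWeightTable, k: int = 5) -> float:
    """Predict weight (g) as the mean weight of the K nearest table lengths.

    Distance is absolute length difference; ties at the K-th distance break
    toward the smaller table length.

    Raises
    ------
    InsufficientDataError
        If the table has fewer than K rows.
    """
    if len(table) < k:
        raise InsufficientDataError(f"table has {len(table)} rows, need >= {k}")
    dist = np.abs(table.lengths - length)
    order = np.lexsort((table.lengths, dist))
    return float(table.weights[order[:k]].mean())


def relative_error(estimate: float, manual: float) -> float:
    """Relative error |estimate - manual| / manual against a manual reference.

    Raises
    ------
    ValueError
        If the manual reference is not strictly positive.
    """
    if manual <= 0:
        raise ValueError(f"manual reference must be positive, got {manual}")
    return abs(estimate - manual) / manual


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineSummary:
    """Per-run distribution summary mirroring a length/weight report row."""

    mean_length_raw: float
    mean_length_gmm: float
    mean_weight_raw: float
    mean_weight_gmm: float
    n_instances: int
    n_single: int
    c: int
    phi: float
    eps_length_raw: float | None = None
    eps_length_gmm: float | None = None
    eps_weight_raw: float | None = None
    eps_weight_gmm: float | None = None
    selected_lengths: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items() if k != "selected_lengths"}
        return pd.DataFrame([d])


def run_length_weight_pipeline(
    masks_or_lengths: Sequence[InstanceMask] | Sequence[float],
    pixel_size: tuple[float, float],
    table: LengthWeightTable,
    manual_length: float | None = None,
    manual_weight: float | None = None,
    k: int = 5,
    seed: int | None = 0,
) -> PipelineSummary:
    """Full length/weight distribution pipeline.

    Measures per-instance lengths (or accepts pre-measured lengths), selects
    a mixture by Phi(c), keeps the samples of the largest-weight component as
    single fish, and regresses their weights from the reference table.  Raw
    (unfiltered) means are reported alongside for comparison; relative errors
    are filled when manual references are supplied.
    """
    first = masks_or_lengths[0] if len(masks_or_lengths) else None
    if isinstance(first, InstanceMask):
        lengths = np.array([mask_length(m, pixel_size) for m in masks_or_lengths])
    else:
        lengths = np.asarray(masks_or_lengths, dtype=float).ravel()
    if len(lengths) < 5:
        raise InsufficientDataError("pipeline needs at least 5 instances")

    fit = select_model(lengths, seed=seed)
    star = single_fish_component(fit)
    selected = lengths[hard_assignments(fit) == star]

    mean_len_raw = float(lengths.mean())
    mean_len_gmm = float(selected.mean())
    weights_raw = np.array([knn_weight(l, table, k) for l in lengths])
    weights_gmm = np.array([knn_weight(l, table, k) for l in selected])

    summary = PipelineSummary(
        mean_length_raw=mean_len_raw,
        mean_length_gmm=mean_len_gmm,
        mean_weight_raw=float(weights_raw.mean()),
        mean_weight_gmm=float(weights_gmm.mean()),
        n_instances=len(lengths),
        n_single=len(selected),
        c=fit.c,
        phi=fit.phi,
        selected_lengths=selected,
    )
    if manual_length is not None:
        summary.eps_length_raw = relative_error(mean_len_raw, manual_length)
        summary.eps_length_gmm = relative_error(mean_len_gmm, manual_length)
    if manual_weight is not None:
        summary.eps_weight_raw = relative_error(summary.mean_weight_raw, manual_weight)
        summary.eps_weight_gmm = relative_error(summary.mean_weight_gmm, manual_weight)
    return summary
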