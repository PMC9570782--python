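# Methods

This note documents the models implemented in `fishmetrics`, their
assumptions, the defaults that matter, and what the synthetic generators do
and do not emulate.

## Coordinate and imaging conventions

Pixels are `(u, v) = (column, row)`, 0-based, origin top-left. The sonar
image is treated as a vertical fan slice: a pixel's world point is
`(x_S − u·w, y_S, v·h)`, so every sonar point shares the device's
y-coordinate and the elevation ambiguity of 2-D imaging sonar is accepted,
not modelled. The pixel footprint `(w, h)` cm is always computed from the
pond extent and image shape (e.g. 630 cm / 1080 columns = 0.583 cm); we do
not hard-code footprints, because quoted per-pixel sizes in device
documentation are not always consistent with the stated extents (600 cm
over 1092 rows is 0.549 cm, not 0.3125 cm). Euler rotations compose as
`R = Rz(yaw)·Ry(pitch)·Rx(roll)`; no alternative conventions are supported.
Angles are radians internally; JSON configs take `_deg` keys.

Stereo input is assumed rectified: correspondences are searched along the
same row only (block matching, sum of absolute differences over an odd
square window, default 11; ties break to the smallest disparity), and
disparities are integer pixels — sub-pixel refinement is out of scope. The
epipolar tolerance defaults to 0 rows and is configurable for noisy input.

## Extrinsic calibration

The sonar→optical transform is rigid (rotation + translation), solved in
closed form by orthogonal Procrustes with reflection correction, minimising
the mean squared residual over all marker points of all calibration frames.
A similarity variant (one isotropic scale, Umeyama) is available behind a
flag for rigs whose range calibrations disagree; a full affine solve is
deliberately not offered — markers are few, and extra degrees of freedom
soak up noise. Collinear marker configurations are rejected
(cross-covariance rank < 2). Overlap detection interprets "the region both
sensors see" as field-of-view membership: a sonar point overlaps when its
transformed image has positive depth and projects inside the optical frame.
Back-mapping to sonar pixels inverts the pixel-to-world relation exactly
(`u = (x_S − x)/w`), keeping the round trip self-consistent.

## Length/weight pipeline

Instance length is the maximum physical distance between mask pixels, with
column and row displacements scaled independently by `(w, h)` — anisotropic
pixels are the norm for sonar imagery. The farthest pair is found on the
convex hull, with a brute-force fallback for degenerate masks.

The mixture model is fitted by a hand-written univariate EM because the
selection criterion needs internals that library fits do not expose: the
per-iteration log-likelihood (monotonicity is asserted in tests) and
component moments under hard assignment. Defaults: k-means initialisation
with 10 seeded restarts keeping the best final log-likelihood, convergence
tolerance 1e-8 on the log-likelihood, at most 500 iterations, variance
floor 1e-6 cm² against component collapse. `sklearn.mixture.GaussianMixture`
serves as an independent cross-check in the test suite, never as the
implementation.

Φ(c) uses **hard assignment** (argmax posterior) and the component's EM
mean and standard deviation rather than re-estimated moments — the score is
asking "do the samples attributed to this component look like draws from
it", and re-standardising would always say yes. Soft-weighted moments would
be the main alternative; hard assignment matches the decision rule used to
select the single-fish population, so the two stages stay consistent. A
component with fewer than 4 members cannot support a kurtosis estimate and
disqualifies its fit (Φ contribution +∞). Ties in Φ break toward fewer
components; ties in the largest-weight rule break toward the smaller mean
(the conservative choice, since contamination by merging inflates lengths).

KNN weight regression is an unweighted mean of the K = 5 nearest table
weights by absolute length difference, ties at the K-th distance broken
toward the smaller table length. The reference table is assumed to be
measured on the same stock; no allometric model is fitted — the
non-parametric regression is deliberately assumption-free. Note a known
reporting bias: if the reference lengths are fork lengths while sonar
measures something closer to standard length, estimates inherit that offset;
no correction is applied.

## Quantity pipeline

The count chain is `n = A·d·δ / V_fish` per gathering frame. Choices worth
stating:

- `g_max` in the density is the maximum pixel value **within the region** of
  the current frame (a per-frame normalisation robust to gain changes); the
  image dtype maximum is available behind a flag-free alternative by passing
  pre-normalised frames.
- `y_max` is the 0-based bottom row index **plus one** (rows counted from
  the top), so a region touching row r has depth proportional to r + 1.
- The fish volume proxy is a cuboid `l·(l/2)·(l/2)`; it is a deliberate
  order-of-magnitude model, and counts inherit its bias.
- Only the non-rotating slant-beam geometry is implemented.
- Across-frame intervals are normal approximations `mean ± z·std` of the
  per-frame estimates with z = 1 and 1.96. The standard deviation uses
  ddof = 1. These are descriptive spread intervals, not standard errors of
  the mean.

Two-mode allocation `Cᵢ = C_sonar·cᵢ/c_total` is real-valued by default;
integer output uses largest-remainder rounding (ties to the
lexicographically smaller type) so the total is conserved exactly.

## Detector fallbacks

The learned detectors used in deployment (instance segmentation of fish,
gathering-frame classification, school segmentation) are replaced by
deterministic intensity heuristics so the pipelines are exercisable without
trained weights: a frame is "gathering" when more than 2 % of pixels exceed
25 % of the frame maximum; the school region is the largest 8-connected
blob after thresholding at the same level, dropping blobs under 25 px and a
3×3 morphological closing. Any callable with the same signature plugs in,
so learned models remain first-class. The fallbacks are honest baselines,
not reimplementations of the networks.

## Synthetic generators

The generators define the study conditions and return enough ground truth
to score every stage without external data. Defaults: populations of 2000
fish, length Normal(22, 2) cm truncated at zero, weights `0.0269·L³` g with
10 % lognormal noise, a 200-row measured table; contamination 20 % merged
(instance length = sum of two fish) and 10 % partial (40–70 % of the body
removed, i.e. 30–60 % kept — "40–70 % truncation" is read as the removed
fraction); cages of 2200 fish, average length 20 cm, beam slant 20°,
96×96 frames at 10 cm per pixel, speckle noise sd 0.05 on [0, 1] frames.
Mask fixtures use 200×200 frames at the 0.583 × 0.549 cm footprint of the
reference pond.

Two constructions are worth explaining:

- **Masks.** Fish echoes are rasterised ellipses in physical coordinates
  with the two major-axis endpoints pinned to the grid, so the
  farthest-point length reproduces the drawn length to within one pixel
  diagonal. Merged instances are two ellipses joined end to end along a
  gently bent axis; partial instances are truncated ellipses. Echo
  rendering does not attempt speckle statistics or point-spread physics.
- **Feeding frames.** Each gathering frame carries one connected school
  region whose pixel count and bottom row are jittered per frame and whose
  pixel values are then solved so the density/area/depth chain returns the
  configured true count exactly (one pixel anchors the region maximum, the
  rest share the value that makes the normalised mean come out right).
  Ground-truth regions store the clean values; emitted frames add clipped
  Gaussian speckle. Dispersing frames contain only sparse bright specks.

What passing tests therefore show: the estimators invert their own model
exactly, degrade gracefully under noise, and the mixture filter removes
contamination of the kind the generator produces. What they do not show:
performance under real sonar artefacts (reverberation, bottom echo,
air-pump noise, partial visibility at the fan edges), real school geometry,
or the error profile of any particular learned detector. The quantity
pipeline's accuracy on real cages is bounded by the cuboid volume proxy and
the single-slice prism assumption, neither of which the synthetic cage
challenges.

## Degenerate inputs and numerical edges

Zero/negative disparity raises a degenerate-depth error (points at or
behind the cameras). Empty masks, empty regions and empty point sets raise;
"no overlap" and "no gathering frame found" are signals (empty result /
`None`), not errors, because they are expected field outcomes. The variance
floor, the ≥ 4-member rule and the collinearity check are the three guards
against degenerate fits. All pipelines are pure functions of
(inputs, config, seed); reruns are byte-identical.

## Problem sizes

Test and acceptance runs use the default study conditions directly: the
contaminated-population run fits five candidate mixtures (10 restarts each)
to 2000 instances in a few seconds; feeding videos are 24 frames of 96×96.
These sizes were chosen as the smallest at which the sampling error of the
checked quantities is comfortably below the asserted bounds.
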