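# fishmetrics

Offline toolkit for **opti-acoustic fish monitoring**: estimating fish
length/weight distributions and cage populations from imaging-sonar video,
fused with a low-cost rectified stereo camera. It is aimed at aquaculture
researchers who have sonar frame sequences, instance/region masks from any
segmentation model, and a manually measured length–weight reference table —
and who want the downstream metric estimation to be reproducible and
hardware-free.

## What it computes

**Opti-acoustic calibration.** Markers visible to both sensors give matched
3-D points: sonar pixels map to world points via the pixel footprint
(`x = x_S − u·w`, `z = v·h`), stereo pixels via disparity `d = x_left −
x_right` and triangulation `z = f·b/d`. The rigid transform (R, T)
minimising the mean squared residual `‖X_O − (R·X_S + T)‖²` over all marker
frames is solved in closed form (orthogonal Procrustes: centroid
subtraction, SVD of the cross-covariance, reflection correction). The
overlap of the two fields of view is found by mapping sonar points into the
camera frustum and bounding the survivors in sonar pixel space.

**Length/weight distributions.** Instance masks from crowded sonar imagery
mix single fish with merged (two fish fused, inflated length) and partial
(truncated, deflated length) detections. Per-instance lengths — the farthest
pixel-pair distance under the anisotropic pixel footprint — are modelled as
a Gaussian mixture `p(x) = Σᵢ wᵢ N(x; μᵢ, σᵢ²)` fitted by EM for c = 1..5
components. The component count is chosen by the non-Gaussianity score

    Φ(c) = (1/c) Σᵢ ( |skewᵢ| + |kurtᵢ − 3| )

over samples hard-assigned to each component (smaller is more Gaussian),
and the largest-weight component is taken as the single-fish population.
Weights follow by K-nearest-neighbour regression (K = 5) against the
measured length–weight table.

**Cage quantity.** During feeding the school packs into a prism that a slant
sonar beam (angle θ) slices. From the segmented region ℱ of each gathering
frame: density `δ = Σ g(x) / (g_max·|ℱ|)`, footprint `A = |ℱ|·Δx·Δy·cos θ`,
depth `d = y_max·Δy·sin θ`, and count `n = A·d·δ / V_fish` with
`V_fish = l·(l/2)²` for average fish length `l`. Per-frame counts are
summarised with mean ± z·std intervals (z = 1, 1.96). A sonar total is split
across species in proportion to optical per-species detections
(`Cᵢ = C_sonar·cᵢ/c_total`, largest-remainder rounding).

Learned detectors (instance segmentation, frame classification, semantic
segmentation) are **pluggable contracts** with deterministic intensity-based
fallbacks, and a synthetic module generates every input with exact ground
truth, so the whole chain runs and is testable on a laptop.

## Worked example

```python
import numpy as np
from fishmetrics import (SimConfig, gen_population, contaminate_lengths,
    run_length_weight_pipeline, gen_feeding_sequence, run_quantity_pipeline)

cfg = SimConfig(seed=42, n_fish=500)
lengths, weights, table = gen_population(cfg)          # ground-truth population
instances, labels = contaminate_lengths(lengths, cfg)  # 20% merged, 10% partial

s = run_length_weight_pipeline(instances, cfg.mask_pixel_size, table,
    manual_length=cfg.mean_length_cm, manual_weight=float(weights.mean()), seed=42)
print(f"N = {s.n_instances}, N_G = {s.n_single}, c = {s.c}")
print(f"mean length: raw {s.mean_length_raw:.2f} cm (eps {s.eps_length_raw:.2f}), "
      f"GMM {s.mean_length_gmm:.2f} cm (eps {s.eps_length_gmm:.2f})")

seq = gen_feeding_sequence(SimConfig(seed=42))
q = run_quantity_pipeline(seq.frames, seq.dx, seq.dy, seq.theta, seq.l_fish)
print(f"quantity: mean {q.mean:.1f} +/- {q.std:.1f}, "
      f"95% CI [{q.ci95[0]:.1f}, {q.ci95[1]:.1f}]")
```

prints

```
N = 500, N_G = 350, c = 3
mean length: raw 25.13 cm (eps 0.14), GMM 21.92 cm (eps 0.00)
quantity: mean 2239.5 +/- 53.4, 95% CI [2134.8, 2344.3]
```

The mixture filter isolates the 350 single-fish instances out of 500
detections (c = 3 components: partial / single / merged), cutting the
mean-length relative error from 0.14 to 0.00; the cage pipeline, using only
the fallback detectors on noisy frames, brackets the true population of
2200 inside its 95 % interval.

The same workflows are available from the shell:

```bash
fishmetrics simulate --out data --seed 42
fishmetrics length-weight --masks data/masks --table data/length_weight_table.csv \
    --config lw.json --out summary.csv
fishmetrics quantity --frames data/frames --config cage.json --out quantity.csv
fishmetrics count --sonar-total 1000 --optical-counts '{"a": 55, "b": 45}' --out alloc.json
```

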