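# Methods

`rhizotrack` quantifies root development from time series of flatbed-scanner
images taken through the transparent face of a soil-filled rhizotron pot.
This note describes the models and procedures the package implements, the
choices made where the design was open, and what the synthetic validation
does and does not demonstrate.

## Physical calibration

All physical quantities derive from the scan resolution alone:
`mm_per_px = 25.4 / dpi`, `px_per_cm = dpi / 2.54`. Two resolution classes
are distinguished: *morphology* scans (any dpi from 50) for whole-frame
traits, growth dynamics and root lifespan, and *hair-grade* scans
(default threshold 4800 dpi, ~5.3 µm/px) for root-hair length, density and
hair lifespan. The observed frame defaults to the 20 × 34 cm pot face and
is configurable, since the scanned window may be smaller than the pot.

## Segmentation

Two segmenters produce binary root masks (white roots, black background):

* **Classical baseline** (`threshold_segment`): the smooth background is
  removed with a large local-mean filter (default 35 px), the flattened
  brightness is adaptively thresholded (a pixel must exceed its Gaussian
  neighbourhood mean by 20 grey levels over a 51 px block), followed by a
  1 px morphological opening and removal of components under 30 px.
  Deterministic, no training.

* **Learned model** (`SubPixelRootSegmenter`): a small encoder–decoder
  CNN implemented directly on numpy with a tape-based autograd. The
  encoder is a full-resolution stem plus stride-2 stages (default channel
  widths 8/16/16, total downsampling ×4). Multi-scale context comes from
  atrous spatial pyramid pooling: parallel 3×3 convolutions with distinct
  dilation rates (default 1/2/4) over the deepest features, fused by a
  1×1 projection. The decoder upsamples exclusively by sub-pixel
  convolution (pixel shuffle): a 1×1 convolution produces `4·C` channels
  that are reshaped into a ×2 larger grid, applied at every decoder stage,
  with encoder skip connections concatenated after each upsampling. This
  avoids the interpolation blur that loses one-to-three-pixel-wide root
  trajectories. The loss is pixel-wise binary cross-entropy plus a soft
  Dice term (weights 1:1); optimization is Adam (lr 5e-3), 10 epochs over
  64 px patches, 14 per frame per epoch, half of them centered on a
  foreground pixel so thin roots are not swamped by soil. Augmentation:
  flips, right-angle rotations, and a photometric gain/offset jitter
  (×0.9–1.1, ±0.04) that emulates scanner and pot-to-pot brightness
  variation; without it the model under-detects the darker senescent
  roots on unseen pots. A single `random_state` seeds initialization,
  sampling and augmentation, making training bit-reproducible. Frames
  larger than a patch are predicted in tiles with 25 % overlap and
  stitched from tile centers.

  The network is deliberately tiny (~15 k parameters): the synthetic
  scenes it is scored on are desk-scale, and the point exercised is the
  architecture pattern, not capacity.

Mask agreement is scored by IoU, Dice, precision and recall, with the
convention that two empty masks agree perfectly. Trait-level agreement
(`compare_trait_agreement`) measures RL/AD/RSA/RV on two mask sets through
the same trait pipeline and reports the squared Pearson correlation per
trait — the analysis style used to validate automatic segmentation
against manual tracing.

## Trait extraction

The mask is thinned to its medial axis; skeleton pixels form an
8-connected graph whose nodes carry the Euclidean distance transform (EDT)
value as a local radius, with diagonal edges suppressed when an orthogonal
two-step path exists (no double counting at junctions). Spurs shorter than
`prune_len_mm` (default 1 mm) that end at a junction are removed.

* **RL** (total root length, cm). Chain-code length (1 px orthogonal,
  √2 px diagonal edge weights) overestimates digitized curves by up to
  ~8 % at intermediate orientations — the classic staircase bias. RL is
  therefore measured per maximal skeleton path after a 5-point moving
  average of the pixel coordinates, which brings the error below ~1 % at
  any orientation. The raw edge weights remain on the graph and drive
  pruning and the cylinder models.
* **AD** (average diameter, mm): mean over skeleton nodes of
  `2·(EDT − 0.5)` pixels. The half-pixel term corrects the EDT (distance
  to the nearest *background pixel center*) to the shape boundary; on a
  5 px ribbon it makes the recovered radius exactly 2.5 px.
* **RSA / RV** (surface area cm², volume cm³): per-edge cylinder model
  using the mean corrected radius of each edge's endpoints — more
  faithful to tapering roots than the global `π·AD·RL` formula.
* **RLD** (root length density, cm/cm³): `RL / (A × DOF)` with `A` the
  observed frame area (cm²) and `DOF` the imaged depth of soil, default
  0.25 cm. Lengths are kept in cm throughout.

## Growth dynamics

The net growth rate of root length density is the finite difference
`RLD_NGR(n) = (RLD_n − RLD_{n−1}) / d` with `d` the true gap in days
(irregular sampling divides by the actual gap). No smoothing is applied to
exported values, so the rates telescope exactly:
`Σ NGR·d = RLD_last − RLD_first`. Negative values indicate net senescence.

Individual roots are tracked inside a static region of interest (the
region an analyst would draw around one root): each day, the connected
components of `mask ∩ ROI` overlapping the previous day's component
(dilated by 12 px, enough to bridge gaps cut by crossing roots and absorb
residual drift) are measured in isolation; a vanished root truncates and
flags the track. Length/diameter growth rates are finite differences over
the actual day gaps.

## Root hairs

On a hair-grade mask, the skeleton is partitioned by local width: nodes at
least `axis_min_width_mm` (default 0.08 mm) wide form the root axis; thin
branches under `hair_max_width_mm` (default 0.04 mm) whose length falls in
a plausibility band (0.05–1.5 mm) are hairs. A hair's length runs from the
root *surface* to its tip: the smoothed skeleton path length from the axis
attachment, minus the local axis radius there. Density is hairs per mm of
axis skeleton in the analyzed window — the density unit is a package
convention, stated explicitly because field reports often omit it.
`sample_hair_lengths` mirrors the manual protocol of measuring a handful
(default five) of randomly chosen hairs, reporting the seeded sample mean
next to the population mean.

Hairs whose base is buried where a junction locally thickens the
axis–hair union are not fully measurable by *any* method, including
manual tracing; validation therefore bounds per-hair error for at least
90 % of hairs (observed errors: mean −0.1 px, 5th–95th percentile
−2.1…+1.4 px).

## Lifespan and survival analysis

Frames are registered to the first frame by integer-pixel translation from
the FFT cross-correlation peak (scanner-fixed pots justify
translation-only; offsets beyond a bound or with low correlation fall back
to zero with a warning). For each subject region of interest:

* **emergence** is the first day the segmented mask puts at least
  `min_area` (default 15) pixels in the ROI;
* a **root** ends when the median brightness of its pixels drops below
  `live_min_brightness` (default 160 of 255; a median exactly at the
  threshold counts live) — newly emerged roots image white, senescent
  roots dark brown;
* a **hair** ends when its skeleton path's tortuosity (arc length over
  endpoint chord) exceeds 1.5 — "twisted and bent"; a semicircle
  (tortuosity π/2 ≈ 1.571) is just past the default threshold;
* subjects alive at the last frame are right-censored there.

Both thresholds are configuration-exposed; the source criteria are verbal,
so the numeric defaults are package conventions validated on the renderer's
palettes.

Lifespans feed a product-limit (Kaplan–Meier) estimator implemented in the
package: `S(t) = Π_{t_i ≤ t} (1 − d_i/n_i)`, censored subjects leaving the
risk set after their censoring time. The median lifespan is the smallest
observed event time with `S(t) ≤ 0.5` (undefined if S never reaches 0.5;
float ties at exactly one half count). Correctness is checked two
independent ways: exhaustively against a redistribute-to-the-right
construction on every sample of size ≤ 5, and against `lifelines` on random
samples. Two-group comparison reports the difference of KM medians plus the
standard log-rank chi-square and p-value (computed via `lifelines`).

## Synthetic rhizotron generator

The generator is the package's ground-truth instrument. A root system
grows as piecewise-linear polylines of fixed 0.5 mm steps: a taproot from
the top center, first-order laterals at Poisson-spaced attachment points
along it (alternating sides, ~55° branch angle), and second-order laterals
on those. Headings follow an AR(1) curvature process with weak reversion to
the initial direction (a simple tropism) and steer away from already-grown
roots — roots explore free soil rather than bundling, which keeps scenes
occlusion-light, the regime in which skeleton-based truth recovery is
well-posed. Laterals emerge at their parent's flank (the truth length is
the protruding arc). Because every step has fixed length, the visible arc
length of root *i* at day *t* is closed-form:
`L_i(t) = min(L0 + rate_i·(t − emergence_i), total_i)` with `L0 = 2.5 mm`
the emergence-day nub, making total root length, per-root rates, mean
diameter (linear taper), hair counts and event days exact oracles.

Default study conditions, chosen once as a realistic desk-scale analog of
a mid-season rhizotron window: 100 × 100 mm frame rendered at 150 dpi
(~591 px), 15-day horizon, taproot 6 mm/d and 1.2 mm basal diameter, 12
first-order laterals at 3 ± 0.6 mm/d and 0.6 mm, 4 second-order laterals
at 1.5 mm/d and 0.35 mm, tip diameter 45 % of basal. Scene density reaches
~0.3–0.7 cm of root per cm², comparable to published rhizotron frames.
Lateral lifespans are exponential (mean 30 d), right-censored at the
horizon; the taproot outlives the window. Hair specimens are separate
mm-scale windows at 4800 dpi with a single thin root (0.15 mm), 3 hairs/mm
of length 0.2–0.8 mm, and exponential hair lifespans (mean 12 d).

Rendering emulates a scan: a brownish soil background whose speckle
texture is a property of the pot (static across the series — this is what
makes registration meaningful) plus per-day fine noise; live roots
near-white (205 of 255), senescent roots dark brown (115) but still
present in the mask (segmentation is color-agnostic; liveness is judged
from appearance, separately); hairs drawn only at hair-grade dpi, bent
into a sinusoid (tortuosity ≈ 2) once distorted. All randomness is seeded;
every generator output is bit-reproducible.

**What passing these tests shows — and does not.** The synthetic scenes
validate the measurement chain against exact truth under controlled
conditions: correct calibration, unbiased length/diameter estimation,
correct survival arithmetic, day-exact event logic, end-to-end
determinism. They do not emulate occlusion by soil particles, condensation,
root decay textures ("folded epidermis"), pot-face pressure artifacts, or
color variation between scanner models, so scores here are upper bounds on
real-image performance; the learned segmenter in particular must be
retrained on annotated frames for any real deployment.

## Validation problem sizes

Chosen to exercise each property at meaningful scale: 30 frames (3 unseen
pots × 10 days) for trait recovery and trait-level agreement; training on
20 frames from 20 distinct pots (one frame each — one pot contributes one
soil texture, so spreading frames across pots maximizes texture diversity
at a fixed frame budget) with 10 held-out frames from 2 further pots;
9 tracked laterals over 3 scenes; exhaustive product-limit checks on all
406 samples of size ≤ 5; exponential-median calibration as the mean over
10 replicates of n = 300 (a single replicate's median has ~8 % standard
error, so only the replicated mean is a powerful test of a 10 % band);
log-rank power over 100 replicates of 200 + 200 subjects; event recovery
over 32 roots in 2 pots; an 8-day end-to-end pipeline determinism check.

## Known limitations

* Trait truth recovery assumes occlusion-light scenes; heavily overlapped
  root mats (late-season real data) break the skeleton-length oracle and
  would need area- or deep-regression-based length estimation.
* Diameter below ~2 px of width is reported at the resolution floor.
* Registration is translation-only; rotation or scale drift (pot
  re-seating) is out of scope.
* The senescence call uses median ROI brightness; partial senescence
  along one root is not staged.
* The KM median convention (smallest event time with S ≤ 0.5) is the
  left-continuous order statistic; software using interpolated medians
  will differ on small samples.
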