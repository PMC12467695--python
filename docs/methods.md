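# Methods

This note documents the models, conventions, numerical choices, and
limitations of `grafangle`. It is the design record; empirical claims here
are limited to what the test suite and `scripts/acceptance.py` themselves
compute.

## Coordinate and angle conventions

Images are 8-bit grayscale `(rows, cols)` arrays, origin top-left, 0-based.
All angles are degrees. A line is stored in angle–offset form: `theta ∈
[0, 180)` is the direction measured from the image **column (vertical)
axis**, positive clockwise (toward +col); `offset` is the signed
perpendicular distance from the origin along the normal
`(-sin θ, cos θ)`. A perfectly vertical iliac margin has θ = 0. Iliac
inclination is θ folded into [−90, 90] (so θ = 175° reads as −5°). The
α-angle between two lines is the inter-line angle folded into [0, 90],
which is the Graf convention for the bony-roof angle with a near-vertical
baseline: α is defined by the baseline along the iliac outer margin and
the line through the bony acetabular rim, not by the labrum (the labrum
belongs to the β construction, which is out of scope). Reported angles are
rounded to one decimal, half away from zero; dimensionless statistics to
two decimals. Rounding is applied only at reporting, never internally.

## The digital phantom

`make_scene` constructs the standard-plane geometry analytically before any
rasterization: the iliac outer margin is a segment at the requested
inclination from vertical ending at the **acetabular rim**; the **bony
roof** leaves the rim at exactly the requested α (unit-vector construction,
so the stored segments reproduce α to floating-point precision) and ends at
the **lower limb of the ilium**; a labrum point is placed beyond the rim as
a minor distractor. Valid domain: α ∈ (30, 90] — the upper bound is
inclusive so the perpendicular-roof case is constructible — and
|inclination| < 30°. Default canvas is 256×256 px at 0.1 mm/px (recorded in
metadata; the algorithms are resolution-agnostic and nothing downstream
depends on the physical spacing).

Rendering draws each bone surface as a **3-px-wide echo band** (Bresenham
line dilated by 1). Real bone surfaces return an echo several pixels thick,
and the band is what keeps ridge contrast well separated from the off-plane
degradation level after blurring; `rasterized_bone_pixels` exposes the
exact band pixel sets, and the noiseless render equals them exactly. The
artifact model, applied in order:

1. **Speckle** — multiplicative Rayleigh-like noise with unit mean,
   interpolated by `speckle_scale` (0 = none; default 0.2 for "moderate
   noise"). Multiplicative speckle is the standard first-order model of
   coherent ultrasound noise.
2. **Blur** — Gaussian PSF, `blur_sigma_px` (default 1.0).
3. **Shadow** — column-wise attenuation (default 0.4) of non-bone pixels
   more than 2 px below the first bone surface in each column, emulating
   acoustic shadowing along the beam axis. Bone pixels are never
   attenuated, so the bone ridge remains the intensity maximum along any
   scanline crossing it whenever speckle is off.

**Off-plane frames** (probe drifted out of the standard plane) are rendered
by multiplying the contrast of the roof and of the rim-adjacent 15 px of
the iliac margin by 0.3 — the structures whose visibility defines the
plane fade, while the cranial iliac margin stays visible. The factor is
chosen so that quality gating must reject these frames. Video sequences
apply a fixed per-frame rotation about the rim plus translation; frame
*k*'s ground truth is the scene after *k* accumulated steps, and
`diagnostic_quality` is false exactly for the off-plane indices.

What the phantom does **not** emulate: anatomical shape variability,
curved bone surfaces, soft-tissue layers, femoral head and cartilage
echoes, depth-dependent attenuation/focusing, and geometric distortion of
off-plane views (off-plane here only dims landmarks; a real off-plane view
also distorts the apparent angle). Passing tests on this phantom therefore
demonstrate correctness of the measurement chain under the stated
conditions, not clinical performance.

## Landmark detection

The detector contract is a callable `frame → [detections]` with at most one
detection per label, rim first; any learned detector satisfying it can be
plugged into the pipeline. The reference implementation is classical:

- bone candidates = per-row strict local maxima, screened (below);
- the **iliac margin** is the longest ridge chain (row-adjacent candidates
  whose column steps stay within 2 px/row — near-vertical structures chain,
  steeper ones fragment);
- the **rim** is the chain's caudal terminus, or the first point where the
  chain deviates more than 1.5 px from the line fitted to its cranial 60%
  (shallow-roof scenes keep the roof chain-connected, so a corner test is
  needed); terminus ties break toward the greater row;
- the **lower limb** is the screened column-scan ridge point with maximal
  perpendicular clearance (≥ 15 px) from the iliac line, ties toward the
  greater row — i.e. the medial terminus of the roof.

Boxes are fixed 24×24 px (the box size is not critical: downstream geometry
uses the box center as the baseline anchor, and α depends only on line
directions, not the anchor). Confidence is the normalized local ridge
contrast: the 95th percentile of the box window minus the frame's 20th
percentile, over the 8-bit range. For the rim, only the **caudal half** of
the box is scored: a true rim is validated by the roof actually departing
caudally from it, whereas a mere fade-out of the iliac ridge (an off-plane
frame) leaves that half dark. Without this the detector can place the rim
at the fade point, with fully bright iliac margin above it, and off-plane
frames would score high confidence. No detection is emitted below a floor
of 0.1. Degenerate frames (constant, non-grayscale) yield an empty list
with a logged warning.

## Peak extraction and screening

Per-scanline strict local maxima (plateaus excluded) with a minimum
separation of 5 px; row scans serve the iliac fit (the near-vertical margin
crosses each row once), column scans serve the roof fit. An optional
three-point parabolic interpolation refines peak positions to sub-pixel
accuracy (on by default in the measurement path; integer positions in the
detector, which only needs boxes).

Screening keeps peaks with intensity ≥ μ + kσ of the candidate-peak
population (k default 2.0, sample SD), **capped at the midpoint of the
peak intensity range**. The cap matters in the degenerate but common clean
case: when nearly every candidate peak already lies on bone the population
is narrow and unimodal, and an uncapped μ + 2σ threshold sits above almost
all of it, discarding valid bone surfaces; on bimodal speckle-plus-bone
populations the cap is inert. Both threshold forms scale linearly with
intensity, so screening is invariant under global intensity scaling. A
second rule drops ridge runs shorter than 5 consecutive scanlines, which
removes isolated impulse/speckle survivors without any median filtering
(median footprints were rejected because every footprint erodes 1-px
ridges at some orientation).

## Line fitting

The iliac margin is near-vertical, so ordinary regression of column on row
is ill-posed; all fits are **total least squares** (principal axis of the
centered points), with the RMS perpendicular distance as the residual.
The static path seeds with a **point Hough transform** (1° × 1 px bins,
direction search restricted to ±30° of vertical for the iliac line),
breaks accumulator ties toward the smallest θ then smallest offset, takes
inliers within 2 rho-bins of the winning bin, and TLS-refines them —
robust to a moderate fraction of gross outliers. The dynamic path fits the
longest ridge chain directly (cheaper, suited to frame-rate processing).
The roof is fitted to screened column-scan points inside the bounding
region spanned by the two landmark boxes inflated by 10 px, after removing
points within 4 px of the baseline so the iliac ridge passing through the
rim box cannot contaminate the fit. Fewer than two usable points at any
stage produces a reason-coded failure (`rim_not_detected`,
`iliac_fit_failed`, `roof_fit_failed`, …), never a silent number.

## Quality gates and aggregation

Defaults: per-landmark confidence ≥ 0.3; |inclination| ≤ 5° (the Graf
standard plane requires a near-vertical iliac margin); iliac fit RMS ≤ 2 px;
roof fit RMS ≤ 3 px. Reasons accumulate rather than short-circuiting, except
that fit-dependent gates are skipped when the measurement itself failed.
Frames are processed independently — no temporal smoothing — and the
sequence aggregate (mean, sample SD) is computed over diagnostic frames
only; zero diagnostic frames yield an explicit empty aggregate. "Success"
for a frame means a gated, non-failure α.

## Statistics

Bland–Altman: bias = mean(value − reference), SD with n−1 denominator,
95% limits of agreement = bias ± 1.96·SD. ICC(2,1) (two-way random
effects, absolute agreement, single measurement) is computed from the
two-way ANOVA mean squares with the F-based McGraw–Wong confidence
interval; ICC(2,k) is exposed for average-of-raters reliability, and the
model label is always recorded in the result because reliability tables
rarely state it. One-way ANOVA reports F, p, η² = SS_between/SS_total,
Cohen's f = √(η²/(1−η²)), and post-hoc power from the noncentral F
distribution with λ = f²·N at the observed effect size. The implementations
are deliberately independent of the reference libraries used to cross-check
them in the tests (an explicit mean-squares oracle and `pingouin` for ICC,
`scipy.stats.f_oneway` for ANOVA).

## Problem sizes and determinism

The phantom benchmark uses 40 frames at 256×256 px (≈ 2 s on one core);
property suites use 50-frame batches and 100-point-cloud oracle sweeps —
sizes chosen so the whole suite exercises every path in well under a
minute while keeping stochastic assertions stable across seeds. Every
random draw flows from an explicit seed through
`numpy.random.SeedSequence` spawning (one child per frame), so renders,
sidecars, and CLI JSON outputs are bit-reproducible for a fixed seed and
config.

## Known limitations

- The detector assumes a single hip in the canonical orientation (iliac
  margin near-vertical, roof opening toward +col); mirrored or multi-hip
  frames are out of scope.
- The corner test for the rim assumes the roof is visibly distinct from
  the iliac direction; at α near the 30° lower bound with strong noise the
  chain corner can blur into the margin.
- Off-plane emulation dims landmarks but does not distort geometry, so
  gate performance on real off-plane frames (which also distort α) is not
  demonstrated here.
- β-angle measurement, Graf type classification, and femoral-head coverage
  are intentionally excluded.
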