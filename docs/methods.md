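# Methods

## Problem and assumptions

The pipeline locates the pupil center in 8-bit grayscale near-infrared
periocular images, including defocus-blurred ones. It assumes only that

- the pupil is the darkest extended structure in the frame (true under NIR
  illumination, where the retina returns almost no light),
- the pupil is compact and roughly elliptical, though its boundary may be
  locally convex/concave and partially occluded by glints,
- blur, if present, acts approximately like a symmetric low-pass kernel.

No edge map, no conic fit to boundary points, and no trained model are used;
every decision is made from region-level statistics, which degrade slowly as
blur diffuses the boundary.

## Stage 1 — grayscale constraint (rough ROI)

**Adaptive threshold.** The 256-bin histogram is smoothed with a centered
moving average (`smooth_window`, default 5, zero-padded at the ends). The
smoothed curve is decomposed into modes: local maxima are found (plateaus
collapse to their left edge), and two adjacent maxima are merged into one
mode when the valley between them stays above half of the lower maximum —
shallow dips of that kind are sampling noise inside one gray mode, not a
boundary between modes. A mode is *significant* when the raw pixel count
over its support is at least `min_peak_frac` (default 0.001) of the image.
Significance is deliberately defined on the mode's **mass**, not on bin
height: sensor noise spreads a small pupil's pixels over a dozen gray bins,
so any per-bin height criterion either misses real pupils or needs
image-dependent tuning, while the total mass of the mode is invariant to
that spread. The threshold T is the smallest gray level attaining the
minimum smoothed count strictly between the peaks of the first (darkest)
and second significant modes. With fewer than two significant modes there
is no valley; the fallback takes the largest T whose cumulative histogram
fraction stays ≤ 5 % (the pupil is a small dark fraction of the frame), and
a uniform image, where even that fails, yields "no pupil candidate" rather
than a forced threshold.

**Projection ROI.** Foreground is gray ≤ T (inclusive). Per-row and
per-column foreground counts are thresholded at `projection_frac` (default
0.15) of each profile's maximum; the first-to-last qualifying indices in
each direction form a rectangle, which is then expanded on every side by
`long_side // expand_divisor` pixels (default divisor 20). The expansion
absorbs boundary glints that eat into the thresholded support; the ROI is
intended to be generous, since stage 2 does the discrimination.

## Stage 2 — geometric constraint (shape-index screening)

The ROI mask is opened with a disc of radius `opening_radius` (default 1)
to delete speckle noise, labeled with 8-connectivity, and each component's
enclosed holes are filled (4-connected background flood, the dual
connectivity — glint reflections punch such holes into the pupil).
Components smaller than `min_area` (default 15 px) never compete.

Each candidate is scored with

w = λ₁ · I_minor/I_major + λ₂ / (1 + ΔFittingError),  λ₁ = 0.6, λ₂ = 0.4.

- **Inertia ratio** I_minor/I_major is the eigenvalue ratio of the 2×2
  second-central-moment matrix of member pixel centers: 1 for a disc,
  (b/a)² for an ellipse, → 0 for a line. Regions with fewer than 5 pixels
  or a degenerate major eigenvalue score 0.
- **ΔFittingError** is the area of the symmetric difference between the
  component and its moment-equivalent ellipse (center = centroid,
  orientation = principal eigenvector, semi-axes = 2·√eigenvalue), divided
  by the component's area. It is ≈ 0 for true ellipses with smooth
  boundaries, ≈ 0.2 for a square, large for bars, arcs and ragged blobs.
  This definition needs no contour extraction, which is the point of the
  whole design: under blur the thresholded boundary is diffuse but the
  region's bulk, and hence its moments, barely move. Degenerate regions get
  +∞, so their second term vanishes.

Both terms are computed in bounding-box-local coordinates, which makes the
score exactly (bit-for-bit) translation-invariant. The highest-w component
wins; exact ties break toward larger area, then smaller centroid distance
to the ROI center, then smaller label — a deterministic total order.

The two terms are complementary: the inertia ratio alone prefers any
symmetric mass distribution (a curled hair strand or an arc can beat a
slightly elliptical pupil), while the fitting error alone tolerates
elongated ellipses (an eyebrow fragment). Their weighted sum favors the
pupil specifically; the screening test in the suite measures this against
inertia-only ranking on candidate sets of pupil + eyebrow bar + hair-like
streaks.

## Stage 3 — geometric moments

Member pixels weigh 1, everything else 0, so M₀₀ = area, M₁₀ = Σx,
M₀₁ = Σy, the center is (M₁₀/M₀₀, M₀₁/M₀₀) shifted by the ROI offset, and
the size is the equivalent-circle radius √(M₀₀/π). The binary weighting
(rather than gray-weighted moments) makes the radius formula exact for
discs and the centroid identical to the arithmetic mean of member
coordinates, which the tests verify against an independent exact-integer
oracle. The cost is one pass over the region — linear in its pixel count.

The radius is a circular-model summary: for elliptical pupils it is the
radius of the equal-area circle, and under heavy blur, if the threshold
absorbs part of the iris into the winning region, the reported radius
inflates even while the center (of a roughly concentric region) stays
accurate. Callers needing axes can fit the moment ellipse to the winning
region.

## Synthetic scene generator

Each scene composites, in order: skin background (gray 160), a lens-shaped
eye opening (intersection of two discs) filled with sclera gray 200, an
iris disc (gray 90), the pupil ellipse (gray 20) with low-order radial
roughness (harmonics 2–5, fractional amplitude `boundary_roughness`,
default 0.04) so the boundary is convex-concave rather than a perfect
conic, an optional soft-edged dark eyebrow bar (gray 55 — between pupil and
iris, so it genuinely competes in thresholding), and 0–2 near-saturated
glints (gray 245) near the pupil. The frame is then blurred with a Gaussian
of `blur_sigma` and perturbed with additive Gaussian noise (std 3, a
typical NIR sensor read-noise scale), clipped to [0, 255].

Defocus distance maps to blur linearly: σ = σ_max·|z|/z_max with σ_max = 6 px
at z_max = 20 cm for 640×480 frames. This is a stated surrogate for a real
camera's point-spread function, not a calibration claim; σ_max is
configurable to emulate harder optics.

Ground truth is the centroid of the rasterized pre-blur pupil support.
Because the blur kernel is symmetric and the noise zero-mean, that centroid
is what an ideal estimator would recover, so measured error is attributable
to the algorithm.

What the generator does **not** emulate: eyelashes and eyelid occlusion,
specular reflections from glasses, off-axis gaze distortion of the pupil,
non-uniform illumination, and motion blur. Passing the synthetic benchmark
therefore demonstrates defocus robustness and distractor rejection under
the stated palette assumptions, not performance on arbitrary field footage.

Randomized draws (used by `generate_dataset` and the benchmark) jitter the
eye center by ±60/±40 px, draw the iris radius from U(55, 75) px, the pupil
semi-major axis from U(0.30, 0.45)·iris radius with aspect U(0.85, 1.0) —
near-circular, as for near-frontal gaze — random orientation, 0–2 glints,
and an eyebrow with probability 0.7. Every image's seed derives
deterministically from the master seed, and the manifest stores it, so any
row can be re-rendered exactly.

## Evaluation

Error is the Euclidean distance between predicted and true centers; an
image is correctly localized when the error is within 1 % of the long side
(inclusive — 6.4 px at 640×480), and accuracy is the correct fraction.
A no-detection counts as incorrect; its error is recorded as NaN, excluded
from mean-error aggregation but kept in the accuracy denominator.
Unreadable files are logged, marked `read_error` and counted as incorrect.
The harness also logs per-image wall-clock at debug level as information
only; timing is hardware-bound and never asserted.

## Problem sizes

The packaged benchmark uses 20 images per defocus level across
z ∈ {0, 5, 10, 15, 20} cm (100 images) for the blur sweep and 60 sharp
images for the in-focus stratum, at 640×480 — large enough that accuracy
fractions are meaningful at the percent level while a full run stays in the
tens of seconds on one core.

## Known limitations

- A distractor darker than the pupil that also forms the darkest histogram
  mode (deep cast shadow filling most of the frame) would capture the
  threshold; the shape index then has to reject it, which works only if it
  is also in the ROI.
- The 0.5 valley-merge fraction in mode detection is a fixed heuristic;
  histograms with genuinely overlapping pupil/iris modes (extreme blur plus
  strong noise) can merge into one mode and force the 5 % dark-tail
  fallback.
- The equivalent radius is unreliable under heavy blur (see stage 3); the
  center is the supported output.
- Multi-pupil frames are out of scope by design: exactly one winner (or
  `no_pupil_found`) is returned.
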