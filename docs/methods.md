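# Methods

## The model

A brightfield two-stain histology image (e.g. hematoxylin–DAB
immunohistochemistry) is, physically, a bivariate dataset: each pixel
records the local concentration of a chromogen and of a counterstain,
rendered through Beer–Lambert absorption.  In optical density,

    OD_c = -log10(I_c / I_0),   c ∈ {R, G, B},  I_0 = 255,

stain mixing is linear: `od = c_h·H + c_d·D + c_res·E`, where `H`, `D` are
unit stain vectors, `E` a unit residual direction, and the concentrations
`c_h, c_d` are the quantities of biological interest.  Everything in this
package rests on four operations built on that model:

1. **Unsupervised stain unmixing.**  The classical Ruifrok–Johnston
   reference vectors describe typical dyes, but real hues drift with
   chemistry, protocol and scanner.  We fit the best origin plane to the
   image's OD pixel cloud by *uncentered* PCA (SVD of the raw pixel
   matrix — the mixing model passes through the origin because zero stain
   means zero absorption), then project the reference vectors onto that
   plane and renormalize.  The optimized residual direction is the plane
   normal, so the mean squared residual channel is exactly the mean squared
   out-of-plane distance, which the SVD plane minimizes among all origin
   planes — the optimized basis can therefore never have a larger residual
   MSE than the reference basis on the pixels used for the fit.

2. **Bivariate color-map extraction.**  Clamped concentrations are
   normalized to the unit square by robust per-channel percentile anchors
   (p1/p99), binned into a K×K grid (default K = 64), and each observed
   bin's color is the CIELAB mean of its member pixels.  Unobserved bins
   are filled by scattered (Delaunay) linear interpolation over observed
   bin centers, nearest-neighbor beyond their convex hull.  The u axis is
   the chromogen (foreground), v the counterstain (background); (0, 0) is
   the unstained white corner.

3. **Perceptually linear map design.**  A replacement map is a bilinear
   patch in CIELAB between four corners — white at (0,0), black at (1,1)
   and two free hues — so equal concentration steps give equal CIE76 ΔE
   steps along any row or column.  Interpolation happens in CIELAB;
   conversion to sRGB (with per-channel clipping, fraction recorded) comes
   last.  Design rules: at most two basic hues among the chromatic corners,
   and never red together with green (red–green deficiency is the most
   prevalent).  Hue categories come from the CIELAB hue angle with
   chroma < 10 counting as achromatic; the red bin spans [−35°, 45°)
   because pure sRGB red sits near 40°.

4. **Re-staining.**  Per pixel: deconvolve, clamp concentrations to ≥ 0,
   normalize to (u, v) with the stored anchors, look the coordinate up in
   the target map (bilinear between grid cells by default; nearest
   available).  Output depends only on (u, v), so a uniform illumination
   change — an additive OD offset absorbed by the per-image percentile
   anchors — leaves the result invariant.

## Contrast metrics

Perceived contrast between two colors is CIE76 ΔE (Euclidean CIELAB
distance, sRGB primaries, D65 white, 2° observer).  Two summaries are
used:

- **Map contrast profile**: ΔE of every map entry to the neutral center,
  the entry at (u, v) = (0.5, 0.5) (for bilinear designed maps this equals
  the corner mean).  Summary statistics are computed on a 25×25 grid
  (`DEFAULT_STATS_K`): the maximum is corner-attained and grid-insensitive,
  while the mean and SD weight edge and corner colors at the resolution
  that reproduces the reference values for both the blue/orange map
  (max 82.6, mean 37.4, SD 16) and the native brown/blue map (max 51.7,
  mean 22.9, SD 10.1).  Maps used as re-staining lookup tables default to
  256×256.
- **Map surface area**: the area of the map's image surface in CIELAB
  (triangulated grid cells) — a direct measure of how much of the
  perceivable color space the map occupies.

## Phantom evaluation

The phantom is an abstract bivariate dataset: 36 equal, disjoint circles
on a homogeneous background.  The circles take the 6×6 product grid of
levels {1/6, …, 1} on *both* stain axes, so they sample the full mixing
surface of a candidate map; the background carries counterstain only,
(u, v) = (0, 1).  A (foreground hue, background hue) pair is scored by the
mean ΔE between each circle's rendered color and the background color;
36 circles give the mean ± SD.  Scoring all 225 ordered pairs of the
15 packaged comparison colors and dividing by the global maximum yields
the normalized pairwise matrix; the standard brown-on-blue pair lands at
43% of the best pair (inside the reference 39% ± 7% band), an improvement
factor of ≈ 2.3 for the best map.  Circle colors depend only on their
(u, v) levels, so the scores are independent of canvas resolution.

Ten of the fifteen packaged colors are corner hues of five candidate
foreground/background map pairs; only two pairs' hues are fixed by the
reference material (#FF0000/#0093FF and #006EFF/#FFAD00), and the
remaining six are synthetic stand-ins chosen inside the red–orange/blue
families the design rules admit (see
`data/phantom_colors_synthetic.json`).

## Foreground segmentation and contrast improvement

DAB-positive foreground is segmented by Otsu's threshold, implemented from
the between-class-variance definition on a 256-bin histogram over the
p1–p99 range so the threshold is bit-reproducible, followed by removal of
8-connected components below 64 px.  The threshold is floored at a DAB
concentration of 0.1: on a blank image Otsu would otherwise split pure
sensor noise, whose supra-threshold speckle percolates into large
components; with the floor, blank images raise the explicit
empty-foreground signal.  Contrast improvement between an original and a
re-stained image is the ΔE between mean foreground and mean background
CIELAB colors, after vs. before, as a percentage change.

## Dichromacy simulation

Deuteranopia and tritanopia are simulated with the Brettel–Viénot–Mollon
confusion-line model: linear sRGB → LMS (Vischeck matrix), replacement of
the missing cone's response by projection onto one of two half-planes
through the gray axis and a monochromatic anchor (475/575 nm for
deuteranopia, 485/660 nm for tritanopia), then LMS → sRGB.  Out-of-gamut
results are desaturated toward the luminance-matched gray rather than
clipped per channel: the gray axis lies in every confusion plane, which
keeps the simulation exactly idempotent on the continuous path (8-bit
quantization can still shift saturated boundary colors by a few steps).
Map robustness is the ratio of mean distance-to-center contrast after vs.
before simulation, computed on the displayed (gamut-clipped) grids.

## Synthetic data

`bistain.synth` generates the test images: a smooth low-frequency
counterstain field (concentration 0.2–0.6), elliptical chromogen blobs
(12 objects, radii 8–20 px, concentration 0.4–1.0) on a 256×256 canvas,
Gaussian noise added in OD space (SD 0.02 — multiplicative in
transmittance, the dominant sensor behavior in brightfield), then
exponentiation and 8-bit quantization.  The image's "true" stain vectors
are the reference vectors rotated 5° (default) about a random axis *in*
the reference stain plane: an in-plane axis tilts the stain plane itself,
which is precisely the deviation the PCA optimization corrects; rotation
about the plane normal would be pure hue drift that no plane method can
address.  All randomness flows from one seed; regeneration is
byte-identical.

What the generator does **not** emulate: tissue texture, scanner point
spread and vignetting, chromatic aberration, stain co-localization
statistics of real tissue.  Passing tests therefore demonstrate the
correctness of the algebra, the recovery behavior under the stated noise
model, and the direction of the contrast effects — not performance on any
particular real-world corpus.

## Numerical choices and degenerate inputs

- All image math in float64; quantization to uint8 only at file
  boundaries.
- OD transform floors intensity at 1 before the log (caps OD at
  log10 255 ≈ 2.407; avoids infinities, keeps the PCA stable).
- Plane fitting excludes pixels with total OD < 0.15 (near-white pixels
  carry no directional information) and subsamples at most 200 000 pixels
  deterministically.
- Blank/constant images, rank-deficient pixel clouds and maps with fewer
  than 3 observed bins raise `DegenerateImageError`; empty segmentations
  raise `EmptyForegroundError`; a reference vector orthogonal to the
  fitted plane (projection norm < 1e-6) is an error because the hue
  orientation is unrecoverable.
- Negative concentrations are preserved in `ConcentrationImage` (so the
  residual MSE is honest) and clamped to ≥ 0 only when mapping into color
  maps.
- Principal directions are sign-fixed against the reference vectors; the
  residual sign makes the basis determinant positive.

## Known limitations

- Strictly two-stain: no three-stain unmixing, no blind estimation of the
  number of stains.
- The corner hues are not globally optimized; the design rules prune the
  search space but the blue/orange pair is adopted from the reference
  material, not re-derived.
- CIE76 ΔE overstates differences among highly chromatic colors relative
  to ΔE2000; all comparative statements here are within-metric.
- The phantom geometry (circle levels, background coordinate) is a
  reconstruction; its headline ratios land inside the reference bands but
  individual pair scores can differ from the reference figure.
- Whole-slide formats, tiled pyramids and viewer integration are out of
  scope.
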