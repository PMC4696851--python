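# bistain

**Digital re-staining of two-stain histology images.**

The blue–brown colors of hematoxylin–DAB immunohistochemistry are dictated
by dye chemistry, not by the human visual system — and in CIELAB terms the
set of colors such an image can display (its *bivariate color map*) is
small, so much of the information in the image never reaches the observer
as perceivable contrast.  `bistain` measures that inherent color map and
replaces it with a perceptually linear one, without touching the
underlying stain-intensity data.

It is aimed at digital-pathology tooling and image-analysis pipelines that
work with brightfield two-stain images (H-DAB, and by the same machinery
H&E or Giemsa).

## What it does

Stain mixing is linear in optical density (Beer–Lambert):
`od = c_h·H⃗ + c_d·D⃗ + c_res·ϵ⃗`, with unit stain vectors `H⃗, D⃗` and a
residual direction `ϵ⃗`.  The pipeline:

1. **Unsupervised optimized deconvolution** — fit the best origin plane to
   the image's OD pixel cloud by uncentered PCA, project the published
   Ruifrok–Johnston H-DAB reference vectors onto it (hue preserved,
   residual minimized), and invert the mixing model per pixel.
2. **Color-map extraction** — normalize concentrations to the unit square
   by robust percentile anchors, bin pixel colors on a K×K grid, and
   interpolate unobserved bins: the image's own bivariate color map.
3. **Map design** — build a replacement map as a bilinear CIELAB patch
   between four corners (white, black, a foreground hue, a background
   hue): perceptually linear by construction, with design rules that cap
   the hue count at two and forbid red–green combinations.
4. **Re-staining** — per pixel, look the (u, v) stain coordinate up in the
   new map.  Output depends only on (u, v), so uniform illumination
   differences drop out.
5. **Evaluation** — CIE76 ΔE contrast metrics: map contrast profiles,
   6×6-circle phantom comparisons of 225 hue pairs, Otsu-segmented
   object-to-background contrast improvement, and dichromacy (deuteranopia
   / tritanopia) robustness checks.

A deterministic synthetic-image generator with full per-pixel ground truth
(`bistain.synth`) backs the test suite.

## Worked example

```sh
# a synthetic H-DAB image with known ground truth
bistain simulate --seed 7 -o sample.png

# the blue/orange replacement map and its contrast profile
bistain design-map --fg "#006EFF" --bg "#FFAD00" -o map.png
# {"mean": 37.40336038406877, "sd": 15.956155164417826, "max": 82.60004175204445}

# re-stain the image with it
bistain restain sample.png restained.png --fg "#006EFF" --bg "#FFAD00"
# {"residual_mse": 0.0003997917594906672, "output": "restained.png"}

# how much did object-to-background contrast improve?
bistain contrast-eval sample.png restained.png
# {"config": {"min_object_px": 64}, "contrast_before": 46.288132375360455,
#  "contrast_after": 73.6201801648163, "improvement_pct": 59.04763572618219}
```

Reading the numbers: the designed blue/orange map reaches a maximum CIE76
distance of **82.6** from its neutral center (mean 37.4 ± 16) — against
51.7 (mean 22.9 ± 10.1) for the native brown/blue map, i.e. the
replacement map simply contains more distinguishable colors.  Re-staining
the sample image left a residual unmixing MSE of 4.0·10⁻⁴ (OD² per pixel)
and raised the ΔE between mean DAB-object color and mean background color
from 46.3 to 73.6, a **+59%** contrast improvement.

The same library surface is available from Python:

```python
from bistain import design_map, fit_stain_model, restain_image, generate_ihc

sample = generate_ihc(seed=7)
model = fit_stain_model(sample.image)          # PCA-optimized stain basis
target = design_map("#006EFF", "#FFAD00")      # perceptually linear map
result = restain_image(sample.image, model, target)
```

## Layout

| Module | Contents |
| --- | --- |
| `bistain.color` | sRGB / OD / CIELAB conversions, CIE76 ΔE |
| `bistain.unmix` | stain bases, PCA plane fit, optimized deconvolution |
| `bistain.maps` | bivariate map extraction, design, validation, metrics |
| `bistain.restain` | pixel-wise re-staining, end-to-end file pipeline |
| `bistain.evaluation` | phantom pairwise matrix, Otsu foreground, contrast reports |
| `bistain.cvd` | dichromacy simulation (Brettel-style LMS projection) |
| `bistain.synth` | synthetic two-stain images with ground truth |
| `bistain.io` / `bistain.cli` | image I/O and the `bistain` command |

Design rationale, numerical choices and limitations: `docs/methods.md`.
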