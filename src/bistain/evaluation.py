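"""Quantitative validation: phantom-image pairwise color-map comparison and
Otsu-based foreground/background contrast improvement.

The phantom is an abstract bivariate dataset — 36 equal circles on a
homogeneous background — that samples the (u, v) unit square of a color map:
the circles take the 6x6 product grid of stain levels {1/6 .. 1} on both
axes, and the background carries counterstain only, (u, v) = (0, 1).
Coloring a phantom with a designed four-corner map and measuring the mean
CIE76 distance of each circle's color to the background color gives a
perceptual-contrast score for that foreground/background hue pair; scoring
all ordered pairs of a color list and normalizing by the global maximum
yields the pairwise contrast matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from skimage.morphology import remove_small_objects

from .color import delta_e, rgb_to_lab
from .errors import DegenerateImageError, EmptyForegroundError
from .maps import design_map
from .unmix import ConcentrationImage

__all__ = [
    "Phantom",
    "PairwiseContrastMatrix",
    "ContrastReport",
    "default_phantom_coords",
    "packaged_phantom_colors",
    "make_phantom",
    "apply_map_to_phantom",
    "phantom_contrast",
    "pairwise_matrix",
    "otsu_threshold",
    "foreground_mask",
    "contrast_improvement",
]


def default_phantom_coords() -> np.ndarray:
    """The 36 default circle coordinates: the row-major 6x6 product grid of
    levels (1/6, 2/6, ..., 1) on the foreground (u) and background (v)
    axes."""
    levels = (np.arange(6) + 1) / 6.0
    uu, vv = np.meshgrid(levels, levels, indexing="ij")
    return np.stack([uu.ravel(), vv.ravel()], axis=-1)


def packaged_phantom_colors() -> list[str]:
    """The 15 phantom comparison colors shipped with the package.

    Ten corner hues of five optimized foreground/background map pairs, the
    standard blue and brown of H-DAB staining, plus black, gray and white as
    controls.  Six of the ten map hues are synthetic stand-ins (see the
    fixture file's note).
    """
    text = resources.files("bistain.data").joinpath(
        "phantom_colors_synthetic.json"
    ).read_text()
    return json.loads(text)["colors"]


@dataclass
class Phantom:
    """Abstract 6x6-circle phantom: geometry plus per-circle (u, v) levels.

    ``label_image`` holds the circle index per pixel (-1 on the background
    field); ``circle_coords`` the 36 (u, v) stain coordinates, row-major;
    ``bg_coord`` the field's coordinate.  Coloring is deferred to
    :func:`apply_map_to_phantom`.
    """

    label_image: np.ndarray
    circle_coords: np.ndarray
    bg_coord: np.ndarray
    radius: int

    @property
    def n_circles(self) -> int:
        return self.circle_coords.shape[0]

    def fg_masks(self) -> list[np.ndarray]:
        return [self.label_image == k for k in range(self.n_circles)]

    def bg_mask(self) -> np.ndarray:
        return self.label_image < 0

    def uv_image(self) -> np.ndarray:
        uv = np.empty(self.label_image.shape + (2,), dtype=float)
        uv[...] = self.bg_coord
        for k in range(self.n_circles):
            uv[self.label_image == k] = self.circle_coords[k]
        return uv


def make_phantom(
    coords: Optional[np.ndarray] = None,
    cell: int = 64,
    radius: Optional[int] = None,
) -> Phantom:
    """Build the circle phantom.

    ``coords`` are 36 (u, v) pairs (defaults to the 6x6 product grid);
    circles are laid out row-major on a 6x6 lattice of ``cell``-pixel cells,
    radius defaulting to ``0.38 * cell`` so circles never touch.
    """
    coords = default_phantom_coords() if coords is None else np.asarray(coords, float)
    if coords.shape != (36, 2):
        raise ValueError("expected 36 (u, v) circle coordinates")
    if np.any(coords < 0) or np.any(coords > 1):
        raise ValueError("circle coordinates must lie in [0, 1]")
    radius = int(round(0.38 * cell)) if radius is None else int(radius)
    if radius * 2 >= cell:
        raise ValueError("radius too large: circles would touch")
    side = 6 * cell
    label = np.full((side, side), -1, dtype=int)
    yy, xx = np.mgrid[0:side, 0:side]
    for k in range(36):
        r, c = divmod(k, 6)
        cy, cx = r * cell + cell // 2, c * cell + cell // 2
        label[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = k
    return Phantom(
        label_image=label,
        circle_coords=coords,
        bg_coord=np.array([0.0, 1.0]),
        radius=radius,
    )


def apply_map_to_phantom(p: Phantom, fg, bg, K: int = 256) -> np.ndarray:
    """Render the phantom through the designed ``fg``/``bg`` four-corner
    map; returns a uint8 RGB image."""
    m = design_map(fg, bg, K=K)
    uv = p.uv_image()
    rgb = m.evaluate(uv[..., 0], uv[..., 1])
    return np.round(rgb).astype(np.uint8)


def phantom_contrast(p: Phantom, fg, bg, K: int = 256) -> tuple[float, float]:
    """Mean and SD over the 36 circles of the CIE76 distance between each
    circle's rendered color and the background's rendered color."""
    m = design_map(fg, bg, K=K)
    circle_lab = m.evaluate(p.circle_coords[:, 0], p.circle_coords[:, 1], space="lab")
    bg_lab = m.evaluate(p.bg_coord[0], p.bg_coord[1], space="lab")
    d = delta_e(circle_lab, bg_lab)
    return float(d.mean()), float(d.std())


@dataclass
class PairwiseContrastMatrix:
    """All ordered foreground/background pairs of a color list, scored on
    the phantom and normalized to the best pair."""

    colors: list[str]
    mean_grid: np.ndarray  # normalized, in [0, 1]
    sd_grid: np.ndarray  # scaled by the same factor
    max_raw: float
    duplicates: list[str]

    def lookup(self, fg: str, bg: str) -> tuple[float, float]:
        i = self.colors.index(fg)
        j = self.colors.index(bg)
        return float(self.mean_grid[i, j]), float(self.sd_grid[i, j])


def pairwise_matrix(
    colors: Optional[Sequence[str]] = None,
    phantom: Optional[Phantom] = None,
) -> PairwiseContrastMatrix:
    """Score every ordered (foreground, background) pair of ``colors`` on
    the phantom and normalize all means by the global maximum mean.

    Defaults to the packaged 15-color list (225 ordered pairs).  Duplicate
    colors are allowed but flagged.
    """
    colors = list(packaged_phantom_colors() if colors is None else colors)
    p = make_phantom() if phantom is None else phantom
    n = len(colors)
    means = np.zeros((n, n))
    sds = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            means[i, j], sds[i, j] = phantom_contrast(p, colors[i], colors[j])
    max_raw = float(means.max())
    if max_raw <= 0:
        raise DegenerateImageError("all phantom contrasts are zero")
    dupes = sorted({c for c in colors if colors.count(c) > 1})
    return PairwiseContrastMatrix(
        colors=colors,
        mean_grid=means / max_raw,
        sd_grid=sds / max_raw,
        max_raw=max_raw,
        duplicates=dupes,
    )


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold from first principles: the histogram split (256
    bins over the p1–p99 range) maximizing between-class variance."""
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = np.percentile(v, [1.0, 99.0])
    if hi - lo < 1e-12:
        raise DegenerateImageError("constant channel: Otsu threshold undefined")
    hist, edges = np.histogram(np.clip(v, lo, hi), bins=nbins, range=(lo, hi))
    p = hist.astype(float) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * w0 - mu) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -np.inf
    k = int(np.argmax(between))
    return float(edges[k + 1])


def foreground_mask(
    conc: ConcentrationImage,
    min_object_px: int = 64,
    min_od: float = 0.1,
) -> np.ndarray:
    """Segment chromogen-positive foreground: Otsu threshold on the DAB
    channel, then removal of connected components smaller than
    ``min_object_px`` (8-connectivity).

    The threshold is floored at ``min_od`` concentration so that blank
    images — where Otsu would split pure sensor noise — yield the
    empty-foreground signal instead of speckle.

    Raises :class:`EmptyForegroundError` when nothing survives cleaning.
    """
    try:
        thr = otsu_threshold(conc.d_chan)
    except DegenerateImageError as e:
        raise EmptyForegroundError(f"no segmentable foreground: {e}") from e
    mask = conc.d_chan >= max(thr, min_od)
    # removes components of area <= max_size, i.e. strictly below min_object_px
    mask = remove_small_objects(mask, max_size=min_object_px - 1, connectivity=2)
    if not mask.any():
        raise EmptyForegroundError(
            "no foreground objects survive Otsu + small-object cleaning"
        )
    return mask


@dataclass(frozen=True)
class ContrastReport:
    """Object-to-background contrast before/after re-staining."""

    fg_before: np.ndarray
    bg_before: np.ndarray
    fg_after: np.ndarray
    bg_after: np.ndarray
    contrast_before: float
    contrast_after: float
    improvement_pct: float


def contrast_improvement(
    original: np.ndarray, restained: np.ndarray, mask: np.ndarray
) -> ContrastReport:
    """Compare mean-foreground-vs-mean-background CIE76 contrast of two
    registered images under a shared foreground mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or mask.all():
        raise ValueError("mask must be non-empty and non-full")
    if original.shape != restained.shape or original.shape[:2] != mask.shape:
        raise ValueError("image/mask shapes do not match")
    lab_o = rgb_to_lab(original)
    lab_r = rgb_to_lab(restained)
    fg_b = lab_o[mask].mean(axis=0)
    bg_b = lab_o[~mask].mean(axis=0)
    fg_a = lab_r[mask].mean(axis=0)
    bg_a = lab_r[~mask].mean(axis=0)
    c_before = float(delta_e(fg_b, bg_b))
    c_after = float(delta_e(fg_a, bg_a))
    if c_before <= 0:
        raise ValueError("degenerate comparison: zero contrast before re-staining")
    return ContrastReport(
        fg_before=fg_b,
        bg_before=bg_b,
        fg_after=fg_a,
        bg_after=bg_a,
        contrast_before=c_before,
        contrast_after=c_after,
        improvement_pct=100.0 * (c_after / c_before - 1.0),
    )
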