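"""Bivariate color maps: extraction from images, perceptually linear design,
and map-level contrast/size metrics.

A bivariate color map is the K-by-K set of colors an image can display,
indexed by normalized (stain-1, stain-2) intensity (u, v) with the
white/background corner at (0, 0).  Designed maps are bilinear patches in
CIELAB between four corner colors — white at (0,0), black at (1,1) and two
free hues — which makes them perceptually linear: equal concentration steps
map to equal CIE76 distances along any row or column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import griddata
from scipy.ndimage import map_coordinates

from .color import delta_e, lab_to_rgb, parse_hex, rgb_to_lab, to_hex
from .errors import DegenerateImageError
from .unmix import ConcentrationImage

__all__ = [
    "BivariateColorMap",
    "MapContrastProfile",
    "design_map",
    "extract_map",
    "validate_design",
    "contrast_profile",
    "map_surface_area",
    "DEFAULT_EXTRACT_K",
    "DEFAULT_DESIGN_K",
    "DEFAULT_STATS_K",
]

#: Default grid for extraction — bins need enough member pixels.
DEFAULT_EXTRACT_K = 64
#: Default grid for designed maps used as re-staining lookup tables.
DEFAULT_DESIGN_K = 256
#: Grid used for map summary statistics (mean/SD/max distance-to-center).
#: The coarse grid weights corner and edge colors the way the reference
#: contrast figures do; the maximum is corner-attained and K-insensitive.
DEFAULT_STATS_K = 25


@dataclass
class BivariateColorMap:
    """K-by-K grid of colors over the (u, v) unit square.

    ``grid`` holds sRGB colors on the 0–255 float scale (quantized only on
    save); axis 0 is u (stain 1), axis 1 is v (stain 2), with u = v = 0 at
    the white/background corner.  ``lab_grid`` keeps the unclipped CIELAB
    surface for designed maps.  ``coverage_mask`` marks bins observed in the
    source image (extracted maps); unobserved bins were interpolated.
    """

    grid: np.ndarray
    kind: str  # "extracted" | "designed"
    corners: Optional[np.ndarray] = None  # 4x3 RGB: white, hue1, hue2, black
    norm_lo: Optional[np.ndarray] = None
    norm_hi: Optional[np.ndarray] = None
    coverage_mask: Optional[np.ndarray] = None
    lab_grid: Optional[np.ndarray] = None
    clipped_fraction: float = 0.0

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 3 or g.shape[0] != g.shape[1] or g.shape[2] != 3 or g.shape[0] < 2:
            raise ValueError("grid must be (K, K, 3) with K >= 2")
        if np.any(g < 0) or np.any(g > 255):
            raise ValueError("grid colors must lie in [0, 255]")
        self.grid = g

    @property
    def K(self) -> int:
        return self.grid.shape[0]

    def lab(self) -> np.ndarray:
        """CIELAB surface of the map (unclipped when available)."""
        if self.lab_grid is not None:
            return self.lab_grid
        return rgb_to_lab(self.grid)

    def evaluate(self, u, v, mode: str = "bilinear", space: str = "rgb") -> np.ndarray:
        """Look up colors at fractional coordinates (u, v) in [0, 1].

        Interpolation happens in CIELAB (perceptual blend), conversion to
        sRGB (with clipping) last.  ``mode='nearest'`` snaps to the nearest
        grid cell for strict lookup-table fidelity.
        """
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        shape = np.broadcast_shapes(u.shape, v.shape)
        ui = np.clip(np.broadcast_to(u, shape), 0.0, 1.0) * (self.K - 1)
        vi = np.clip(np.broadcast_to(v, shape), 0.0, 1.0) * (self.K - 1)
        order = {"bilinear": 1, "nearest": 0}[mode]
        lab_src = self.lab()
        coords = np.stack([ui.ravel(), vi.ravel()])
        out = np.stack(
            [
                map_coordinates(lab_src[..., c], coords, order=order, mode="nearest")
                for c in range(3)
            ],
            axis=-1,
        ).reshape(shape + (3,))
        if space == "lab":
            return out
        return lab_to_rgb(out)

    def to_json(self) -> str:
        obj = {
            "kind": self.kind,
            "K": self.K,
            "clipped_fraction": self.clipped_fraction,
            "corners": None
            if self.corners is None
            else [to_hex(c) for c in self.corners],
            "norm_lo": None if self.norm_lo is None else list(map(float, self.norm_lo)),
            "norm_hi": None if self.norm_hi is None else list(map(float, self.norm_hi)),
        }
        return json.dumps(obj, indent=2)


@dataclass(frozen=True)
class MapContrastProfile:
    """CIE76 distance of every map entry to the map's neutral center."""

    center: np.ndarray  # CIELAB
    distance_grid: np.ndarray
    mean: float
    sd: float
    max: float


def design_map(hue1, hue2, K: int = DEFAULT_DESIGN_K) -> BivariateColorMap:
    """Four-corner perceptually linear map: white (0,0), black (1,1),
    ``hue1`` at (1,0) on the foreground-stain axis, ``hue2`` at (0,1) on the
    background-stain axis, bilinearly interpolated in CIELAB.

    Hues may be hex strings or RGB triples (0–255).  Cells falling outside
    the sRGB gamut are clipped per channel; their fraction is recorded.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    h1 = parse_hex(hue1) if isinstance(hue1, str) else np.asarray(hue1, dtype=float)
    h2 = parse_hex(hue2) if isinstance(hue2, str) else np.asarray(hue2, dtype=float)
    white = np.array([255.0, 255.0, 255.0])
    black = np.zeros(3)
    corners_rgb = np.stack([white, h1, h2, black])
    w_l, h1_l, h2_l, b_l = (rgb_to_lab(c) for c in corners_rgb)
    u = np.linspace(0.0, 1.0, K)[:, None, None]
    v = np.linspace(0.0, 1.0, K)[None, :, None]
    lab = (1 - u) * (1 - v) * w_l + u * v * b_l + u * (1 - v) * h1_l + (1 - u) * v * h2_l
    rgb, oog = lab_to_rgb(lab, return_gamut_mask=True)
    return BivariateColorMap(
        grid=rgb,
        kind="designed",
        corners=corners_rgb,
        coverage_mask=np.ones((K, K), dtype=bool),
        lab_grid=lab,
        clipped_fraction=float(np.mean(oog)),
    )


def extract_map(
    image: np.ndarray,
    conc: Optional[ConcentrationImage] = None,
    K: int = DEFAULT_EXTRACT_K,
    uv: Optional[np.ndarray] = None,
) -> BivariateColorMap:
    """Measure the bivariate color map inherent in an image.

    Pixels are binned by their normalized stain coordinates (u, v) — from
    ``conc`` (percentile anchors p1/p99, set on demand) or from an explicit
    ``uv`` field — into a K-by-K grid.  Each observed bin's color is the
    CIELAB mean of its member pixels; unobserved bins are filled by
    scattered linear interpolation over observed bin centers, with
    nearest-neighbor fill outside their convex hull.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    image = np.asarray(image)
    if uv is None:
        if conc is None:
            raise ValueError("either conc or uv must be given")
        if conc.shape != image.shape[:2]:
            raise ValueError("concentration image not aligned with RGB image")
        if conc.norm_lo is None:
            conc.normalize()
        uv = conc.uv()
        norm_lo, norm_hi = conc.norm_lo, conc.norm_hi
    else:
        uv = np.asarray(uv, dtype=float)
        norm_lo, norm_hi = np.zeros(2), np.ones(2)

    bins = np.minimum((uv.reshape(-1, 2) * K).astype(int), K - 1)
    flat = bins[:, 0] * K + bins[:, 1]
    lab_px = rgb_to_lab(image).reshape(-1, 3)
    counts = np.bincount(flat, minlength=K * K).astype(float)
    sums = np.stack(
        [np.bincount(flat, weights=lab_px[:, c], minlength=K * K) for c in range(3)],
        axis=-1,
    )
    observed = counts > 0
    if int(observed.sum()) < 3:
        raise DegenerateImageError(
            f"only {int(observed.sum())} observed color-map bins (need >= 3); "
            "image too uniform to carry a bivariate map"
        )
    lab_bins = np.full((K * K, 3), np.nan)
    lab_bins[observed] = sums[observed] / counts[observed, None]

    centers = (np.indices((K, K)).reshape(2, -1).T + 0.5) / K
    obs_pts = centers[observed]
    missing = ~observed
    if missing.any():
        for c in range(3):
            vals = griddata(
                obs_pts, lab_bins[observed, c], centers[missing], method="linear"
            )
            nan = np.isnan(vals)
            if nan.any():
                vals[nan] = griddata(
                    obs_pts,
                    lab_bins[observed, c],
                    centers[missing][nan],
                    method="nearest",
                )
            lab_bins[missing, c] = vals
    lab_grid = lab_bins.reshape(K, K, 3)
    rgb, oog = lab_to_rgb(lab_grid, return_gamut_mask=True)
    return BivariateColorMap(
        grid=rgb,
        kind="extracted",
        norm_lo=np.asarray(norm_lo, dtype=float),
        norm_hi=np.asarray(norm_hi, dtype=float),
        coverage_mask=observed.reshape(K, K),
        clipped_fraction=float(np.mean(oog)),
    )


# CIELAB hue-angle bins (degrees) for the design rules.  "Basic hues" are
# coarse perceptual categories; achromatic colors (chroma < 10) carry none.
# The red bin extends to 45 deg: pure sRGB red (#FF0000) sits at hue angle
# ~40 deg in CIELAB and must classify as red for the red-green rule to bite.
_HUE_BINS = (
    ("red", -35.0, 45.0),
    ("orange/yellow", 45.0, 100.0),
    ("green", 100.0, 190.0),
    ("blue", 190.0, 325.0),
)
_ACHROMATIC_CHROMA = 10.0


def _hue_category(lab: np.ndarray) -> Optional[str]:
    a, b = lab[1], lab[2]
    if np.hypot(a, b) < _ACHROMATIC_CHROMA:
        return None
    ang = np.degrees(np.arctan2(b, a)) % 360.0
    for name, lo, hi in _HUE_BINS:
        if lo <= ang < hi or lo <= ang - 360.0 < hi:
            return name
    return "red"  # wrap-around of the red bin


def validate_design(corners: Sequence) -> list[str]:
    """Check four corner colors against the color-map design rules.

    Rules: at most two basic hues among the non-achromatic corners, and red
    and green must not co-occur (red–green color-vision deficiency is the
    most prevalent).  Returns a list of human-readable violations (empty
    when the design is acceptable).
    """
    if len(corners) != 4:
        raise ValueError("expected exactly 4 corner colors")
    cats = []
    for c in corners:
        rgb = parse_hex(c) if isinstance(c, str) else np.asarray(c, dtype=float)
        cat = _hue_category(rgb_to_lab(rgb))
        if cat is not None:
            cats.append(cat)
    distinct = sorted(set(cats))
    violations = []
    if len(distinct) > 2:
        violations.append(
            f"more than two basic hues among corners: {', '.join(distinct)}"
        )
    if "red" in distinct and "green" in distinct:
        violations.append("red and green hues co-occur (deuteranomaly hazard)")
    return violations


def contrast_profile(m: BivariateColorMap) -> MapContrastProfile:
    """Perceptual contrast of a map relative to its neutral center.

    The neutral element is the color at (u, v) = (0.5, 0.5); for designed
    maps the bilinear identity makes this the corner mean.  Distances are
    CIE76 over all grid entries.
    """
    lab = m.lab()
    center = m.evaluate(0.5, 0.5, space="lab")
    dist = delta_e(lab, center)
    return MapContrastProfile(
        center=np.asarray(center, dtype=float),
        distance_grid=dist,
        mean=float(dist.mean()),
        sd=float(dist.std()),
        max=float(dist.max()),
    )


def map_surface_area(m: BivariateColorMap) -> float:
    """Area of the map's image surface in CIELAB, summing the two triangles
    tiling each grid cell — the 'size' of the color map, i.e. how much of
    the perceivable color space it occupies."""
    lab = m.lab()
    p00 = lab[:-1, :-1]
    p10 = lab[1:, :-1]
    p01 = lab[:-1, 1:]
    p11 = lab[1:, 1:]
    a1 = 0.5 * np.linalg.norm(np.cross(p10 - p00, p01 - p00), axis=-1)
    a2 = 0.5 * np.linalg.norm(np.cross(p10 - p11, p01 - p11), axis=-1)
    return float(a1.sum() + a2.sum())
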