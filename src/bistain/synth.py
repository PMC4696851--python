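"""Deterministic generator of synthetic two-stain brightfield images with
per-pixel ground truth.

The forward model is the Beer–Lambert composition the deconvolution
inverts: a smooth counterstain field (hematoxylin-like, everywhere) plus
elliptical chromogen objects (DAB-like blobs), mixed along "true" stain
vectors, Gaussian noise added in OD space (physically multiplicative in
transmittance), then exponentiated and quantized to 8-bit sRGB.  The true
stain vectors are the published reference vectors rotated by a configurable
angle, emulating the per-image hue drift the unsupervised optimization is
meant to correct.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import zoom

from .color import od_to_rgb
from .maps import BivariateColorMap
from .unmix import StainBasis, reference_basis

__all__ = ["SynthParams", "SyntheticSample", "generate_ihc", "generate_from_map"]


@dataclass(frozen=True)
class SynthParams:
    """Generator settings for one synthetic H-DAB-like image.

    Defaults emulate a moderately stained 256x256 field: a counterstain
    everywhere at 0.2–0.6 OD-units concentration, a dozen chromogen blobs at
    0.4–1.0, OD noise SD 0.02, and true stain vectors rotated 5 degrees away
    from the reference.
    """

    shape: tuple = (256, 256)
    n_objects: int = 12
    radius_range: tuple = (8, 20)
    h_range: tuple = (0.2, 0.6)
    d_range: tuple = (0.4, 1.0)
    noise_sd: float = 0.02
    perturb_deg: float = 5.0
    reference: str = "ruifrok"
    seed: int = 0

    def __post_init__(self):
        if self.h_range[0] < 0 or self.d_range[0] < 0 or self.noise_sd < 0:
            raise ValueError("concentration ranges and noise SD must be nonnegative")
        if self.radius_range[0] < 1 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("invalid radius range")


@dataclass
class SyntheticSample:
    """A synthetic image with full ground truth."""

    image: np.ndarray  # uint8 RGB
    true_h: np.ndarray
    true_d: np.ndarray
    true_basis: StainBasis
    params: SynthParams

    def object_mask(self) -> np.ndarray:
        return self.true_d > 0

    def params_dict(self) -> dict:
        return asdict(self.params)


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def perturbed_basis(
    reference: StainBasis, angle_deg: float, rng: np.random.Generator
) -> StainBasis:
    """Rotate the reference stain frame by ``angle_deg`` about a random axis
    lying in the reference stain plane — the synthetic image's 'true'
    per-image hues.

    An in-plane rotation axis tilts the stain plane itself (the geometry the
    plane-fitting optimization corrects); a purely in-plane hue rotation
    would leave the plane unchanged and nothing to optimize.
    """
    if angle_deg == 0.0:
        return StainBasis(matrix=reference.matrix.copy(), label="synthetic-true")
    phi = rng.uniform(0.0, 2.0 * np.pi)
    axis = np.cos(phi) * reference.h_vec + np.sin(phi) * reference.d_vec
    rot = _rotation_matrix(axis, angle_deg)
    return StainBasis.from_stain_vectors(
        rot @ reference.h_vec, rot @ reference.d_vec, label="synthetic-true"
    )


def _smooth_field(shape, lo, hi, rng) -> np.ndarray:
    """Low-frequency random field scaled into [lo, hi]."""
    coarse = rng.normal(size=(8, 8))
    f = zoom(coarse, (shape[0] / 8, shape[1] / 8), order=3)
    fmin, fmax = f.min(), f.max()
    if fmax - fmin < 1e-12:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (f - fmin) / (fmax - fmin)


def generate_ihc(params: Optional[SynthParams] = None, **overrides) -> SyntheticSample:
    """Generate one synthetic two-stain image with ground truth.

    Keyword overrides update the default :class:`SynthParams`.  Regenerating
    with the same parameters is byte-identical.
    """
    if params is None:
        params = SynthParams(**overrides)
    elif overrides:
        params = SynthParams(**{**asdict(params), **overrides})
    rng = np.random.default_rng(params.seed)
    h, w = params.shape

    true_basis = perturbed_basis(
        reference_basis(params.reference), params.perturb_deg, rng
    )
    true_h = _smooth_field((h, w), *params.h_range, rng)
    true_d = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(params.n_objects):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry = rng.uniform(*params.radius_range)
        rx = rng.uniform(*params.radius_range)
        level = rng.uniform(*params.d_range)
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        true_d[inside] = np.maximum(true_d[inside], level)

    od = (
        true_h[..., None] * true_basis.h_vec
        + true_d[..., None] * true_basis.d_vec
    )
    if params.noise_sd > 0:
        od = od + rng.normal(0.0, params.noise_sd, size=od.shape)
    od = np.maximum(od, 0.0)
    image = np.round(np.clip(od_to_rgb(od), 0, 255)).astype(np.uint8)
    return SyntheticSample(
        image=image,
        true_h=true_h,
        true_d=true_d,
        true_basis=true_basis,
        params=params,
    )


def generate_from_map(
    m: BivariateColorMap,
    n_points: int = 4096,
    seed: int = 0,
    mode: str = "random",
) -> tuple[np.ndarray, np.ndarray]:
    """Render random or grid (u, v) samples of a color map into an image.

    Returns ``(image, uv)``: a uint8 RGB image of side ``floor(sqrt(n))``
    and the per-pixel ground-truth coordinates.  Supports the
    extract-then-compare round-trip tests.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1: cannot build an empty image")
    side = max(int(np.floor(np.sqrt(n_points))), 1)
    if mode == "random":
        rng = np.random.default_rng(seed)
        uv = rng.uniform(0.0, 1.0, size=(side, side, 2))
    elif mode == "grid":
        g = np.linspace(0.0, 1.0, side)
        uu, vv = np.meshgrid(g, g, indexing="ij")
        uv = np.stack([uu, vv], axis=-1)
    else:
        raise ValueError("mode must be 'random' or 'grid'")
    rgb = m.evaluate(uv[..., 0], uv[..., 1])
    return np.round(rgb).astype(np.uint8), uv
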