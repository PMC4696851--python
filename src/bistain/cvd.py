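"""Dichromacy simulation (deuteranopia, tritanopia) for testing color-map
robustness under impaired color vision.

Implements the Brettel–Viénot–Mollon confusion-line model: linear sRGB is
taken to LMS cone space, the missing cone's response is replaced by
projecting onto one of two half-planes anchored at the equal-white axis and
a monochromatic anchor (475/575 nm for deuteranopia, 485/660 nm for
tritanopia), and the result is taken back to sRGB with clipping.  The
projection preserves achromatic colors exactly and is idempotent.
"""

from __future__ import annotations

import numpy as np

from .maps import BivariateColorMap, contrast_profile

__all__ = ["DICHROMACY_TYPES", "simulate_dichromacy", "cvd_robustness"]

DICHROMACY_TYPES = ("deuteranopia", "tritanopia")

# Linear sRGB -> LMS and back (Vischeck implementation of Brettel 1997).
_RGB_TO_LMS = np.array(
    [
        [0.05059983, 0.08585369, 0.00952420],
        [0.01893033, 0.08925308, 0.01370054],
        [0.00292202, 0.00975732, 0.07145979],
    ]
)
_LMS_TO_RGB = np.linalg.inv(_RGB_TO_LMS)

# LMS coordinates of the monochromatic half-plane anchors.
_ANCHOR = {
    475: np.array([0.08008, 0.1579, 0.5897]),
    485: np.array([0.1284, 0.2237, 0.3636]),
    575: np.array([0.9856, 0.7325, 0.001079]),
    660: np.array([0.0914, 0.007009, 0.0]),
}
# LMS of the white axis (linear RGB = (1,1,1)); both projection half-planes
# contain this axis, so grays are invariant.
_WHITE = _RGB_TO_LMS.sum(axis=1)


def _plane_normal(anchor_nm: int) -> np.ndarray:
    return np.cross(_WHITE, _ANCHOR[anchor_nm])


def _srgb_decode(rgb01: np.ndarray) -> np.ndarray:
    return np.where(rgb01 <= 0.04045, rgb01 / 12.92, ((rgb01 + 0.055) / 1.055) ** 2.4)


def _srgb_encode(lin: np.ndarray) -> np.ndarray:
    lin = np.clip(lin, 0.0, 1.0)
    return np.where(lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1.0 / 2.4) - 0.055)


def _gamut_map(lin: np.ndarray) -> np.ndarray:
    """Bring out-of-gamut linear RGB into [0, 1] by desaturating toward the
    luminance-matched gray.

    The gray axis lies inside every confusion plane, so this mapping keeps
    projected colors on their plane and the simulation stays idempotent
    (hard per-channel clipping would not).
    """
    y = np.clip(
        0.2126 * lin[..., 0] + 0.7152 * lin[..., 1] + 0.0722 * lin[..., 2], 0.0, 1.0
    )[..., None]
    d = lin - y
    with np.errstate(divide="ignore", invalid="ignore"):
        t_hi = np.where(d > 1e-12, (1.0 - y) / d, np.inf)
        t_lo = np.where(d < -1e-12, -y / d, np.inf)
    t = np.minimum(1.0, np.min(np.minimum(t_hi, t_lo), axis=-1, keepdims=True))
    return y + t * d


def simulate_dichromacy(image: np.ndarray, kind: str) -> np.ndarray:
    """Simulate how a dichromat perceives an RGB image (0–255 scale).

    ``kind`` is ``"deuteranopia"`` (missing M cone) or ``"tritanopia"``
    (missing S cone).  uint8 input gives uint8 output; float input stays
    float (0–255).
    """
    if kind not in _SIM_SETUP:
        raise ValueError(
            f"unknown dichromacy type {kind!r}; expected one of {DICHROMACY_TYPES}"
        )
    missing, ratio_axes, planes = _SIM_SETUP[kind]
    arr = np.asarray(image)
    lin = _srgb_decode(np.clip(arr.astype(float), 0, 255) / 255.0)
    lms = lin @ _RGB_TO_LMS.T

    i, j = ratio_axes  # coordinates unchanged by the projection
    inflection = _WHITE[j] / _WHITE[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        side = lms[..., j] < inflection * lms[..., i]
    n_lo, n_hi = planes
    keep = [k for k in range(3) if k != missing]
    for normal, mask in ((n_lo, side), (n_hi, ~side)):
        num = sum(normal[k] * lms[..., k] for k in keep)
        lms[..., missing] = np.where(
            mask, -num / normal[missing], lms[..., missing]
        )

    out = _srgb_encode(_gamut_map(lms @ _LMS_TO_RGB.T)) * 255.0
    if np.issubdtype(arr.dtype, np.integer):
        return np.round(out).astype(np.uint8)
    return out


# kind -> (missing cone index, (ratio axes i, j), (plane for side, other)).
# For deuteranopia the pixel's S/L ratio against white's picks the 575 nm
# half-plane (yellow side) or the 475 nm one; for tritanopia M/L picks
# 660 nm (red side) or 485 nm.
_SIM_SETUP = {
    "deuteranopia": (1, (0, 2), (_plane_normal(575), _plane_normal(475))),
    "tritanopia": (2, (0, 1), (_plane_normal(660), _plane_normal(485))),
}


def cvd_robustness(
    map_a: BivariateColorMap, map_b: BivariateColorMap, kind: str
) -> tuple[float, float]:
    """Contrast retention of two color maps under dichromacy simulation.

    For each map the mean distance-to-center contrast is computed before and
    after simulating ``kind`` on the map's displayed (gamut-clipped) color
    grid; the returned ratios (after/before) tell how much perceptual
    contrast each map keeps for that observer.
    """
    if map_a.K != map_b.K:
        raise ValueError("maps must share the same grid resolution K")

    def retention(m: BivariateColorMap) -> float:
        shown = BivariateColorMap(grid=m.grid, kind=m.kind)
        before = contrast_profile(shown).mean
        sim_grid = simulate_dichromacy(m.grid, kind)
        sim_map = BivariateColorMap(grid=sim_grid.astype(float), kind=m.kind)
        after = contrast_profile(sim_map).mean
        return after / before if before > 0 else 1.0

    return retention(map_a), retention(map_b)
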