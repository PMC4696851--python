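"""Color-space plumbing: 8-bit sRGB, optical density and CIELAB.

All conversions are vectorized over arrays whose last axis has length 3.
RGB values are carried as floats on the 0–255 scale; quantization to 8-bit
integers happens only at file boundaries.  The CIELAB pipeline is fixed to
the sRGB primaries, D65 white point and the 2-degree standard observer,
and perceived contrast is the CIE76 Euclidean distance

    dE = sqrt((dL*)^2 + (da*)^2 + (db*)^2),

which is the metric the whole package optimizes.
"""

from __future__ import annotations

import re

import numpy as np
from skimage.color import rgb2lab

__all__ = [
    "OD_FLOOR",
    "parse_hex",
    "to_hex",
    "rgb_to_lab",
    "lab_to_rgb",
    "rgb_to_od",
    "od_to_rgb",
    "delta_e",
    "contrast_ratio",
]

#: Intensity floor applied before the logarithm of the OD transform.  A zero
#: channel would give infinite optical density; flooring at one intensity
#: step caps OD at log10(255) ~ 2.407 and keeps downstream PCA stable.
OD_FLOOR = 1.0

_HEX_RE = re.compile(r"^#?([0-9a-fA-F]{6})$")

# D65 reference white (2-degree observer), CIE 1931.
_XN, _YN, _ZN = 0.95047, 1.0, 1.08883

# Linear sRGB -> XYZ (IEC 61966-2-1, D65); the inverse is derived from the
# same constants so forward and backward conversions agree exactly.
_RGB_TO_XYZ = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)
_XYZ_TO_RGB = np.linalg.inv(_RGB_TO_XYZ)


def parse_hex(code: str) -> np.ndarray:
    """Parse ``#RRGGBB`` (case-insensitive, leading ``#`` optional) into a
    float array ``[r, g, b]`` on the 0–255 scale."""
    m = _HEX_RE.match(code.strip())
    if m is None:
        raise ValueError(f"not a valid #RRGGBB color: {code!r}")
    s = m.group(1)
    return np.array([int(s[i : i + 2], 16) for i in (0, 2, 4)], dtype=float)


def to_hex(rgb) -> str:
    """Serialize an RGB triple (0–255) to lowercase ``#rrggbb``."""
    r, g, b = (int(round(float(c))) for c in np.asarray(rgb).reshape(3))
    for c in (r, g, b):
        if not 0 <= c <= 255:
            raise ValueError(f"channel {c} outside [0, 255]")
    return f"#{r:02x}{g:02x}{b:02x}"


def rgb_to_lab(rgb) -> np.ndarray:
    """sRGB (0–255, any shape ``(..., 3)``) to CIELAB (D65, 2-degree)."""
    arr = np.asarray(rgb, dtype=float) / 255.0
    return rgb2lab(arr)


def _finv(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta, t**3, 3.0 * delta**2 * (t - 4.0 / 29.0))


def lab_to_rgb(lab, return_gamut_mask: bool = False):
    """CIELAB to sRGB on the 0–255 float scale.

    Out-of-gamut colors are clipped per channel; when ``return_gamut_mask``
    is true the (clipped RGB, boolean mask) pair is returned, the mask
    flagging pixels whose linear RGB fell outside [0, 1] before clipping.
    Clipping is reported, never fatal.
    """
    lab = np.asarray(lab, dtype=float)
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    xyz = np.stack([_XN * _finv(fx), _YN * _finv(fy), _ZN * _finv(fz)], axis=-1)
    linear = xyz @ _XYZ_TO_RGB.T
    oog = np.any((linear < -1e-9) | (linear > 1.0 + 1e-9), axis=-1)
    linear = np.clip(linear, 0.0, 1.0)
    srgb = np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(linear, 1.0 / 2.4) - 0.055,
    )
    out = np.clip(srgb, 0.0, 1.0) * 255.0
    if return_gamut_mask:
        return out, oog
    return out


def rgb_to_od(rgb) -> np.ndarray:
    """Beer–Lambert optical density per channel: ``-log10(max(I, 1) / 255)``.

    OD is 0 at the reference white (I = 255) and strictly decreasing in
    intensity; the floor bounds it at ``log10(255)``.
    """
    arr = np.asarray(rgb, dtype=float)
    return -np.log10(np.maximum(arr, OD_FLOOR) / 255.0)


def od_to_rgb(od) -> np.ndarray:
    """Inverse OD transform, ``I = 255 * 10**(-od)``, on the float scale."""
    return 255.0 * np.power(10.0, -np.asarray(od, dtype=float))


def delta_e(lab1, lab2) -> np.ndarray:
    """CIE76 color difference (Euclidean distance in CIELAB)."""
    d = np.asarray(lab1, dtype=float) - np.asarray(lab2, dtype=float)
    return np.sqrt(np.sum(d * d, axis=-1))


def contrast_ratio(c1: float, c2: float) -> float:
    """Fold change of two contrast values, ``R = C1 / C2`` (C2 > 0)."""
    if c2 <= 0.0:
        raise ValueError("contrast_ratio: denominator contrast must be positive")
    return float(c1) / float(c2)
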