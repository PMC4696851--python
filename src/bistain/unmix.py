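"""Unsupervised, PCA-optimized color deconvolution of two-stain images.

The mixing model is Beer–Lambert: each pixel's optical-density vector is a
nonnegative combination of two unit stain vectors (counterstain and
chromogen) plus a residual orthogonal to their plane.  The standard
hematoxylin–DAB reference vectors describe typical dyes, but actual hues
drift with chemistry, protocol and scanner; the optimization here fits the
best origin plane to the image's own OD pixel cloud (uncentered PCA) and
projects the reference vectors onto it, keeping their hue orientation while
minimizing the out-of-plane residual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .color import rgb_to_od
from .errors import DegenerateImageError

__all__ = [
    "StainBasis",
    "StainPlane",
    "FittedStainModel",
    "ConcentrationImage",
    "reference_basis",
    "fit_stain_plane",
    "optimize_basis",
    "fit_stain_model",
    "deconvolve",
    "residual_mse",
]

# Hematoxylin and DAB absorption coefficients per RGB channel, as measured
# by Ruifrok & Johnston for their H-DAB(-Eosin) calibration; rows are
# normalized to unit length at construction.
_RUIFROK_H = (0.18, 0.20, 0.08)
_RUIFROK_D = (0.10, 0.21, 0.29)

# The renormalized H-DAB vectors shipped with the Fiji/ImageJ
# colour-deconvolution plugin.
_FIJI_H = (0.650, 0.704, 0.286)
_FIJI_D = (0.268, 0.570, 0.776)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


@dataclass(frozen=True)
class StainBasis:
    """Three unit row vectors in OD space: two stains plus a residual.

    ``matrix`` rows are (h_vec, d_vec, res_vec).  A pixel's OD vector is
    modeled as ``od = c @ matrix`` for concentrations ``c``; the basis must
    therefore be invertible.
    """

    matrix: np.ndarray
    label: str = "user"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain basis must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("stain basis rows must have unit norm")
        if abs(np.linalg.det(m)) < 1e-8:
            raise ValueError("stain basis is singular")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @property
    def h_vec(self) -> np.ndarray:
        return self.matrix[0]

    @property
    def d_vec(self) -> np.ndarray:
        return self.matrix[1]

    @property
    def res_vec(self) -> np.ndarray:
        return self.matrix[2]

    def to_json(self) -> str:
        return json.dumps(
            {"label": self.label, "matrix": self.matrix.tolist()}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "StainBasis":
        obj = json.loads(text)
        return cls(matrix=np.array(obj["matrix"], dtype=float), label=obj["label"])

    @classmethod
    def from_stain_vectors(cls, h, d, label: str = "user") -> "StainBasis":
        """Build a basis from two stain vectors; the residual is the unit
        normal of their plane, signed for a positive determinant."""
        h = _unit(np.asarray(h, dtype=float))
        d = _unit(np.asarray(d, dtype=float))
        res = _unit(np.cross(h, d))
        m = np.stack([h, d, res])
        if np.linalg.det(m) < 0:
            m[2] = -m[2]
        return cls(matrix=m, label=label)


def reference_basis(name: str) -> StainBasis:
    """Published H-DAB reference bases: ``"ruifrok"`` (row-normalized
    Ruifrok & Johnston coefficients) or ``"fiji"`` (the Fiji plugin's
    renormalized variant)."""
    key = name.lower()
    if key == "ruifrok":
        return StainBasis.from_stain_vectors(_RUIFROK_H, _RUIFROK_D, label="ruifrok")
    if key == "fiji":
        return StainBasis.from_stain_vectors(_FIJI_H, _FIJI_D, label="fiji")
    raise ValueError(f"unknown reference basis {name!r}; expected 'ruifrok' or 'fiji'")


@dataclass(frozen=True)
class StainPlane:
    """Best origin plane through the OD pixel cloud.

    ``c1`` and ``c2`` are the first two right singular directions of the
    uncentered OD pixel matrix; ``normal`` their cross product.
    ``explained_fraction`` is the share of total OD sum-of-squares captured
    by the plane.
    """

    c1: np.ndarray
    c2: np.ndarray
    normal: np.ndarray
    explained_fraction: float
    n_pixels_used: int

    def project(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return v - np.dot(v, self.normal) * self.normal


def fit_stain_plane(
    od_pixels: np.ndarray,
    background_od_threshold: float = 0.15,
    max_pixels: int = 200_000,
    seed: int = 0,
) -> StainPlane:
    """Fit the two-stain plane to OD pixels by uncentered PCA.

    Pixels whose total OD (sum over channels) falls below
    ``background_od_threshold`` are excluded: near-white pixels carry no
    stain-direction information.  For very large images at most
    ``max_pixels`` pixels are used (deterministic subsample given ``seed``).
    The plane passes through the origin because zero stain means zero OD.

    Raises
    ------
    DegenerateImageError
        If fewer than 3 stained pixels remain or the pixel cloud has
        rank < 2 (blank or single-stain image).
    """
    od = np.asarray(od_pixels, dtype=float).reshape(-1, 3)
    keep = od.sum(axis=1) >= background_od_threshold
    od = od[keep]
    if od.shape[0] < 3:
        raise DegenerateImageError(
            f"only {od.shape[0]} non-background pixels (need >= 3) "
            f"at OD threshold {background_od_threshold}"
        )
    if od.shape[0] > max_pixels:
        rng = np.random.default_rng(seed)
        od = od[rng.choice(od.shape[0], size=max_pixels, replace=False)]
    _, s, vt = np.linalg.svd(od, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0 or s[1] <= 1e-10 * s[0]:
        rank = int(np.sum(s > 1e-10 * max(s[0], 1e-30)))
        raise DegenerateImageError(
            f"OD pixel cloud has rank {rank} < 2; cannot span a stain plane"
        )
    c1, c2 = vt[0], vt[1]
    normal = _unit(np.cross(c1, c2))
    explained = float((s[0] ** 2 + s[1] ** 2) / total)
    return StainPlane(
        c1=c1,
        c2=c2,
        normal=normal,
        explained_fraction=explained,
        n_pixels_used=int(od.shape[0]),
    )


def optimize_basis(reference: StainBasis, plane: StainPlane) -> StainBasis:
    """Project the reference stain vectors onto the fitted plane.

    The optimized stain vectors are the normalized in-plane projections of
    the reference vectors (hue orientation preserved, residual minimized);
    the residual direction is the plane normal, signed so the basis has a
    positive determinant.
    """
    rows = []
    for name, v in (("h_vec", reference.h_vec), ("d_vec", reference.d_vec)):
        p = plane.project(v)
        n = np.linalg.norm(p)
        if n < 1e-6:
            raise ValueError(
                f"reference {name} is orthogonal to the fitted plane; "
                "hue orientation unrecoverable"
            )
        rows.append(p / n)
    m = np.stack(rows + [plane.normal])
    if np.linalg.det(m) < 0:
        m[2] = -m[2]
    return StainBasis(matrix=m, label="optimized")


@dataclass(frozen=True)
class FittedStainModel:
    """Per-image unmixing model: fitted plane plus the optimized basis."""

    plane: StainPlane
    basis: StainBasis
    reference_label: str

    @property
    def explained_fraction(self) -> float:
        return self.plane.explained_fraction

    @property
    def n_pixels_used(self) -> int:
        return self.plane.n_pixels_used


def fit_stain_model(
    image: np.ndarray,
    reference: StainBasis | str = "ruifrok",
    background_od_threshold: float = 0.15,
    max_pixels: int = 200_000,
    seed: int = 0,
) -> FittedStainModel:
    """Fit the stain plane of an RGB image and optimize the reference basis
    against it (the unsupervised deconvolution pipeline in one call)."""
    if isinstance(reference, str):
        reference = reference_basis(reference)
    od = rgb_to_od(image)
    plane = fit_stain_plane(
        od,
        background_od_threshold=background_od_threshold,
        max_pixels=max_pixels,
        seed=seed,
    )
    basis = optimize_basis(reference, plane)
    return FittedStainModel(plane=plane, basis=basis, reference_label=reference.label)


@dataclass
class ConcentrationImage:
    """Per-pixel stain concentrations in OD units along each basis vector.

    Raw (possibly negative) values are kept so the residual honestly
    measures unmixing error; clamping to >= 0 happens only when mapping to
    color-map coordinates.  ``norm_lo``/``norm_hi`` are the per-stain
    percentile anchors used to normalize concentrations onto [0, 1]^2; they
    are unset until :meth:`normalize` is called.
    """

    h_chan: np.ndarray
    d_chan: np.ndarray
    res_chan: np.ndarray
    basis: StainBasis
    norm_lo: Optional[np.ndarray] = field(default=None)
    norm_hi: Optional[np.ndarray] = field(default=None)

    @property
    def shape(self) -> tuple:
        return self.h_chan.shape

    def normalize(self, p_lo: float = 1.0, p_hi: float = 99.0) -> "ConcentrationImage":
        """Set percentile normalization anchors from the clamped channels.

        Robust p1/p99 anchors ignore specular/dust outliers.  Raises
        :class:`DegenerateImageError` when a channel is constant.
        """
        lo, hi = [], []
        for chan in (self.d_chan, self.h_chan):
            c = np.maximum(chan, 0.0)
            a, b = np.percentile(c, [p_lo, p_hi])
            if b - a < 1e-9:
                raise DegenerateImageError(
                    "constant stain channel: cannot set normalization anchors"
                )
            lo.append(a)
            hi.append(b)
        self.norm_lo = np.array(lo)
        self.norm_hi = np.array(hi)
        return self

    def uv(self) -> np.ndarray:
        """Clamped, anchor-normalized (u, v) coordinates in [0, 1]^2.

        ``u`` is the chromogen (foreground, DAB) axis and ``v`` the
        counterstain (background, hematoxylin) axis, matching the
        orientation of designed maps (foreground hue at (1, 0)).
        Out-of-range concentrations clamp to the interval ends.
        """
        if self.norm_lo is None:
            raise ValueError("normalization anchors unset; call normalize() first")
        out = np.empty(self.shape + (2,), dtype=float)
        for k, chan in enumerate((self.d_chan, self.h_chan)):
            c = np.maximum(chan, 0.0)
            out[..., k] = (c - self.norm_lo[k]) / (self.norm_hi[k] - self.norm_lo[k])
        return np.clip(out, 0.0, 1.0)


def deconvolve(image: np.ndarray, basis: StainBasis) -> ConcentrationImage:
    """Solve the linear OD mixing model per pixel.

    For each pixel, ``od = c_h*h + c_d*d + c_res*res`` is inverted exactly;
    re-composing ``c @ M`` reproduces the OD image to machine precision.
    """
    od = rgb_to_od(image)
    conc = od @ np.linalg.inv(basis.matrix)
    return ConcentrationImage(
        h_chan=conc[..., 0],
        d_chan=conc[..., 1],
        res_chan=conc[..., 2],
        basis=basis,
    )


def residual_mse(conc: ConcentrationImage) -> float:
    """Mean squared residual-channel value over all pixels — the scalar
    figure of merit for unmixing quality."""
    return float(np.mean(conc.res_chan**2))
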