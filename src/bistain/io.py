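"""Image and report I/O shared by the command-line tools.

Reads PNG/TIFF/JPEG into 8-bit RGB (grayscale promoted, alpha dropped with
a warning); writes PNG/TIFF.  All math elsewhere is double precision —
8-bit quantization happens here, at the file boundary.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image"]


def read_image(path) -> np.ndarray:
    """Read an image file as an (H, W, 3) uint8 RGB array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.floating):
        raise ValueError(
            f"{path}: floating-point images are not supported; expected 8-bit"
        )
    if arr.dtype != np.uint8:
        if arr.dtype == np.uint16:
            arr = (arr // 257).astype(np.uint8)
        else:
            raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        warnings.warn(f"{path}: dropping alpha channel", stacklevel=2)
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: cannot interpret shape {arr.shape} as RGB")
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Write an (H, W, 3) uint8 RGB array to PNG/TIFF."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("write_image expects uint8 data (quantize at the boundary)")
    iio.imwrite(Path(path), image)
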