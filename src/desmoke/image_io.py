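"""8-bit raster I/O with an explicit [0, 1] float convention.

Every image inside the package is a ``float64`` array of shape ``(H, W, 3)``
with values in ``[0, 1]`` and channels ordered R, G, B.  Quantization to
8 bits happens only at the file boundary (``round(v * 255)``), so a PNG
round trip perturbs each pixel by at most ``1/510``.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = ["ImageFormatError", "read_image", "write_image", "validate_image"]


class ImageFormatError(ValueError):
    """Raised for unsupported bit depths or channel layouts."""


def validate_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Check that ``img`` is a finite (H, W, 3) float field in [0, 1]."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{name} must have shape (H, W, 3), got {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must have positive height and width")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"{name} values must lie in [0, 1]")
    return arr


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit PNG/JPEG as an (H, W, 3) float array in [0, 1].

    Grayscale images are promoted to RGB by channel replication; an alpha
    channel, if present, is dropped.
    """
    raw = iio.imread(path)
    if raw.dtype != np.uint8:
        raise ImageFormatError(
            f"only 8-bit images are supported, got dtype {raw.dtype} in {path}"
        )
    if raw.ndim == 2:
        raw = np.repeat(raw[:, :, None], 3, axis=2)
    elif raw.ndim == 3:
        if raw.shape[2] == 2:  # gray + alpha
            raw = np.repeat(raw[:, :, :1], 3, axis=2)
        elif raw.shape[2] == 4:
            raw = raw[:, :, :3]
        elif raw.shape[2] != 3:
            raise ImageFormatError(
                f"unsupported channel count {raw.shape[2]} in {path}"
            )
    else:
        raise ImageFormatError(f"unsupported image rank {raw.ndim} in {path}")
    return raw.astype(np.float64) / 255.0


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0, 1] float image as 8-bit, clipping then rounding."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"image must have shape (H, W, 3), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    quantized = np.rint(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(path, quantized)
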