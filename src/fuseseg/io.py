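"""Reading and writing images on the internal [0, 255] float scale."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

# Rec. 709 / sRGB luminance coefficients
_LUMA = np.array([0.2125, 0.7154, 0.0721])


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF (8- or 16-bit) as a [0, 255] float grid.

    RGB inputs are converted by luminance; 16-bit values are divided by
    257 so full scale maps to 255.0 exactly.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise IOError(f"unsupported image layout {arr.shape} in {path}")
    if raw.dtype == np.uint16:
        return arr.astype(np.float64) / 257.0
    return arr.astype(np.float64)


def write_mask(path: str | Path, mask) -> None:
    """Write a binary mask as an 8-bit PNG (foreground 255)."""
    mask = np.asarray(mask).astype(bool)
    iio.imwrite(Path(path), mask.astype(np.uint8) * 255)


def write_overlay(path: str | Path, image, contours) -> None:
    """Write the image with the zero-level contour burned in in red."""
    img = np.clip(np.round(np.asarray(image, dtype=np.float64)), 0, 255).astype(np.uint8)
    rgb = np.stack([img, img, img], axis=-1)
    for poly in contours:
        rr = np.clip(np.round(poly[:, 0]).astype(int), 0, img.shape[0] - 1)
        cc = np.clip(np.round(poly[:, 1]).astype(int), 0, img.shape[1] - 1)
        rgb[rr, cc] = (255, 0, 0)
    iio.imwrite(Path(path), rgb)
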