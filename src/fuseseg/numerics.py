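"""Finite-difference and filtering primitives shared by all evolution terms.

All operators act on 2-D double-precision grids, return a grid of the same
shape, and use replicate (Neumann) boundary handling, so the normal
derivative at the image border is zero under central differencing.
Coordinate convention: row-major, pixel-centered, 0-based; ``x`` is the
column index and ``y`` the row index, with unit pixel spacing.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

#: Floor applied to |grad phi| wherever it appears in a denominator.  The
#: curvature and unit-normal fields divide by the gradient magnitude, which
#: vanishes on flat plateaus of the level-set field.
GRAD_FLOOR = 1e-10


def _as_grid(field) -> np.ndarray:
    arr = np.asarray(field, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D grid, got shape {arr.shape}")
    return arr


def neumann_extend(field) -> np.ndarray:
    """Pad ``field`` by one replicated pixel on every side.

    The replicated border makes central differences at the original border
    see a zero normal derivative, which is the discrete Neumann condition
    applied at every iteration of the contour evolution.
    """
    arr = _as_grid(field)
    return np.pad(arr, 1, mode="edge")


def grad_central(field) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient ``(gx, gy)`` with Neumann boundaries.

    ``gx`` differentiates along columns (the x axis), ``gy`` along rows.
    """
    ext = neumann_extend(field)
    gx = (ext[1:-1, 2:] - ext[1:-1, :-2]) / 2.0
    gy = (ext[2:, 1:-1] - ext[:-2, 1:-1]) / 2.0
    return gx, gy


def divergence(px, py) -> np.ndarray:
    """Discrete divergence d(px)/dx + d(py)/dy of a vector field."""
    gx, _ = grad_central(px)
    _, gy = grad_central(py)
    return gx + gy


def laplacian(field) -> np.ndarray:
    """5-point stencil Laplacian with replicated boundaries."""
    ext = neumann_extend(field)
    return (
        ext[1:-1, 2:]
        + ext[1:-1, :-2]
        + ext[2:, 1:-1]
        + ext[:-2, 1:-1]
        - 4.0 * ext[1:-1, 1:-1]
    )


def curvature(phi, grad_floor: float = GRAD_FLOOR) -> np.ndarray:
    """Curvature ``div(grad phi / |grad phi|)`` of the level-set field.

    The gradient magnitude in the denominator is floored at ``grad_floor``,
    so the output stays finite (magnitude O(1/grad_floor)) on flat fields.
    For a signed distance function of a circle of radius R the value near
    the zero level set approaches 1/R.
    """
    gx, gy = grad_central(phi)
    norm = np.maximum(np.sqrt(gx * gx + gy * gy), grad_floor)
    return divergence(gx / norm, gy / norm)


def gaussian_blur(field, sigma: float) -> np.ndarray:
    """Gaussian convolution with replicate padding.

    The kernel is truncated at an odd window covering +-4*sigma (rounded
    up), leaving under 1e-4 of the mass outside the window; a constant
    field is preserved exactly because the truncated kernel is
    renormalised.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    arr = _as_grid(field)
    radius = math.ceil(4.0 * sigma)
    return ndimage.gaussian_filter(arr, sigma=sigma, mode="nearest", radius=radius)


def local_std_3x3(image) -> np.ndarray:
    """Per-pixel population standard deviation over a 3x3 neighborhood.

    The window is replicate-padded at the border and the divisor is the
    window size (population convention), so a constant image maps to zero
    everywhere.
    """
    arr = _as_grid(image)
    mean = ndimage.uniform_filter(arr, size=3, mode="nearest")
    mean_sq = ndimage.uniform_filter(arr * arr, size=3, mode="nearest")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return np.sqrt(var)
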