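"""Local binary fitting (LBF) region model.

The LBF energy fits two spatially varying intensity functions through
Gaussian-window weighted means -- ``f1`` approximating the image outside
the contour (phi > 0) and ``f2`` inside (phi < 0) -- which makes the model
robust to smooth multiplicative intensity inhomogeneity that defeats
global two-phase statistics:

    E = lambda1 * sum_x e1(x) H_eps(phi(x))
      + lambda2 * sum_x e2(x) (1 - H_eps(phi(x)))
      + v_len * sum_x delta_eps(phi) |grad phi|
      + mu * 0.5 * sum_x (|grad phi| - 1)^2

with local fitting errors ``e_i(x) = sum_y k_sigma(y - x) (I(x) - f_i(y))^2``
and the arctan-regularised Heaviside ``H_eps``.  The gradient flow adds a
length term and a distance-regularization penalty:

    dphi = { -delta_eps2(phi) (lambda1 e1 - lambda2 e2)
             + v_len * delta_eps2(phi) * div(grad phi/|grad phi|)
             + mu * [Lap(phi) - div(grad phi/|grad phi|)] } * dt
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adpls import dirac_eps
from .numerics import _as_grid, curvature, gaussian_blur, grad_central, laplacian

#: Floor for the smoothed Heaviside mass in the fitting-function
#: denominators; below it the local fit falls back to the plain smoothed
#: intensity (the Dirac factor is ~0 at such pixels, so the choice is inert).
_MASS_FLOOR = 1e-10


@dataclass(frozen=True)
class LbfParams:
    """Tunables of the LBF flow.

    lambda1, lambda2
        Weights of the outside / inside fitting errors; image dependent,
        equal by default.
    v_len
        Weight of the contour-length term; scales with the squared
        intensity range (default 0.002 * 255^2).
    mu
        Weight of the signed-distance penalty; explicit stepping requires
        ``mu * dt_lbf <= 0.25``.
    sigma_lbf
        Std (pixels) of the Gaussian localisation kernel of the fits.
    eps2
        Width of the regularised Heaviside/Dirac pair.
    dt_lbf
        Time step of the LBF flow.
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    v_len: float = 0.002 * 255.0 * 255.0
    mu: float = 1.0
    sigma_lbf: float = 3.0
    eps2: float = 1.0
    dt_lbf: float = 0.1

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "v_len", "mu", "sigma_lbf", "eps2", "dt_lbf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class FittingFields:
    """Local fits and fitting errors of the LBF model at a given phi."""

    f1: np.ndarray  # local fit of the intensity outside the contour
    f2: np.ndarray  # local fit of the intensity inside the contour
    e1: np.ndarray
    e2: np.ndarray


def heaviside_eps(x, eps: float):
    """Arctan-regularised Heaviside ``0.5 * (1 + (2/pi) arctan(x/eps))``.

    Strictly increasing with values in (0, 1); its derivative is
    :func:`fuseseg.adpls.dirac_eps` with the same width.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    x = np.asarray(x, dtype=np.float64)
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(x / eps))


def fitting_functions(image, phi, sigma_lbf: float, eps2: float) -> tuple[np.ndarray, np.ndarray]:
    """Local weighted-mean fits ``(f1, f2)`` outside/inside the contour.

    ``f1 = k*(H(phi) I) / k*H(phi)`` and ``f2`` with ``1 - H(phi)``; both
    are convex local averages of the image so they stay within its
    intensity range.  Where a side's smoothed mass underflows (deep inside
    the other region) the fit falls back to the smoothed intensity.
    """
    image = _as_grid(image)
    phi = _as_grid(phi)
    if image.shape != phi.shape:
        raise ValueError(f"image shape {image.shape} != phi shape {phi.shape}")
    h = heaviside_eps(phi, eps2)
    smoothed_image = gaussian_blur(image, sigma_lbf)

    def _fit(weight: np.ndarray) -> np.ndarray:
        mass = gaussian_blur(weight, sigma_lbf)
        num = gaussian_blur(weight * image, sigma_lbf)
        safe = mass > _MASS_FLOOR
        return np.where(safe, num / np.where(safe, mass, 1.0), smoothed_image)

    return _fit(h), _fit(1.0 - h)


def fitting_errors(image, f1, f2, sigma_lbf: float) -> tuple[np.ndarray, np.ndarray]:
    """Local fitting errors ``e_i(x) = sum_y k(y-x) (I(x) - f_i(y))^2``.

    Expanded as ``I^2 (k*1) - 2 I (k*f_i) + k*(f_i^2)`` so each term is a
    single Gaussian convolution; tiny negative excursions from cancellation
    are clipped at zero.
    """
    image = _as_grid(image)
    kernel_mass = gaussian_blur(np.ones_like(image), sigma_lbf)

    def _err(f: np.ndarray) -> np.ndarray:
        e = image * image * kernel_mass - 2.0 * image * gaussian_blur(f, sigma_lbf) + gaussian_blur(f * f, sigma_lbf)
        return np.maximum(e, 0.0)

    return _err(np.asarray(f1, dtype=np.float64)), _err(np.asarray(f2, dtype=np.float64))


def compute_fitting(image, phi, p: LbfParams) -> FittingFields:
    """Fits and errors for the current level-set field."""
    f1, f2 = fitting_functions(image, phi, p.sigma_lbf, p.eps2)
    e1, e2 = fitting_errors(image, f1, f2, p.sigma_lbf)
    return FittingFields(f1=f1, f2=f2, e1=e1, e2=e2)


def lbf_step(phi, image, p: LbfParams) -> np.ndarray:
    """One LBF increment (already multiplied by ``dt_lbf``).

    The fitting fields are recomputed from the current phi on every call.
    """
    phi = _as_grid(phi)
    image = _as_grid(image)
    if image.shape != phi.shape:
        raise ValueError(f"image shape {image.shape} != phi shape {phi.shape}")
    fit = compute_fitting(image, phi, p)
    delta = dirac_eps(phi, p.eps2)
    kappa = curvature(phi)
    data = -delta * (p.lambda1 * fit.e1 - p.lambda2 * fit.e2)
    length = p.v_len * delta * kappa
    penalty = p.mu * (laplacian(phi) - kappa)
    return (data + length + penalty) * p.dt_lbf


def lbf_energy(phi, image, p: LbfParams) -> float:
    """Discretised LBF energy at the current phi (unit pixel area)."""
    phi = _as_grid(phi)
    image = _as_grid(image)
    if image.shape != phi.shape:
        raise ValueError(f"image shape {image.shape} != phi shape {phi.shape}")
    fit = compute_fitting(image, phi, p)
    h = heaviside_eps(phi, p.eps2)
    gx, gy = grad_central(phi)
    grad_mag = np.sqrt(gx * gx + gy * gy)
    data = float(np.sum(p.lambda1 * fit.e1 * h + p.lambda2 * fit.e2 * (1.0 - h)))
    length = float(np.sum(dirac_eps(phi, p.eps2) * grad_mag))
    penalty = float(0.5 * np.sum((grad_mag - 1.0) ** 2))
    return data + p.v_len * length + p.mu * penalty
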