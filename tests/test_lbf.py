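"""Local binary fitting: Heaviside, fits, errors, update and energy."""

import numpy as np
import pytest

from fuseseg.adpls import dirac_eps
from fuseseg.fusion import initialize_phi
from fuseseg.lbf import (
    LbfParams,
    compute_fitting,
    fitting_errors,
    fitting_functions,
    heaviside_eps,
    lbf_energy,
    lbf_step,
)
from fuseseg.numerics import curvature, laplacian
from tests.conftest import circle_sdf, two_phase
from tests.test_numerics import gaussian_kernel_2d


class TestHeaviside:
    def test_zero_maps_to_half(self):
        assert heaviside_eps(0.0, 1.0) == pytest.approx(0.5)

    def test_complement_symmetry(self, rng):
        x = rng.normal(scale=10.0, size=100)
        assert np.allclose(heaviside_eps(x, 1.0) + heaviside_eps(-x, 1.0), 1.0)

    def test_saturation(self):
        assert heaviside_eps(1e6 * 1.0, 1.0) > 0.999

    def test_strictly_increasing(self):
        x = np.linspace(-5, 5, 101)
        h = heaviside_eps(x, 1.0)
        assert (np.diff(h) > 0).all()

    def test_invalid_eps(self):
        with pytest.raises(ValueError):
            heaviside_eps(0.0, -1.0)


class TestFittingFunctions:
    def test_constant_image(self):
        img = np.full((16, 16), 88.0)
        phi = circle_sdf(16, 5.0)
        f1, f2 = fitting_functions(img, phi, sigma_lbf=3.0, eps2=1.0)
        assert np.allclose(f1, 88.0) and np.allclose(f2, 88.0)

    def test_two_phase_far_field_values(self):
        n = 96
        img = two_phase(n, 24.0, fg=60.0, bg=180.0)  # inside value 60
        phi = circle_sdf(n, 24.0)  # negative inside, matching the disk
        f1, f2 = fitting_functions(img, phi, sigma_lbf=3.0, eps2=1.0)
        far = np.abs(phi) >= 4 * 3.0
        inside_far = far & (phi < 0)
        outside_far = far & (phi > 0)
        assert np.abs(f2[inside_far] - 60.0).max() < 1.0
        assert np.abs(f1[outside_far] - 180.0).max() < 1.0

    def test_sign_flip_swaps_fits(self, rng):
        img = rng.uniform(0, 255, (20, 20))
        phi = rng.normal(scale=2.0, size=(20, 20))
        f1, f2 = fitting_functions(img, phi, 3.0, 1.0)
        f1n, f2n = fitting_functions(img, -phi, 3.0, 1.0)
        assert np.allclose(f1, f2n, atol=1e-9)
        assert np.allclose(f2, f1n, atol=1e-9)

    def test_fits_within_intensity_range(self, rng):
        img = rng.uniform(10, 200, (24, 24))
        phi = rng.normal(scale=3.0, size=(24, 24))
        f1, f2 = fitting_functions(img, phi, 3.0, 1.0)
        for f in (f1, f2):
            assert f.min() >= img.min() - 1e-6
            assert f.max() <= img.max() + 1e-6


class TestFittingErrors:
    def test_constant_image_zero_error(self):
        img = np.full((12, 12), 33.0)
        phi = circle_sdf(12, 4.0)
        fit = compute_fitting(img, phi, LbfParams())
        assert np.allclose(fit.e1, 0.0, atol=1e-8)
        assert np.allclose(fit.e2, 0.0, atol=1e-8)

    def test_matches_double_loop_oracle(self, rng):
        """e_i(x) = sum_y k(y-x) (I(x) - f_i(y))^2 by direct summation on 9x9."""
        img = rng.uniform(0, 255, (9, 9))
        phi = rng.normal(scale=2.0, size=(9, 9))
        sigma = 3.0
        f1, f2 = fitting_functions(img, phi, sigma, 1.0)
        e1, e2 = fitting_errors(img, f1, f2, sigma)
        kern = gaussian_kernel_2d(sigma)
        r = kern.shape[0] // 2
        for f, e in ((f1, e1), (f2, e2)):
            for i in range(9):
                for j in range(9):
                    total = 0.0
                    for di in range(-r, r + 1):
                        for dj in range(-r, r + 1):
                            yi = min(max(i + di, 0), 8)
                            yj = min(max(j + dj, 0), 8)
                            total += kern[di + r, dj + r] * (img[i, j] - f[yi, yj]) ** 2
                    assert e[i, j] == pytest.approx(total, abs=1e-6)

    def test_nonnegative(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        phi = rng.normal(scale=2.0, size=(16, 16))
        fit = compute_fitting(img, phi, LbfParams())
        assert (fit.e1 >= 0).all() and (fit.e2 >= 0).all()


class TestLbfStep:
    def test_constant_image_reduces_to_regularization(self):
        img = np.full((20, 20), 55.0)
        phi = initialize_phi(img.shape, (6, 6, 14, 14))
        p = LbfParams()
        step = lbf_step(phi, img, p)
        kappa = curvature(phi)
        expected = (
            p.v_len * dirac_eps(phi, p.eps2) * kappa + p.mu * (laplacian(phi) - kappa)
        ) * p.dt_lbf
        assert np.allclose(step, expected, atol=1e-6)

    def test_term_decomposition_oracle(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        phi = rng.normal(scale=2.0, size=(16, 16))
        p = LbfParams(lambda1=0.8, lambda2=1.3)
        fit = compute_fitting(img, phi, p)
        delta = dirac_eps(phi, p.eps2)
        kappa = curvature(phi)
        expected = (
            -delta * (p.lambda1 * fit.e1 - p.lambda2 * fit.e2)
            + p.v_len * delta * kappa
            + p.mu * (laplacian(phi) - kappa)
        ) * p.dt_lbf
        assert np.allclose(lbf_step(phi, img, p), expected, atol=1e-12)

    def test_data_term_cancels_when_balanced(self):
        # lambda1 = lambda2 and e1 = e2 (constant image) -> pure regularization,
        # independent of the lambdas
        img = np.full((14, 14), 120.0)
        phi = initialize_phi(img.shape, (4, 4, 10, 10))
        s1 = lbf_step(phi, img, LbfParams(lambda1=1.0, lambda2=1.0))
        s2 = lbf_step(phi, img, LbfParams(lambda1=5.0, lambda2=5.0))
        assert np.allclose(s1, s2, atol=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lbf_step(np.zeros((5, 5)), np.zeros((6, 6)), LbfParams())


class TestLbfEnergy:
    def test_constant_image_sdf_energy_is_length_only(self):
        n = 41
        img = np.full((n, n), 77.0)
        phi = circle_sdf(n, 12.0)
        p = LbfParams()
        e = lbf_energy(phi, img, p)
        # data = 0 (perfect fit), penalty ~ 0 (|grad phi| = 1); remaining term
        # is v_len * sum(delta |grad phi|) ~ v_len * circumference
        length = float(np.sum(dirac_eps(phi, p.eps2)))
        assert e == pytest.approx(p.v_len * length, rel=0.05)

    def test_descent_over_twenty_steps(self):
        img = two_phase(64, 16.0)
        phi = initialize_phi(img.shape, (20, 20, 44, 44))
        p = LbfParams()
        prev = lbf_energy(phi, img, p)
        for _ in range(20):
            phi = phi + lbf_step(phi, img, p)
            cur = lbf_energy(phi, img, p)
            assert cur <= prev * (1 + 1e-6)
            prev = cur

    def test_data_portion_linear_in_lambdas(self):
        img = two_phase(32, 8.0)
        phi = circle_sdf(32, 8.0) + 1.5  # misplaced contour -> nonzero data term
        reg_only = lbf_energy(phi, np.full_like(img, img.mean()), LbfParams())
        # the regularization part does not depend on the image values
        e1 = lbf_energy(phi, img, LbfParams(lambda1=1.0, lambda2=1.0))
        e2 = lbf_energy(phi, img, LbfParams(lambda1=2.0, lambda2=2.0))
        assert e2 - reg_only == pytest.approx(2.0 * (e1 - reg_only), rel=1e-9)


def test_data_term_descends_alone():
    """The pure data force moves phi downhill on the data part of the energy
    at a small time step."""
    img = two_phase(32, 8.0)
    phi = initialize_phi(img.shape, (10, 10, 22, 22))
    p = LbfParams()

    def data_energy(f):
        fit = compute_fitting(img, f, p)
        h = heaviside_eps(f, p.eps2)
        return float(np.sum(p.lambda1 * fit.e1 * h + p.lambda2 * fit.e2 * (1 - h)))

    prev = data_energy(phi)
    for _ in range(10):
        fit = compute_fitting(img, phi, p)
        phi = phi - dirac_eps(phi, p.eps2) * (p.lambda1 * fit.e1 - p.lambda2 * fit.e2) * 0.01
        cur = data_energy(phi)
        assert cur <= prev * (1 + 1e-9)
        prev = cur
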