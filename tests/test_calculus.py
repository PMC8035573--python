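"""Forward differences, boundary bookkeeping, and exact inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dpca
from dpca.calculus import BoundaryRecord, boundary_smooth, integrate, partial_derivative
from tests.conftest import COMBINED_COEFFS


def _image(values):
    return dpca.phase_image_from_array(np.asarray(values, dtype=float))


def _brute_force_diff(arr, axis, order):
    # independent oracle: repeated elementwise subtraction in python loops
    arr = np.asarray(arr, dtype=float)
    for _ in range(order):
        if axis == "x":
            arr = np.array(
                [[arr[r, c + 1] - arr[r, c] for c in range(arr.shape[1] - 1)]
                 for r in range(arr.shape[0])]
            )
        else:
            arr = np.array(
                [[arr[r + 1, c] - arr[r, c] for c in range(arr.shape[1])]
                 for r in range(arr.shape[0] - 1)]
            )
    return arr


class TestPartialDerivative:
    def test_constant_image_first_difference_is_zero(self):
        d, rec = partial_derivative(_image(np.full((8, 10), 3.3)), "x", 1)
        np.testing.assert_array_equal(d, 0.0)
        assert rec.order == 1 and len(rec.saved) == 1
        np.testing.assert_allclose(rec.saved[0], 3.3)

    @pytest.mark.parametrize("j", [1, 2, 3])
    def test_factorial_identity_on_integer_grid(self, j):
        # j-fold forward difference of x**j is exactly j!
        g = dpca.GridConvention(6, 20)
        x, y = g.coords()
        phi = _image((x**j) * np.ones_like(y))
        d, _ = partial_derivative(phi, "x", j)
        np.testing.assert_array_equal(d, float(math.factorial(j)))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(7, 9))
        for axis in ("x", "y"):
            for order in (1, 2):
                d, _ = partial_derivative(_image(arr), axis, order)
                np.testing.assert_allclose(
                    d, _brute_force_diff(arr, axis, order), atol=1e-12
                )

    def test_cross_term_becomes_non_cross(self):
        # second x-difference of P*x^2*y is the separable surface 2P*y
        g = dpca.GridConvention(64, 64)
        phi = dpca.eval_polynomial_aberration(dpca.AberrationSpec({(2, 1): 1e-8}), g)
        d, _ = partial_derivative(phi, "x", 2)
        y = np.arange(64.0)[:, None]
        np.testing.assert_allclose(d, 2e-8 * y * np.ones((1, 62)), atol=1e-18)
        fit = dpca.fit_polynomial_surface_2d(dpca.phase_image_from_array(d), K=2, L=1)
        assert not fit.cross_terms() or max(
            abs(v) for v in fit.cross_terms().values()
        ) < 1e-18

    def test_wrapped_input_rejected(self):
        g = dpca.GridConvention(8, 8)
        w = dpca.PhaseImage(np.zeros(g.shape), wrapped=True, grid=g)
        with pytest.raises(ValueError):
            partial_derivative(w, "x", 1)

    def test_shrinking_extent_tracked(self):
        d, rec = partial_derivative(_image(np.zeros((10, 12))), "y", 3)
        assert d.shape == (7, 12)
        assert [v.shape for v in rec.saved] == [(12,)] * 3


class TestIntegrate:
    def test_zero_derivative_with_constant_boundary(self):
        rec = BoundaryRecord(axis="x", order=1, saved=(np.full(5, 2.0),))
        out = integrate(np.zeros((5, 9)), rec)
        np.testing.assert_array_equal(out.values, 2.0)

    def test_constant_surface_zero_boundary_gives_ramp(self):
        rec = BoundaryRecord(axis="x", order=1, saved=(np.zeros(4),))
        out = integrate(np.full((4, 7), 0.5), rec)
        expected = np.broadcast_to(0.5 * np.arange(8.0)[None, :], (4, 8))
        np.testing.assert_allclose(out.values, expected)

    @pytest.mark.parametrize("axis,order", [("x", 1), ("x", 2), ("y", 1), ("y", 3)])
    def test_exact_round_trip(self, axis, order, combined_aberration):
        d, rec = partial_derivative(combined_aberration, axis, order)
        back = integrate(d, rec)
        assert np.abs(back.values - combined_aberration.values).max() < 1e-9

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_round_trip_on_random_polynomial_surfaces(self, seed):
        rng = np.random.default_rng(seed)
        g = dpca.GridConvention(24, 24)
        coeffs = {
            (int(k), int(l)): rng.normal() * 10.0 ** (-2 * (k + l))
            for k, l in rng.integers(0, 4, size=(3, 2))
        }
        phi = dpca.eval_polynomial_aberration(dpca.AberrationSpec(coeffs), g)
        axis = "x" if rng.integers(2) else "y"
        order = int(rng.integers(1, 4))
        d, rec = partial_derivative(phi, axis, order)
        back = integrate(d, rec)
        assert np.abs(back.values - phi.values).max() < 1e-9

    def test_mismatched_boundary_rejected(self):
        rec = BoundaryRecord(axis="x", order=1, saved=(np.zeros(6),))
        with pytest.raises(ValueError):
            integrate(np.zeros((5, 9)), rec)

    def test_record_json_round_trip(self):
        rec = BoundaryRecord(axis="y", order=2, saved=(np.arange(4.0), np.ones(4)))
        again = BoundaryRecord.from_json(rec.to_json())
        assert again.axis == "y" and again.order == 2
        for a, b in zip(again.saved, rec.saved):
            np.testing.assert_array_equal(a, b)


class TestBoundarySmooth:
    def test_polynomial_surface_unchanged(self):
        g = dpca.GridConvention(64, 64)
        phi = dpca.eval_polynomial_aberration(
            dpca.AberrationSpec({(2, 0): 1e-4, (0, 3): 1e-6}), g
        )
        out = boundary_smooth(phi, j=2, fit_degree=5)
        assert np.abs(out.values - phi.values).max() < 1e-9

    def test_noisy_first_row_is_denoised(self):
        g = dpca.GridConvention(64, 256)
        x, y = g.coords()
        truth = 1e-2 * x * np.ones_like(y)
        rng = np.random.default_rng(11)
        noisy = truth.copy()
        sigma = 0.2
        noisy[0, :] += rng.normal(0, sigma, g.width)
        out = boundary_smooth(dpca.phase_image_from_array(noisy), j=1, fit_degree=1)
        resid = out.values[0, :] - truth[0, :]
        assert np.std(resid) < sigma / 2  # OLS line fit shrinks noise ~sqrt(2/n)

    def test_interior_bit_identical(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(32, 32))
        out = boundary_smooth(_image(arr), j=2, fit_degree=3)
        np.testing.assert_array_equal(out.values[2:, 2:], arr[2:, 2:])

    def test_j_too_large_rejected(self):
        with pytest.raises(ValueError):
            boundary_smooth(_image(np.zeros((4, 4))), j=4, fit_degree=1)
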