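"""Unit and property tests for the synthetic phase generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dpca
from dpca.synthgen import _GLYPHS


class TestPolynomialAberration:
    def test_pure_y_term_has_zero_first_row(self):
        g = dpca.GridConvention(32, 32)
        surf = dpca.eval_polynomial_aberration(dpca.AberrationSpec({(0, 1): 1e-2}), g)
        assert np.all(surf.values[0, :] == 0.0)
        assert not surf.wrapped

    def test_monomial_scalar_evaluation(self):
        # independent scalar check of P * x**2 * y at (x=100, y=200)
        g = dpca.GridConvention(256, 256)
        surf = dpca.eval_polynomial_aberration(dpca.AberrationSpec({(2, 1): 1e-8}), g)
        assert surf.values[200, 100] == pytest.approx(1e-8 * 100**2 * 200, rel=1e-14)
        assert surf.values[200, 100] == pytest.approx(0.02, rel=1e-12)

    def test_linearity_in_coefficients(self):
        g = dpca.GridConvention(64, 48)
        s1 = dpca.AberrationSpec({(3, 0): 1e-8, (0, 1): 1e-2})
        s2 = dpca.AberrationSpec({(1, 1): 1e-4})
        lhs = dpca.eval_polynomial_aberration(s1.scaled(2.5) + s2, g).values
        rhs = (
            2.5 * dpca.eval_polynomial_aberration(s1, g).values
            + dpca.eval_polynomial_aberration(s2, g).values
        )
        np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-12)

    def test_separable_spec_gives_rank1_field(self):
        # only k=0 or l=0 terms -> exp(i*surface) is rank 1 (singular values)
        g = dpca.GridConvention(128, 128)
        spec = dpca.AberrationSpec({(3, 0): 1e-6, (0, 1): 1e-2, (0, 2): 1e-5})
        surf = dpca.eval_polynomial_aberration(spec, g)
        s = np.linalg.svd(np.exp(1j * surf.values), compute_uv=False)
        assert s[1] / s[0] < 1e-10

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            dpca.AberrationSpec({(-1, 0): 1.0})

    def test_cross_term_classification(self):
        spec = dpca.AberrationSpec({(2, 1): 1.0, (3, 0): 1.0, (0, 2): 1.0})
        assert spec.cross_terms() == {(2, 1): 1.0}
        assert set(spec.non_cross_terms()) == {(3, 0), (0, 2)}
        assert spec.K == 3 and spec.L == 2

    def test_yaml_round_trip(self):
        spec = dpca.AberrationSpec({(2, 1): 1e-8, (0, 1): 1e-2})
        again = dpca.AberrationSpec.from_yaml_dict(spec.to_yaml_dict())
        assert again.coefficients == spec.coefficients


class TestSamplePhase:
    def test_null_sample_is_zero(self):
        g = dpca.GridConvention(64, 64)
        s = dpca.make_sample_phase(
            dpca.SampleSpec(gaussian_peak=0.0, mask_height=0.0), g
        )
        np.testing.assert_array_equal(s.values, 0.0)

    def test_gaussian_maximum_at_center(self):
        g = dpca.GridConvention(101, 101)
        s = dpca.make_sample_phase(
            dpca.SampleSpec(gaussian_peak=1.0, gaussian_sigma=50.0,
                            gaussian_center=(50, 50), mask=None), g
        )
        assert s.values[50, 50] == pytest.approx(1.0)
        assert s.values.max() == pytest.approx(1.0)

    def test_mask_offsets_exactly_masked_pixels(self):
        g = dpca.GridConvention(256, 256)
        mask = dpca.letters_mask(g, scale=4, top_left=(180, 40))
        s = dpca.make_sample_phase(
            dpca.SampleSpec(gaussian_peak=0.0, mask_height=1.5, mask=mask), g
        )
        on = mask == 1
        assert on.sum() > 0
        np.testing.assert_array_equal(s.values[on], 1.5)
        assert np.count_nonzero(s.values) == on.sum()

    def test_mask_shape_mismatch_raises(self):
        g = dpca.GridConvention(64, 64)
        bad = np.zeros((32, 32))
        with pytest.raises(ValueError):
            dpca.make_sample_phase(dpca.SampleSpec(mask=bad), g)

    def test_letters_mask_binary_and_coverage(self, grid512):
        mask = dpca.letters_mask(grid512)
        assert set(np.unique(mask)) <= {0.0, 1.0}
        assert 0 < mask.mean() < 0.05
        # glyph raster is 7 rows high for every character
        assert all(len(glyph) == 7 for glyph in _GLYPHS.values())


class TestWrapAndNoise:
    def test_wrap_zero_and_modular_identity(self):
        g = dpca.GridConvention(16, 16)
        zero = dpca.PhaseImage(np.zeros(g.shape), False, g)
        assert np.all(dpca.wrap_phase(zero).values == 0.0)
        const = dpca.PhaseImage(np.full(g.shape, 1.5 * np.pi), False, g)
        np.testing.assert_allclose(dpca.wrap_phase(const).values, -0.5 * np.pi)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_wrap_range_and_congruence(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(-30, 30, size=(8, 8))
        w = dpca.wrap_array(vals)
        assert np.all(w > -np.pi) and np.all(w <= np.pi)
        # congruent mod 2*pi: residual wraps back to zero
        np.testing.assert_allclose(dpca.wrap_array(w - vals), 0.0, atol=1e-9)

    def test_wrap_unwrap_round_trip_on_smooth_surface(self):
        g = dpca.GridConvention(128, 128)
        phi = dpca.eval_polynomial_aberration(
            dpca.AberrationSpec({(0, 1): 5e-2, (1, 0): 3e-2}), g
        )
        w = dpca.wrap_phase(phi)
        rewrapped = dpca.wrap_phase(dpca.unwrap_2d(w))
        np.testing.assert_allclose(rewrapped.values, w.values, atol=1e-9)

    def test_noise_zero_sigma_identity_and_seed_determinism(self):
        g = dpca.GridConvention(64, 64)
        phi = dpca.PhaseImage(np.zeros(g.shape), False, g)
        assert dpca.add_noise(phi, 0.0, seed=1) is phi
        a = dpca.add_noise(phi, 0.05, seed=42).values
        b = dpca.add_noise(phi, 0.05, seed=42).values
        np.testing.assert_array_equal(a, b)
        c = dpca.add_noise(phi, 0.05, seed=43).values
        assert not np.array_equal(a, c)

    def test_noise_std_matches_sigma(self):
        g = dpca.GridConvention(256, 256)
        phi = dpca.PhaseImage(np.zeros(g.shape), False, g)
        sigma = 0.1
        out = dpca.add_noise(phi, sigma, seed=7)
        n = out.values.size
        assert np.std(out.values) == pytest.approx(
            sigma, abs=3 * sigma / np.sqrt(2 * n)
        )
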