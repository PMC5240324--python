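import numpy as np
import pytest

from mcnedi.metrics import psnr
from mcnedi.superres import (
    bicubic_baseline,
    expand_nearest,
    interpolate_pixel,
    multicontrast_upscale,
    nedi_upscale,
)
from mcnedi.synthetic import DegradationSpec, degrade
from mcnedi.weight_regression import edge_mask


class TestExpandNearest:
    def test_2x2_blocks(self):
        out = expand_nearest(np.array([[1.0, 2.0], [3.0, 4.0]]))
        expected = np.array(
            [[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]],
            dtype=float,
        )
        np.testing.assert_array_equal(out, expected)

    def test_constant(self):
        assert np.all(expand_nearest(np.full((5, 5), 0.3)) == 0.3)

    def test_anchoring(self, rng):
        lr = rng.random((6, 7))
        hr = expand_nearest(lr)
        np.testing.assert_array_equal(hr[::2, ::2], lr)

    def test_factor_restriction(self):
        with pytest.raises(ValueError):
            expand_nearest(np.zeros((4, 4)), factor=3)


class TestInterpolatePixel:
    def test_convexity(self):
        assert interpolate_pixel([0.25] * 4, [0.7] * 4) == pytest.approx(0.7)

    def test_half_half(self):
        assert interpolate_pixel(
            [0.5, 0, 0, 0.5], [0.78, 0.0, 0.0, 0.78]
        ) == pytest.approx(0.78)

    def test_selector(self):
        assert interpolate_pixel([1, 0, 0, 0], [0.42, 0.9, 0.1, 0.5]) == (
            pytest.approx(0.42)
        )

    def test_wrong_length(self):
        with pytest.raises(ValueError):
            interpolate_pixel([1, 0, 0], [0, 0, 0, 0])

    def test_clipping(self):
        assert interpolate_pixel([2, 0, 0, 0], [0.9, 0, 0, 0]) == 1.0


class TestBicubic:
    def test_constant(self):
        out = bicubic_baseline(np.full((8, 8), 0.4))
        np.testing.assert_allclose(out, 0.4)

    def test_linear_ramp_interior(self):
        lr = np.tile(np.linspace(0.1, 0.9, 16), (16, 1))
        hr = bicubic_baseline(lr)
        truth = np.tile(np.interp(np.arange(32) / 2, np.arange(16),
                                  np.linspace(0.1, 0.9, 16)), (32, 1))
        np.testing.assert_allclose(hr[4:-4, 4:-4], truth[4:-4, 4:-4],
                                   atol=1e-9)

    def test_output_shape(self):
        assert bicubic_baseline(np.zeros((10, 14))).shape == (20, 28)

    def test_anchoring(self, rng):
        lr = rng.random((9, 9))
        hr = bicubic_baseline(lr)
        np.testing.assert_allclose(hr[::2, ::2], lr, atol=1e-9)


class TestNediUpscale:
    def test_constant(self):
        res = nedi_upscale(np.full((10, 10), 0.6))
        np.testing.assert_allclose(res.image, 0.6)
        assert res.edge_fraction == 0.0

    def test_diagonal_structure_exact_at_edges(self, diagonal_step_hr):
        lr = diagonal_step_hr[::2, ::2]
        res = nedi_upscale(lr)
        # every interior odd-odd pixel that got edge treatment averages two
        # along-diagonal equal neighbors -> exact reproduction
        hr = res.image
        count = 0
        for r in range(13, 51, 2):
            for c in range(13, 51, 2):
                s = [lr[(r - 1) // 2 + dr, (c - 1) // 2 + dc]
                     for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1))]
                if np.var(s) > 1e-4:
                    count += 1
                    assert hr[r, c] == pytest.approx(
                        diagonal_step_hr[r, c], abs=1e-12
                    )
        assert count > 10

    def test_beats_nearest_on_phantom(self, phantom_pair, phantom_lr):
        truth = phantom_pair.image_b
        p_nedi = psnr(nedi_upscale(phantom_lr).image, truth)
        p_near = psnr(expand_nearest(phantom_lr), truth)
        assert p_nedi > p_near

    def test_too_small(self):
        with pytest.raises(ValueError):
            nedi_upscale(np.zeros((5, 5)))

    def test_deterministic(self, phantom_lr):
        a = nedi_upscale(phantom_lr).image
        b = nedi_upscale(phantom_lr).image
        np.testing.assert_array_equal(a, b)


class TestMulticontrastUpscale:
    def test_constant_target(self, phantom_pair):
        lr = np.full((64, 64), 0.5)
        res = multicontrast_upscale(lr, phantom_pair.image_a)
        np.testing.assert_allclose(res.image, 0.5)

    def test_self_reference_beats_nedi_on_diagonal_phantom(
        self, diagonal_step_hr
    ):
        lr = diagonal_step_hr[::2, ::2]
        p_self = psnr(
            multicontrast_upscale(lr, diagonal_step_hr).image,
            diagonal_step_hr,
        )
        p_nedi = psnr(nedi_upscale(lr).image, diagonal_step_hr)
        assert p_self >= p_nedi

    def test_beats_bicubic_on_edge_band(self, phantom_pair, phantom_lr):
        truth = phantom_pair.image_b
        band = edge_mask(truth).mask
        mc = multicontrast_upscale(phantom_lr, phantom_pair.image_a).image
        bc = bicubic_baseline(phantom_lr)
        mse_mc = np.mean((mc[band] - truth[band]) ** 2)
        mse_bc = np.mean((bc[band] - truth[band]) ** 2)
        assert mse_mc < mse_bc

    def test_shape_mismatch(self, phantom_pair):
        with pytest.raises(ValueError, match="shape"):
            multicontrast_upscale(np.zeros((32, 32)), phantom_pair.image_a)

    def test_reference_scale_invariance_bit_exact(
        self, phantom_pair, phantom_lr
    ):
        base = multicontrast_upscale(phantom_lr, phantom_pair.image_a).image
        for alpha in (0.5, 2.0):
            out = multicontrast_upscale(
                phantom_lr, alpha * phantom_pair.image_a
            ).image
            np.testing.assert_array_equal(out, base)

    def test_deterministic(self, phantom_pair, phantom_lr):
        a = multicontrast_upscale(phantom_lr, phantom_pair.image_a).image
        b = multicontrast_upscale(phantom_lr, phantom_pair.image_a).image
        np.testing.assert_array_equal(a, b)


class TestDataConsistency:
    def test_both_engines(self, phantom_pair, phantom_lr):
        nd = nedi_upscale(phantom_lr).image
        mc = multicontrast_upscale(phantom_lr, phantom_pair.image_a).image
        np.testing.assert_array_equal(nd[::2, ::2], phantom_lr)
        np.testing.assert_array_equal(mc[::2, ::2], phantom_lr)

    def test_intensity_bounds(self, phantom_pair, phantom_lr):
        for img in (
            nedi_upscale(phantom_lr).image,
            multicontrast_upscale(phantom_lr, phantom_pair.image_a).image,
        ):
            assert img.min() >= 0.0 and img.max() <= 1.0

    def test_degrade_inverts_expansion_on_constant(self):
        c = np.full((10, 10), 0.7)
        np.testing.assert_allclose(
            degrade(expand_nearest(c), DegradationSpec()), c
        )
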