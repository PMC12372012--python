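import numpy as np
import pytest
from scipy import ndimage

from fuzzedge import GrayImage, apply_filter, canny_edges, gradient_edges, make_disk_phantom
from fuzzedge.classical import laplacian_raw
from fuzzedge.phantoms import make_step_image


class TestGradientOperators:
    def test_constant_image_zero_magnitude_empty_map(self):
        img = GrayImage(np.full((8, 8), 7.0), 255.0)
        grad, edges = gradient_edges(img, "sobel")
        assert grad.magnitude.max() == 0
        assert edges.pixels.sum() == 0

    @pytest.mark.parametrize("operator,expected", [("sobel", 4.0), ("prewitt", 3.0)])
    def test_unit_step_response(self, operator, expected):
        t = make_step_image(16, 8, 0, 1)
        grad, _ = gradient_edges(t.image, operator, threshold=100)
        # interior pixel adjacent to the step
        assert abs(grad.gx[8, 7]) == expected
        assert grad.gy[8, 7] == 0

    def test_magnitude_consistent_with_components(self, random_gray):
        grad, _ = gradient_edges(random_gray(seed=3), "prewitt")
        np.testing.assert_allclose(grad.magnitude, np.hypot(grad.gx, grad.gy), rtol=1e-9)

    def test_roberts_works_on_2x2(self):
        img = GrayImage(np.array([[0.0, 1.0], [1.0, 0.0]]), 255.0)
        grad, _ = gradient_edges(img, "roberts", threshold=100)
        assert grad.magnitude.max() > 0

    def test_shift_invariance(self, random_gray):
        """Adding a constant intensity leaves gradients unchanged."""
        img = random_gray(seed=5)
        shifted = GrayImage(img.pixels * 0.5 + 100, 255.0)
        base = GrayImage(img.pixels * 0.5, 255.0)
        g1, _ = gradient_edges(base, "sobel", threshold=10)
        g2, _ = gradient_edges(shifted, "sobel", threshold=10)
        np.testing.assert_allclose(g1.magnitude, g2.magnitude, atol=1e-9)

    def test_contrast_linearity(self, random_gray):
        img = random_gray(seed=6)
        half = GrayImage(img.pixels * 0.5, 255.0)
        g1, _ = gradient_edges(img, "sobel", threshold=10)
        g2, _ = gradient_edges(half, "sobel", threshold=10)
        np.testing.assert_allclose(g1.magnitude * 0.5, g2.magnitude, rtol=1e-9, atol=1e-9)

    def test_unknown_operator(self, random_gray):
        with pytest.raises(ValueError):
            gradient_edges(random_gray(), "scharr")


class TestCanny:
    def test_constant_image_empty(self):
        assert canny_edges(GrayImage(np.full((16, 16), 9.0), 255.0)).pixels.sum() == 0

    def test_disk_localization(self, disk_truth):
        """Detections lie within 2 px of the circle and cover >= 80% of it."""
        em = canny_edges(disk_truth.image)
        det = em.pixels.astype(bool)
        tmask = disk_truth.edge_mask()
        d_truth = ndimage.distance_transform_edt(~tmask)
        d_det = ndimage.distance_transform_edt(~det)
        assert det.any()
        assert d_truth[det].max() <= 2
        assert (d_det[tmask] <= 2).mean() >= 0.8

    @pytest.mark.parametrize("seed", range(3))
    def test_thinness_no_2x2_blocks(self, seed):
        t = make_disk_phantom(48, (23.5, 23.5), 10, 220, 40, noise_sd=8, seed=seed)
        p = canny_edges(t.image).pixels
        assert (p[:-1, :-1] & p[1:, :-1] & p[:-1, 1:] & p[1:, 1:]).sum() == 0

    def test_bad_thresholds_rejected(self, disk_truth):
        with pytest.raises(ValueError):
            canny_edges(disk_truth.image, low=0.9, high=0.1)

    def test_agrees_with_reference_canny_on_disk(self, disk_truth):
        """Independent cross-check: skimage's Canny localizes the same circle."""
        from skimage.feature import canny as sk_canny

        ours = canny_edges(disk_truth.image).pixels.astype(bool)
        ref = sk_canny(disk_truth.image.pixels / 255.0, sigma=np.sqrt(2))
        d_ref = ndimage.distance_transform_edt(~ref)
        assert d_ref[ours].max() <= 2


class TestFilters:
    def test_ramp_laplace_interior_zero(self):
        ramp = np.tile(np.arange(16.0), (16, 1))
        out = apply_filter(GrayImage(ramp, 255.0), "laplace")
        assert np.abs(out.pixels[1:-1, 1:-1]).max() == 0

    def test_constant_sharpen_unchanged(self):
        img = GrayImage(np.full((8, 8), 77.0), 255.0)
        np.testing.assert_array_equal(apply_filter(img, "sharpen").pixels, img.pixels)

    def test_single_bright_pixel_laplacian_kernel_arithmetic(self):
        arr = np.zeros((9, 9))
        arr[4, 4] = 50.0
        raw = laplacian_raw(GrayImage(arr, 255.0))
        assert raw[4, 4] == -4 * 50
        for r, c in [(3, 4), (5, 4), (4, 3), (4, 5)]:
            assert raw[r, c] == 50

    @pytest.mark.parametrize("name", ["laplace", "sobel_gradient", "smoothed_sobel_gradient", "sharpen"])
    def test_output_within_value_range(self, name, random_gray):
        out = apply_filter(random_gray(seed=11), name)
        assert out.pixels.min() >= 0 and out.pixels.max() <= 255

    def test_unknown_filter(self, random_gray):
        with pytest.raises(ValueError):
            apply_filter(random_gray(), "emboss")
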