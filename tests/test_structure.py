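"""Classical extraction pipeline: per-stage oracles and end-to-end recovery."""

import numpy as np
import pytest

from fi2ffa.evaluation import dice
from fi2ffa.image_io import RasterImage
from fi2ffa.structure import (
    ExtractionParams,
    equalize_contrast,
    extract_structure,
    fov_mask,
    gamma_correct,
    grayscale_stretch,
    green_channel,
    homomorphic_filter,
    line_response,
    otsu_binarize,
)


class TestGreenChannel:
    def test_pure_green_is_all_ones_and_pure_red_all_zeros(self):
        g = np.zeros((8, 8, 3), dtype=np.float32)
        g[:, :, 1] = 1.0
        assert np.array_equal(green_channel(RasterImage(g)), np.ones((8, 8), dtype=np.float32))
        r = np.zeros((8, 8, 3), dtype=np.float32)
        r[:, :, 0] = 1.0
        assert np.array_equal(green_channel(RasterImage(r)), np.zeros((8, 8), dtype=np.float32))

    def test_equals_channel_slice_and_single_channel_warns(self, rng):
        px = rng.random((6, 6, 3), dtype=np.float32)
        assert np.array_equal(green_channel(RasterImage(px)), px[:, :, 1])
        with pytest.warns(UserWarning):
            out = green_channel(RasterImage(px[:, :, :1]))
        assert np.array_equal(out, px[:, :, 0])


class TestEqualization:
    def test_constant_image_is_noop_with_warning(self):
        c = np.full((20, 20), 0.5, dtype=np.float32)
        with pytest.warns(UserWarning):
            out = equalize_contrast(c)
        assert np.array_equal(out, c)

    def test_two_level_image_maps_to_cdf_values(self):
        # CDF mapping sends the lower level to its mass (0.5), upper to 1.0
        img = np.zeros((10, 10), dtype=np.float32)
        img[:, 5:] = 0.8
        img[:, :5] = 0.2
        out = equalize_contrast(img, apply_clahe=False)
        assert np.allclose(np.unique(out.round(6)), [0.5, 1.0], atol=1e-6)

    def test_output_stays_in_unit_range(self, rng):
        for _ in range(10):
            out = equalize_contrast(rng.random((32, 32), dtype=np.float32))
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestHomomorphic:
    def test_unit_gammas_give_allpass_rescaled_identity(self, rng):
        img = rng.random((32, 32), dtype=np.float32) * 0.8 + 0.1
        out = homomorphic_filter(img, gamma_high=1.0, gamma_low=1.0)
        assert np.allclose(out, grayscale_stretch(img), atol=1e-4)

    def test_boosts_line_contrast_relative_to_illumination_gradient(self):
        # smooth large-scale gradient plus a small bright line
        h = w = 64
        grad = np.linspace(0.2, 0.8, w)[None, :].repeat(h, axis=0)
        img = grad.copy()
        img[30:32, 8:56] += 0.15
        out = homomorphic_filter(img, gamma_high=1.5, gamma_low=0.5, cutoff=8.0)
        def ratio(im):
            line = im[30:32, 8:56].mean() - im[[28, 34], 8:56].mean()
            amp = abs(im[5, -5] - im[5, 5])
            return line / amp
        assert ratio(out) > ratio(img)

    def test_finite_for_inputs_containing_zeros(self):
        img = np.zeros((16, 16))
        img[4:8, 4:8] = 0.5
        assert np.isfinite(homomorphic_filter(img)).all()


class TestGamma:
    def test_power_law_values_and_endpoints(self):
        assert np.isclose(gamma_correct(np.array([[0.25]]), 1.5)[0, 0], 0.125)
        assert gamma_correct(np.array([[1.0]]), 1.5)[0, 0] == 1.0
        assert gamma_correct(np.array([[0.0]]), 1.5)[0, 0] == 0.0
        x = np.linspace(0, 1, 11).reshape(1, -1)
        assert np.allclose(gamma_correct(x, 1.0), x)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            gamma_correct(np.ones((2, 2)), 0.0)


class TestLineResponse:
    def test_constant_image_gives_zero_response(self):
        resp = line_response(np.full((32, 32), 0.4))
        assert np.allclose(resp, 0.0, atol=1e-12)

    @pytest.mark.parametrize("angle", [0, 45, 90])
    def test_detects_drawn_line_and_its_orientation(self, angle):
        img = np.full((40, 40), 0.8)
        rr = np.arange(8, 32)
        if angle == 0:
            img[20, 8:32] = 0.2
            drawn = [(20, c) for c in range(8, 32)]
        elif angle == 90:
            img[8:32, 20] = 0.2
            drawn = [(r, 20) for r in range(8, 32)]
        else:
            for r in rr:
                img[r, r] = 0.2
            drawn = [(r, r) for r in range(8, 32)]
        resp, ang = line_response(img, return_orientation=True)
        peak = tuple(int(v) for v in np.unravel_index(np.argmax(resp), resp.shape))
        assert peak in drawn
        # measured orientation at interior line pixels within one 15-deg step
        want = {0: 0.0, 90: 90.0, 45: 135.0}[angle]  # image rows grow downward
        angs = np.array([ang[p] for p in drawn[4:-4]])
        delta = np.minimum(np.abs(angs - want), 180 - np.abs(angs - want))
        assert np.median(delta) <= 15.0 + 1e-9

    def test_line_outscores_isolated_dot_of_equal_darkness(self):
        base = np.full((40, 40), 0.8)
        line = base.copy()
        line[20, 8:32] = 0.2
        dot = base.copy()
        dot[20, 20] = 0.2
        r_line = line_response(line)[20, 20]
        r_dot = line_response(dot)[20, 20]
        assert r_line > r_dot


class TestStretchAndOtsu:
    def test_stretch_is_the_expected_linear_map(self):
        img = np.array([[0.2, 0.4, 0.6]])
        out = grayscale_stretch(img)
        assert np.allclose(out, [[0.0, 0.5, 1.0]])
        spanning = np.array([[0.0, 0.3, 1.0]])
        assert np.allclose(grayscale_stretch(spanning), spanning)

    def test_stretch_preserves_pixel_order(self, rng):
        img = rng.random((16, 16))
        out = grayscale_stretch(img)
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= -1e-12).all()

    def test_stretch_constant_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = grayscale_stretch(np.full((4, 4), 0.3))
        assert np.array_equal(out, np.zeros((4, 4), dtype=np.float32))

    def test_bimodal_threshold_separates_classes(self):
        img = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)]).reshape(10, 10)
        thr, binary = otsu_binarize(img)
        assert 0.1 < thr < 0.9
        assert np.array_equal(binary, (img > 0.5).astype(np.uint8))
        assert set(np.unique(binary)) <= {0, 1}
        assert binary.size == 100

    def test_threshold_matches_exhaustive_variance_search(self, rng):
        def oracle(img):
            lo, hi = img.min(), img.max()
            hist, edges = np.histogram(img.ravel(), bins=256, range=(lo, hi))
            centers = (edges[:-1] + edges[1:]) / 2
            n = hist.sum()
            best_k, best_v = 0, -1.0
            for k in range(256):
                w0 = hist[: k + 1].sum() / n
                w1 = 1 - w0
                if w0 == 0 or w1 == 0:
                    continue
                mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / hist[: k + 1].sum()
                mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / max(hist[k + 1 :].sum(), 1)
                v = w0 * w1 * (mu0 - mu1) ** 2
                if v > best_v + 1e-15:
                    best_v, best_k = v, k
            return edges[best_k + 1]

        images = [rng.random((24, 24)) for _ in range(8)]
        # structured: gradient, blob, two-tone, noisy line
        g = np.linspace(0, 1, 24)[None, :].repeat(24, axis=0)
        blob = np.exp(-((np.mgrid[0:24, 0:24][0] - 12) ** 2 + (np.mgrid[0:24, 0:24][1] - 12) ** 2) / 40.0)
        images += [g, blob, (g > 0.6).astype(float) * 0.7 + 0.1, g + rng.normal(0, 0.05, g.shape)]
        for img in images:
            thr, _ = otsu_binarize(img)
            assert np.isclose(thr, oracle(img), atol=1e-10)

    def test_degenerate_constant_input(self):
        with pytest.warns(UserWarning):
            thr, binary = otsu_binarize(np.full((5, 5), 0.7))
        assert np.isnan(thr) and binary.sum() == 0


class TestFovMask:
    def test_mask_area_close_to_analytic_disc(self, fi256):
        mask = fov_mask(fi256)
        r = 128.0
        assert abs(mask.sum() - np.pi * r * r) / (np.pi * r * r) < 0.10

    def test_all_white_is_all_ones_and_all_black_empty(self):
        white = RasterImage(np.ones((32, 32, 3), dtype=np.float32))
        assert fov_mask(white).all()
        with pytest.warns(UserWarning):
            mask = fov_mask(RasterImage(np.zeros((32, 32, 3), dtype=np.float32)))
        assert not mask.any()


class TestExtractStructure:
    def test_constant_image_yields_empty_structure(self):
        with pytest.warns(UserWarning):
            sm = extract_structure(RasterImage(np.full((64, 64, 3), 0.5, dtype=np.float32)), "FI")
        assert sm.pixels.sum() == 0

    def test_structure_is_zero_outside_field_mask(self, fi256):
        sm = extract_structure(fi256, "FI")
        mask = fov_mask(fi256)
        assert sm.pixels[~mask].sum() == 0

    def test_ffa_path_equals_fi_path_on_inverted_image(self, ffa256):
        mask = fov_mask(ffa256)
        via_ffa = extract_structure(ffa256, "FFA")
        inv = RasterImage(1.0 - ffa256.pixels, modality="FI")
        via_fi = extract_structure(inv, "FI", mask=mask)
        assert np.array_equal(via_ffa.pixels, via_fi.pixels)

    def test_recovers_phantom_vasculature(self, fi256, gt256):
        sm = extract_structure(fi256, "FI")
        assert dice(sm.pixels, gt256) >= 0.5

    def test_cross_modality_extractions_agree(self, fi256, ffa256):
        a = extract_structure(fi256, "FI")
        b = extract_structure(ffa256, "FFA")
        assert dice(a.pixels, b.pixels) >= 0.4

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ExtractionParams(gaussian_kernel=4)
        with pytest.raises(ValueError):
            ExtractionParams(gamma=-1.0)
        with pytest.raises(ValueError):
            ExtractionParams(line_length=2, line_width=3)
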