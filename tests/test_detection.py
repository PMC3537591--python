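import numpy as np
import pytest
from scipy import ndimage

from mammocalc.detection import (
    DetectionConfig,
    binarize,
    detect,
    difference_image,
    euler_number,
    kirsch_edges,
    laplacian_sharpen,
    smooth3x3,
    wavelet_bandpass,
    weighted_area,
)
from mammocalc.errors import (
    DegenerateInputError,
    DimensionError,
    EmptyRegionError,
)
from mammocalc.image_io import normalize_gray
from mammocalc.synthetic import generate_background


def spot_image(n=64, spots=(), background=0.0, noise_seed=None, sigma=0.0):
    """Smooth test image with Gaussian bumps at given (row, col, amp, width)."""
    img = np.full((n, n), float(background))
    yy, xx = np.mgrid[0:n, 0:n]
    for row, col, amp, width in spots:
        img += amp * np.exp(-((yy - row) ** 2 + (xx - col) ** 2)
                            / (2.0 * width ** 2))
    if noise_seed is not None:
        img += np.random.default_rng(noise_seed).normal(0, sigma, (n, n))
    return img


class TestSpatialBranch:
    def test_laplacian_sharpen_flat_field(self):
        np.testing.assert_allclose(laplacian_sharpen(np.full((5, 5), 3.0)), 3.0)

    def test_laplacian_sharpen_single_pixel(self):
        img = np.zeros((7, 7))
        img[3, 3] = 4.0
        assert laplacian_sharpen(img)[3, 3] == 5 * 4.0

    def test_laplacian_sharpen_ramp_unchanged_in_interior(self):
        ramp = np.tile(np.arange(8.0), (8, 1))
        out = laplacian_sharpen(ramp)
        np.testing.assert_allclose(out[1:-1, 1:-1], ramp[1:-1, 1:-1])

    def test_smooth3x3_spreads_single_pixel(self):
        img = np.zeros((7, 7))
        img[3, 3] = 9.0
        out = smooth3x3(img)
        np.testing.assert_allclose(out[2:5, 2:5], 1.0)
        assert out[0, 0] == 0.0

    def test_smooth3x3_checkerboard(self):
        yy, xx = np.mgrid[0:8, 0:8]
        board = 2.0 * ((yy + xx) % 2)
        out = smooth3x3(board)
        interior = out[1:-1, 1:-1]
        assert set(np.round(interior.ravel(), 6)) == {
            round(8 / 9, 6), round(10 / 9, 6)}

    def test_difference_image_and_shape_check(self):
        a = np.ones((4, 4))
        np.testing.assert_array_equal(difference_image(a, a), 0.0)
        np.testing.assert_allclose(difference_image(a + 2.5, a), 2.5)
        with pytest.raises(DimensionError):
            difference_image(a, np.ones((5, 5)))

    def test_difference_image_peaks_at_spot(self):
        img = spot_image(spots=[(32, 32, 50.0, 2.0)], background=10.0)
        f3 = difference_image(laplacian_sharpen(img), smooth3x3(img))
        assert np.unravel_index(np.argmax(f3), f3.shape) == (32, 32)
        assert abs(f3[5, 5]) < 1e-6

    def test_kirsch_flat_field_zero(self):
        np.testing.assert_allclose(kirsch_edges(np.full((6, 6), 4.0)), 0.0)

    def test_kirsch_step_response(self):
        img = np.zeros((9, 9))
        img[:, 5:] = 3.0
        out = kirsch_edges(img)
        assert out.max() == 15 * 3.0
        assert out[:, 4].max() == 15 * 3.0

    def test_kirsch_offset_invariant(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 50, (12, 12))
        np.testing.assert_allclose(kirsch_edges(img + 17.0),
                                   kirsch_edges(img), atol=1e-9)

    def test_too_small_image_rejected(self):
        for fn in (laplacian_sharpen, smooth3x3, kirsch_edges):
            with pytest.raises(DimensionError):
                fn(np.zeros((2, 2)))


class TestBinarize:
    def test_otsu_separates_bimodal(self):
        img = np.concatenate([np.full(60, 10.0), np.full(40, 200.0)])
        mask = binarize(img.reshape(10, 10), "otsu")
        np.testing.assert_array_equal(mask.pixels.ravel(), img >= 200)

    def test_percentile_100_keeps_only_maxima(self):
        img = np.arange(16.0).reshape(4, 4)
        mask = binarize(img, "percentile", percentile=100.0)
        assert mask.pixels.sum() == 1
        assert mask.pixels[3, 3] == 1

    def test_otsu_matches_exhaustive_sweep(self):
        """Otsu equals a brute-force search over all 256 histogram split
        points maximizing between-class variance."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            img = rng.uniform(0, 255, (32, 32))
            counts, edges = np.histogram(img, bins=256)
            centers = 0.5 * (edges[:-1] + edges[1:])
            best, best_t = -1.0, None
            for k in range(1, 256):
                w0, w1 = counts[:k].sum(), counts[k:].sum()
                if w0 == 0 or w1 == 0:
                    continue
                mu0 = (counts[:k] * centers[:k]).sum() / w0
                mu1 = (counts[k:] * centers[k:]).sum() / w1
                var = w0 * w1 * (mu0 - mu1) ** 2
                if var > best:
                    best, best_t = var, centers[k - 1]
            mask = binarize(img, "otsu")
            np.testing.assert_array_equal(mask.pixels, img >= best_t)

    def test_otsu_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            binarize(np.full((4, 4), 3.0), "otsu")


class TestWaveletBranch:
    def test_constant_image_maps_to_zero(self):
        out = wavelet_bandpass(np.full((64, 64), 9.0))
        assert np.abs(out).max() < 1e-6

    def test_pure_finest_level_content_removed(self):
        """An image living (almost) entirely in the finest detail level is
        annihilated by the band-pass, which zeroes that level."""
        import pywt
        coeffs = pywt.wavedec2(np.zeros((64, 64)), "db4", level=4,
                               mode="symmetric")
        rng = np.random.default_rng(8)
        coeffs[-1] = tuple(rng.normal(size=b.shape) for b in coeffs[-1])
        img = pywt.waverec2(coeffs, "db4", mode="symmetric")[:64, :64]
        # project into the level-1 subspace (arbitrary coefficient arrays are
        # not exactly realizable with boundary extension; iterate to converge)
        for _ in range(3):
            c = pywt.wavedec2(img, "db4", level=4, mode="symmetric")
            c = ([np.zeros_like(c[0])]
                 + [tuple(np.zeros_like(b) for b in lev) for lev in c[1:-1]]
                 + [c[-1]])
            img = pywt.waverec2(c, "db4", mode="symmetric")[:64, :64]
        out = wavelet_bandpass(img)
        assert (out ** 2).sum() < 0.01 * (img ** 2).sum()

    def test_energy_localizes_near_spots(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = 0.5 * xx + 0.3 * yy  # smooth gradient background
        centers = [(16, 20), (40, 44), (50, 12)]
        for r, c in centers:
            img += 60.0 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 1.5 ** 2))
        out = wavelet_bandpass(img) ** 2
        near = np.zeros_like(out, dtype=bool)
        for r, c in centers:
            near |= ((yy - r) ** 2 + (xx - c) ** 2) <= 25
        assert out[near].sum() / out.sum() > 0.8

    def test_small_image_rejected(self):
        with pytest.raises(DimensionError):
            wavelet_bandpass(np.zeros((8, 8)))


class TestRegionMeasures:
    def test_weighted_area_single_pixel(self):
        mask = np.zeros((3, 3), dtype=np.uint8)
        mask[1, 1] = 1
        assert weighted_area(mask) == 0.5

    def test_weighted_area_3x3_square(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1:4, 1:4] = 1
        assert weighted_area(mask) == 5.0

    def test_weighted_area_converges_to_pixel_count(self):
        n = 101
        mask = np.ones((n, n), dtype=np.uint8)
        assert weighted_area(mask) / n ** 2 > 0.97

    def test_weighted_area_empty_rejected(self):
        with pytest.raises(EmptyRegionError):
            weighted_area(np.zeros((4, 4), dtype=np.uint8))

    def test_euler_solid_square(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[1:5, 1:5] = 1
        assert euler_number(mask) == 1

    def test_euler_annulus(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[1:6, 1:6] = 1
        mask[3, 3] = 0
        assert euler_number(mask) == 0

    def test_euler_two_components(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[1:3, 1:3] = 1
        mask[5:7, 5:7] = 1
        assert euler_number(mask) == 2

    def test_euler_matches_flood_fill_oracle(self):
        """E = C - H agrees with an independent BFS flood-fill labeling on
        random masks."""

        def flood_count(arr, structure_offsets):
            seen = np.zeros_like(arr, dtype=bool)
            count = 0
            rows, cols = arr.shape
            for r0 in range(rows):
                for c0 in range(cols):
                    if arr[r0, c0] and not seen[r0, c0]:
                        count += 1
                        stack = [(r0, c0)]
                        seen[r0, c0] = True
                        while stack:
                            r, c = stack.pop()
                            for dr, dc in structure_offsets:
                                rr, cc = r + dr, c + dc
                                if (0 <= rr < rows and 0 <= cc < cols
                                        and arr[rr, cc] and not seen[rr, cc]):
                                    seen[rr, cc] = True
                                    stack.append((rr, cc))
            return count

        eight = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
        four = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        rng = np.random.default_rng(12)
        for _ in range(50):
            mask = (rng.uniform(size=(32, 32)) < 0.4)
            comp = flood_count(mask, eight)
            padded = np.pad(mask, 1, constant_values=False)
            holes = flood_count(~padded, four) - 1
            assert euler_number(mask.astype(np.uint8)) == comp - holes


class TestDetect:
    def test_blank_roi_has_no_spots(self):
        result = detect(np.full((64, 64), 5.0))
        assert result.spots == []
        assert result.mask.pixels.sum() == 0

    def test_planted_spots_recovered(self):
        rng = np.random.default_rng(7)
        centers = []
        while len(centers) < 10:
            cand = rng.uniform(10, 118, size=2)
            if all(np.hypot(cand[0] - r, cand[1] - c) > 14 for r, c in centers):
                centers.append(tuple(cand))
        spots = [(r, c, 50.0, rng.uniform(1.0, 2.0)) for r, c in centers]
        img = spot_image(n=128, spots=spots, background=100.0,
                         noise_seed=7, sigma=2.0)
        result = detect(normalize_gray(img), DetectionConfig())
        matched = 0
        for r, c, _, _ in spots:
            if any(np.hypot(s.centroid[0] - r, s.centroid[1] - c) <= 3.0
                   for s in result.spots):
                matched += 1
        assert matched >= 8

    def test_fused_mask_subset_of_branches(self):
        img = generate_background(seed=21).pixels
        result = detect(normalize_gray(img))
        fused = result.mask.pixels
        for branch in result.branch_masks:
            assert np.all(fused <= branch.pixels)

    def test_spots_lie_inside_mask(self):
        img = generate_background(seed=22).pixels
        result = detect(normalize_gray(img))
        for spot in result.spots:
            r, c = (int(round(v)) for v in spot.centroid)
            window = result.mask.pixels[max(r - 2, 0):r + 3,
                                        max(c - 2, 0):c + 3]
            assert window.any()

    def test_stage_outputs_preserve_shape(self):
        img = np.random.default_rng(1).uniform(0, 255, (48, 48))
        for fn in (laplacian_sharpen, smooth3x3, kirsch_edges,
                   wavelet_bandpass):
            assert fn(img).shape == img.shape

    def test_recall_monotone_in_contrast(self):
        """Detected-spot recall does not decrease as planted contrast grows."""
        rng = np.random.default_rng(13)
        centers = []
        while len(centers) < 8:
            cand = rng.uniform(12, 116, size=2)
            if all(np.hypot(cand[0] - r, cand[1] - c) > 16 for r, c in centers):
                centers.append(tuple(cand))
        recalls = []
        for contrast in (10.0, 30.0, 50.0, 80.0):
            img = spot_image(
                n=128,
                spots=[(r, c, contrast, 1.5) for r, c in centers],
                background=100.0, noise_seed=99, sigma=3.0)
            result = detect(normalize_gray(img))
            hit = sum(
                any(np.hypot(s.centroid[0] - r, s.centroid[1] - c) <= 3.0
                    for s in result.spots)
                for r, c in centers)
            recalls.append(hit / len(centers))
        assert all(b >= a - 1e-9 for a, b in zip(recalls, recalls[1:]))

    def test_pure_noise_fusion_dominance(self):
        rng = np.random.default_rng(31)
        img = rng.normal(128, 10, (64, 64)).clip(0, 255)
        result = detect(normalize_gray(img))
        fused = result.mask.pixels.sum()
        assert fused <= min(b.pixels.sum() for b in result.branch_masks)
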