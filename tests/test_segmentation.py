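import numpy as np
import pytest

from rootpheno.errors import DegenerateHistogramError, FormatError, InvalidArgumentError
from rootpheno.segmentation import (
    BinaryMask,
    GrayImage,
    SegmentationConfig,
    invert,
    manual_threshold,
    median_smooth,
    remove_small_components,
    threshold_adaptive,
    threshold_otsu,
    threshold_triangle,
    to_grayscale,
)


# ---------------------------------------------------------------- oracles
def otsu_bruteforce(pixels):
    """Exhaustive 256-candidate between-class-variance maximization."""
    hist = np.bincount(pixels.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t, best_var


def otsu_variance_at(pixels, t):
    hist = np.bincount(pixels.ravel(), minlength=256).astype(float)
    total = hist.sum()
    w0 = hist[: t + 1].sum()
    w1 = total - w0
    if w0 == 0 or w1 == 0:
        return -1.0
    mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
    mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
    return (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2


def triangle_distance_profile(pixels):
    """Perpendicular distance of every candidate bin from the peak->tail
    chord (longer-baseline side), as a {bin: distance} dict."""
    hist = np.bincount(pixels.ravel(), minlength=256).astype(float)
    nonzero = np.nonzero(hist)[0]
    peak = int(np.argmax(hist))
    first, last = nonzero[0], nonzero[-1]
    tail = first if peak - first >= last - peak else last
    lo, hi = sorted((peak, tail))
    x1, y1 = peak, hist[peak]
    x2, y2 = tail, hist[tail]
    norm = np.hypot(x2 - x1, y2 - y1)
    out = {}
    for x in range(lo, hi + 1):
        out[x] = abs((x2 - x1) * (y1 - hist[x]) - (x1 - x) * (y2 - y1)) / norm
    return out


# ---------------------------------------------------------- preprocessing
class TestToGrayscale:
    def test_uniform_rgb_maps_to_its_gray_value(self):
        img = np.full((4, 4, 3), 77, dtype=np.uint8)
        assert (to_grayscale(img).pixels == 77).all()

    def test_black_stays_black(self):
        assert (to_grayscale(np.zeros((3, 3, 3), dtype=np.uint8)).pixels == 0).all()

    def test_known_luminance_weights(self):
        # 0.299*10 + 0.587*200 + 0.114*30 = 123.81 -> 124
        img = np.zeros((3, 3, 3), dtype=np.uint8)
        img[:, :] = (10, 200, 30)
        assert (to_grayscale(img).pixels == 124).all()

    def test_single_channel_passthrough(self):
        arr = np.arange(16, dtype=np.uint8).reshape(4, 4)
        assert (to_grayscale(arr).pixels == arr).all()

    def test_bad_channel_count_rejected(self):
        with pytest.raises(FormatError):
            to_grayscale(np.zeros((4, 4, 2), dtype=np.uint8))

    def test_too_small_rejected(self):
        with pytest.raises(FormatError):
            to_grayscale(np.zeros((1, 5), dtype=np.uint8))


class TestMedianSmooth:
    def test_constant_unchanged(self):
        g = GrayImage(np.full((8, 8), 42, dtype=np.uint8))
        assert (median_smooth(g, 5).pixels == 42).all()

    def test_isolated_bright_pixel_removed(self):
        arr = np.zeros((7, 7), dtype=np.uint8)
        arr[3, 3] = 255
        out = median_smooth(GrayImage(arr), 3)
        assert out.pixels[3, 3] == 0

    def test_kernel_one_is_identity(self):
        arr = np.random.default_rng(0).integers(0, 256, (10, 10)).astype(np.uint8)
        g = GrayImage(arr)
        assert median_smooth(g, 1) is g

    def test_even_kernel_rejected(self):
        with pytest.raises(InvalidArgumentError):
            median_smooth(GrayImage(np.zeros((4, 4), dtype=np.uint8)), 4)


class TestInvert:
    def test_zero_maps_to_255(self):
        g = GrayImage(np.zeros((2, 2), dtype=np.uint8))
        assert (invert(g).pixels == 255).all()

    def test_involution(self, rng):
        g = GrayImage(rng.integers(0, 256, (12, 12)).astype(np.uint8))
        assert (invert(invert(g)).pixels == g.pixels).all()

    def test_midgray(self):
        g = GrayImage(np.full((2, 2), 128, dtype=np.uint8))
        assert (invert(g).pixels == 127).all()


# ------------------------------------------------------------ thresholding
class TestOtsu:
    def test_perfect_bimodal(self):
        arr = np.zeros((10, 10), dtype=np.uint8)
        arr[:, 5:] = 255
        mask, t = threshold_otsu(GrayImage(arr))
        assert 0 <= t < 255
        assert (mask.pixels == (arr == 255)).all()

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            threshold_otsu(GrayImage(np.full((5, 5), 7, dtype=np.uint8)))

    def test_gaussian_mixture_matches_bruteforce(self, rng):
        samples = np.concatenate([
            rng.normal(60, 12, 800), rng.normal(200, 15, 800)
        ])
        arr = np.clip(np.rint(samples), 0, 255).astype(np.uint8).reshape(40, 40)
        _, t = threshold_otsu(GrayImage(arr))
        t_ref, _ = otsu_bruteforce(arr)
        assert t == t_ref

    def test_oracle_equivalence_100_random_images(self, rng):
        for _ in range(100):
            kind = rng.integers(3)
            n = 1024
            if kind == 0:
                samples = rng.integers(0, 256, n)
            elif kind == 1:
                mus = rng.uniform(20, 235, size=2)
                samples = np.concatenate([
                    rng.normal(mus[0], rng.uniform(2, 30), n // 2),
                    rng.normal(mus[1], rng.uniform(2, 30), n - n // 2),
                ])
            else:
                samples = rng.exponential(rng.uniform(10, 80), n)
            arr = np.clip(np.rint(samples), 0, 255).astype(np.uint8).reshape(32, 32)
            if arr.min() == arr.max():
                continue
            _, t = threshold_otsu(GrayImage(arr))
            t_ref, var_ref = otsu_bruteforce(arr)
            assert otsu_variance_at(arr, t) == pytest.approx(var_ref, rel=1e-9)
            assert t == t_ref

    def test_binary_partition(self, rng):
        arr = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        mask, t = threshold_otsu(GrayImage(arr))
        assert ((arr > t) == mask.pixels).all()
        assert (mask.pixels | ~mask.pixels).all()


class TestTriangle:
    def test_two_level_separates(self):
        arr = np.zeros((10, 10), dtype=np.uint8)
        arr[:2, :] = 220  # minority bright phase
        mask, t = threshold_triangle(GrayImage(arr))
        assert 0 <= t < 220
        assert (mask.pixels == (arr == 220)).all()

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            threshold_triangle(GrayImage(np.full((5, 5), 99, dtype=np.uint8)))

    def test_skewed_unimodal_matches_geometric_oracle(self, rng):
        for _ in range(50):
            loc = rng.uniform(150, 230)
            samples = np.concatenate([
                rng.normal(loc, rng.uniform(5, 15), 2000),
                rng.uniform(0, loc, rng.integers(40, 120)),
            ])
            arr = np.clip(np.rint(samples[:2025]), 0, 255).astype(np.uint8).reshape(45, 45)
            if arr.min() == arr.max():
                continue
            _, t = threshold_triangle(GrayImage(arr))
            profile = triangle_distance_profile(arr)
            assert t in profile
            assert profile[t] == pytest.approx(max(profile.values()), rel=1e-9, abs=1e-9)

    def test_mirror_symmetry_within_one_bin(self, rng):
        samples = np.concatenate([rng.normal(190, 10, 3000), rng.uniform(0, 150, 100)])
        arr = np.clip(np.rint(samples[:3025]), 0, 255).astype(np.uint8).reshape(55, 55)
        g = GrayImage(arr)
        _, t = threshold_triangle(g)
        _, t_inv = threshold_triangle(invert(g))
        assert abs((255 - t) - t_inv) <= 1


class TestAdaptive:
    def test_constant_image_positive_offset_empty(self):
        g = GrayImage(np.full((9, 9), 100, dtype=np.uint8))
        mask = threshold_adaptive(g, "mean", block_size=3, offset_c=1.0)
        assert not mask.pixels.any()

    def test_step_edge_mean_mode_interior(self):
        # columns 0-4 dark (50), 5-9 bright (200); block 3, offset 0
        arr = np.full((9, 10), 50, dtype=np.uint8)
        arr[:, 5:] = 200
        mask = threshold_adaptive(GrayImage(arr), "mean", block_size=3, offset_c=0.0)
        interior = mask.pixels[1:-1, :]
        # hand 3x3 means: col 4 mean = (2*50+1*200)/3 = 100 > 50 -> background;
        # col 5 mean = (1*50+2*200)/3 = 150 < 200 -> foreground;
        # flat interior columns equal their mean -> strict '>' gives background
        assert interior[:, 5].all()
        assert not interior[:, 4].any()
        assert not interior[:, 1:4].any()
        assert not interior[:, 7:].any()

    def test_gaussian_close_to_mean_on_smooth_image(self):
        from scipy.ndimage import uniform_filter

        # on a smooth (locally linear) ramp both symmetric local statistics
        # equal the center value away from the borders, so the two modes may
        # only disagree within ~1 gray level of the decision boundary
        xs = np.linspace(0, 255, 128)
        arr = np.rint(np.add.outer(xs * 0.3, xs * 0.7)).clip(0, 255).astype(np.uint8)
        g = GrayImage(arr)
        m_mean = threshold_adaptive(g, "mean", block_size=31, offset_c=0.0)
        m_gauss = threshold_adaptive(g, "gaussian", block_size=31, offset_c=0.0)
        local_mean = uniform_filter(arr.astype(float), size=31, mode="reflect")
        interior = np.s_[32:-32, 32:-32]
        disagree = (m_mean.pixels != m_gauss.pixels)[interior]
        deviation = np.abs(arr.astype(float) - local_mean)[interior]
        assert (deviation[disagree] <= 1.5).all()

    def test_even_block_rejected(self):
        with pytest.raises(InvalidArgumentError):
            threshold_adaptive(GrayImage(np.zeros((5, 5), np.uint8)), "mean", block_size=4)

    def test_bad_mode_rejected(self):
        with pytest.raises(InvalidArgumentError):
            threshold_adaptive(GrayImage(np.zeros((5, 5), np.uint8)), "median", 3)


class TestManualThresholdMonotonicity:
    def test_foreground_grows_as_threshold_drops(self, rng):
        arr = rng.integers(0, 256, (30, 30)).astype(np.uint8)
        g = GrayImage(arr)
        counts = [manual_threshold(g, t).count() for t in range(0, 256, 16)]
        assert counts == sorted(counts, reverse=True)


# ------------------------------------------------------- particle clearance
class TestRemoveSmallComponents:
    @staticmethod
    def three_blob_mask():
        m = np.zeros((40, 80), dtype=bool)
        m[1:4, 1:2] = True          # 3 px
        m[10:15, 10:20] = True      # 50 px
        m[20:40, 30:55] = True      # 500 px
        return BinaryMask(m)

    def test_min_area_zero_is_identity(self):
        m = self.three_blob_mask()
        out = remove_small_components(m, 0)
        assert (out.pixels == m.pixels).all()

    def test_census_threshold_10(self):
        out = remove_small_components(self.three_blob_mask(), 10)
        assert out.count() == 550
        assert not out.pixels[1:4, 1:2].any()

    def test_everything_removed(self):
        out = remove_small_components(self.three_blob_mask(), 10_000)
        assert not out.pixels.any()

    def test_idempotent_and_monotone(self, rng):
        from conftest import make_blobs

        for _ in range(5):
            m = make_blobs(rng)
            once = remove_small_components(m, 30)
            twice = remove_small_components(once, 30)
            assert (once.pixels == twice.pixels).all()
            assert once.count() <= m.count()

    def test_connectivity_4_vs_8_diagonal_pair(self):
        m = np.zeros((6, 6), dtype=bool)
        m[1, 1] = m[2, 2] = True  # diagonal pair: one 8-component, two 4-components
        assert remove_small_components(BinaryMask(m), 2, connectivity=8).count() == 2
        assert remove_small_components(BinaryMask(m), 2, connectivity=4).count() == 0

    def test_negative_min_area_rejected(self):
        with pytest.raises(InvalidArgumentError):
            remove_small_components(BinaryMask(np.zeros((3, 3), bool)), -1)


class TestSegmentationConfig:
    @pytest.mark.parametrize("kwargs", [
        {"median_kernel": 2}, {"block_size": 8}, {"min_particle_area": -5},
        {"connectivity": 6},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            SegmentationConfig(**kwargs)
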