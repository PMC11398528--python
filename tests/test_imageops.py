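"""Unit and property tests for the primitive image operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage as ndi

from microquant import imageops as ops
from microquant.image import Image2D


# ---------------------------------------------------------------------------
# rolling-ball background subtraction
# ---------------------------------------------------------------------------

def brute_paraboloid_opening(f, radius):
    """Exhaustive structuring-element sweep: the independent oracle."""
    h, w = f.shape
    ms = int(np.ceil(np.sqrt(2 * radius * (f.max() - f.min())))) + 1
    ero = np.empty_like(f)
    out = np.empty_like(f)
    for y in range(h):
        for x in range(w):
            lo = np.inf
            for v in range(max(0, y - ms), min(h, y + ms + 1)):
                for u in range(max(0, x - ms), min(w, x + ms + 1)):
                    lo = min(lo, f[v, u] + ((v - y) ** 2 + (u - x) ** 2) / (2 * radius))
            ero[y, x] = lo
    for y in range(h):
        for x in range(w):
            hi = -np.inf
            for v in range(max(0, y - ms), min(h, y + ms + 1)):
                for u in range(max(0, x - ms), min(w, x + ms + 1)):
                    hi = max(hi, ero[v, u] - ((v - y) ** 2 + (u - x) ** 2) / (2 * radius))
            out[y, x] = hi
    return out


def brute_ball_opening(f, radius):
    """Exhaustive sweep with the spherical height profile (interior only)."""
    r = int(radius)
    offs = [(v, u, np.sqrt(radius ** 2 - v * v - u * u))
            for v in range(-r, r + 1) for u in range(-r, r + 1)
            if v * v + u * u <= radius ** 2]
    h, w = f.shape
    ero = np.full_like(f, np.inf)
    out = np.full_like(f, -np.inf)
    for y in range(r, h - r):
        for x in range(r, w - r):
            ero[y, x] = min(f[y + v, x + u] - z for v, u, z in offs)
    for y in range(2 * r, h - 2 * r):
        for x in range(2 * r, w - 2 * r):
            out[y, x] = max(ero[y + v, x + u] + z for v, u, z in offs)
    return out


class TestRollingBall:
    def test_constant_image_gives_zeros(self):
        out = ops.rolling_ball_subtract(np.full((30, 30), 7.0), 5)
        assert np.allclose(out, 0.0, atol=1e-9)

    @pytest.mark.parametrize("method", ["ball", "paraboloid"])
    def test_matches_exhaustive_sweep_oracle(self, rng, method):
        f = rng.uniform(0, 40, (26, 28))
        r = 3
        got = ops.rolling_ball_subtract(f, r, presmooth=False, method=method)
        if method == "paraboloid":
            expected = np.clip(f - np.minimum(brute_paraboloid_opening(f, r), f), 0, None)
            assert np.allclose(got, expected, atol=1e-9)
        else:
            bg = brute_ball_opening(f, r)
            inner = np.zeros(f.shape, bool)
            inner[2 * r:-2 * r, 2 * r:-2 * r] = True  # oracle skips borders
            expected = np.clip(f - np.minimum(bg, f), 0, None)
            assert np.allclose(got[inner], expected[inner], atol=1e-9)

    def test_ramp_removed_spot_preserved(self):
        # planar ramp + one bright disk: ramp residual vanishes, spot survives
        yy, xx = np.mgrid[:64, :64]
        ramp = 0.1 * xx + 3.0
        img = ramp.copy()
        spot = (xx - 32) ** 2 + (yy - 32) ** 2 <= 16
        img[spot] += 100.0
        out = ops.rolling_ball_subtract(img, 50, presmooth=False)
        off_spot = (xx - 32) ** 2 + (yy - 32) ** 2 > 100
        assert np.median(out[off_spot]) < 1.0
        assert abs(out.max() - 100.0) < 10.0

    def test_delta_spike_preserved(self):
        img = np.zeros((48, 48))
        img[20, 20] = 80.0
        out = ops.rolling_ball_subtract(img, 10, presmooth=False)
        assert out.max() >= 0.9 * 80.0

    def test_output_bounded_by_input(self, rng):
        img = rng.uniform(0, 200, (40, 40))
        out = ops.rolling_ball_subtract(img, 7)
        assert np.all(out <= img + 1e-9)
        assert np.all(out >= 0)

    def test_invalid_radius_raises(self):
        with pytest.raises(ValueError):
            ops.rolling_ball_subtract(np.zeros((20, 20)), 0)
        with pytest.raises(ValueError):
            ops.rolling_ball_subtract(np.zeros((20, 20)), 20)


# ---------------------------------------------------------------------------
# 8-bit conversion
# ---------------------------------------------------------------------------

class TestTo8Bit:
    @pytest.mark.parametrize("values,kwargs,expected", [
        ([0.0, 50.0, 100.0], {}, [0, 128, 255]),
        ([10.0, 20.0], {"lo": 0, "hi": 40}, [64, 128]),
        (list(range(0, 256)), {}, list(range(0, 256))),  # identity on full 8-bit span
    ])
    def test_examples(self, values, kwargs, expected):
        out = ops.to_8bit(np.array([values]), **kwargs)
        assert out.tolist() == [expected]

    def test_constant_image_needs_explicit_bounds(self):
        with pytest.raises(ValueError, match="explicit bounds"):
            ops.to_8bit(np.full((4, 4), 9.0))
        out = ops.to_8bit(np.full((4, 4), 9.0), lo=0, hi=18)
        assert np.all(out == 128)

    @given(hnp.arrays(np.float64, (3, 4), elements=st.floats(0, 1e4)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone(self, arr):
        if arr.max() <= arr.min():
            return
        out = ops.to_8bit(arr)
        order = np.argsort(arr.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= 0)

    def test_sets_8bit_hint(self):
        img = Image2D(np.array([[0.0, 9.0]]))
        assert ops.to_8bit(img).bit_depth_hint == "8bit"


# ---------------------------------------------------------------------------
# unsharp mask
# ---------------------------------------------------------------------------

class TestUnsharpMask:
    def test_constant_is_fixed_point(self):
        out = ops.unsharp_mask(np.full((20, 20), 42.0), sigma=3, weight=0.9)
        assert np.allclose(out, 42.0)

    def test_small_weight_limit_approaches_identity(self, rng):
        img = rng.uniform(10, 200, (24, 24))
        out = ops.unsharp_mask(img, sigma=2, weight=1e-9)
        assert np.allclose(out, img, atol=1e-5)

    def test_impulse_against_dense_convolution_oracle(self):
        # centre response of (I − w·G)/(1−w) on a unit impulse
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        sigma, w = 3.0, 0.9
        blurred = ndi.gaussian_filter(img, sigma, mode="reflect")
        expected = (img - w * blurred) / (1 - w)
        got = ops.unsharp_mask(img, sigma, w)
        assert np.allclose(got, np.clip(expected, 0, None), atol=1e-12)
        assert got[16, 16] == pytest.approx((1 - w * blurred[16, 16]) / (1 - w))

    def test_8bit_output_clamped_and_integer(self):
        img = Image2D(np.array([[0., 255., 0.], [255., 0., 255.], [0., 255., 0.]]),
                      bit_depth_hint="8bit")
        out = ops.unsharp_mask(img, sigma=1, weight=0.9)
        assert out.pixels.min() >= 0 and out.pixels.max() <= 255
        assert np.allclose(out.pixels, np.round(out.pixels))

    def test_invalid_weight_raises(self):
        for w in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                ops.unsharp_mask(np.zeros((5, 5)), sigma=1, weight=w)


# ---------------------------------------------------------------------------
# rank / mean filters
# ---------------------------------------------------------------------------

class TestRankFilters:
    def test_constant_unchanged(self):
        for f in (ops.mean_filter, ops.median_filter):
            assert np.allclose(f(np.full((10, 10), 3.0), 1), 3.0)

    def test_median_removes_isolated_outlier(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        assert ops.median_filter(img, 1)[4, 4] == 0.0

    def test_mean_disk_radius_one_is_centre_plus_4_neighbours(self):
        img = np.zeros((9, 9))
        img[4, 4] = 9.0
        assert ops.mean_filter(img, 1)[4, 4] == pytest.approx(9.0 / 5.0)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

class TestThresholdRange:
    def test_inclusive_bounds(self):
        img = np.array([[99.0, 100.0, 255.0]])
        assert ops.threshold_range(img, 100, 255).tolist() == [[False, True, True]]

    def test_saturation_only(self):
        assert ops.threshold_range(np.array([[254.0, 255.0]]), 255, 255).tolist() == \
            [[False, True]]

    def test_full_range_all_true(self):
        assert ops.threshold_range(np.array([[0.0, 128.0, 255.0]]), 0, 255).all()

    def test_rejects_non_8bit(self):
        with pytest.raises(ValueError):
            ops.threshold_range(np.array([[0.5, 300.0]]), 0, 255)


# ---------------------------------------------------------------------------
# tubeness
# ---------------------------------------------------------------------------

class TestTubeness:
    def test_constant_gives_zero(self):
        assert np.allclose(ops.tubeness(np.full((20, 20), 5.0), 2.0), 0.0)

    def test_affine_interior_gives_zero(self):
        yy, xx = np.mgrid[:40, :40]
        out = ops.tubeness(0.3 * xx + 0.1 * yy + 2.0, 2.0)
        assert np.allclose(out[10:-10, 10:-10], 0.0, atol=1e-9)

    def test_bright_line_gives_ridge(self):
        img = np.zeros((41, 41))
        img[20, :] = 10.0
        sigma = 1.5
        out = ops.tubeness(img, sigma)
        on_line = out[20, 5:-5].min()
        off = out[20 + int(3 * sigma) + 2, 5:-5].max()
        assert on_line > 0
        assert off < 0.1 * on_line

    def test_flat_square_interior_quiet(self):
        img = np.zeros((40, 40))
        img[10:30, 10:30] = 50.0
        out = ops.tubeness(img, 1.5)
        assert out[18:22, 18:22].max() < 0.05 * out.max()

    def test_subpixel_sigma_clamped_with_warning(self):
        img = Image2D(np.zeros((10, 10)), pixel_size=0.5)
        with pytest.warns(UserWarning, match="clamping"):
            ops.tubeness(img, 0.05)  # 0.1 px effective

    def test_calibrated_sigma_conversion(self):
        # same response whether sigma is given in px or in µm on a
        # calibrated image of matching pixel size
        rng = np.random.default_rng(0)
        arr = rng.uniform(0, 10, (32, 32))
        out_px = ops.tubeness(arr, 1.6)
        out_um = ops.tubeness(Image2D(arr, pixel_size=0.031), 0.0496)
        assert np.allclose(out_px, out_um.pixels)


# ---------------------------------------------------------------------------
# binary morphology
# ---------------------------------------------------------------------------

class TestFillHoles:
    def test_annulus_becomes_disk(self):
        yy, xx = np.mgrid[:30, :30]
        d2 = (xx - 15) ** 2 + (yy - 15) ** 2
        annulus = (d2 <= 100) & (d2 >= 49)
        disk = d2 <= 100
        assert np.array_equal(ops.fill_holes(annulus), disk)

    def test_border_connected_bay_not_filled(self):
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        mask[0:5, 4] = False  # carve a bay open to the image border
        out = ops.fill_holes(mask)
        assert not out[3, 4]  # bay interior stays background

    def test_solid_disk_idempotent(self):
        yy, xx = np.mgrid[:20, :20]
        disk = (xx - 10) ** 2 + (yy - 10) ** 2 <= 36
        assert np.array_equal(ops.fill_holes(disk), disk)


class TestBinaryWatershed:
    def test_overlapping_disks_split_in_two(self, two_disk_mask):
        out = ops.binary_watershed(two_disk_mask)
        n = ndi.label(out, structure=np.ones((3, 3)))[1]
        assert n == 2

    def test_single_disk_unchanged(self):
        yy, xx = np.mgrid[:30, :30]
        disk = (xx - 15) ** 2 + (yy - 15) ** 2 <= 81
        out = ops.binary_watershed(disk)
        assert ndi.label(out, structure=np.ones((3, 3)))[1] == 1

    def test_empty_mask(self):
        assert not ops.binary_watershed(np.zeros((8, 8), bool)).any()

    def test_never_grows_and_count_non_decreasing(self, rng):
        mask = ndi.binary_dilation(rng.random((48, 48)) > 0.9,
                                   iterations=3)
        out = ops.binary_watershed(mask)
        assert np.all(out <= mask)
        s = np.ones((3, 3))
        assert ndi.label(out, structure=s)[1] >= ndi.label(mask, structure=s)[1]


# ---------------------------------------------------------------------------
# particle analysis
# ---------------------------------------------------------------------------

class TestAnalyzeParticles:
    def test_size_gate_keeps_only_large_square(self):
        mask = np.zeros((20, 40), bool)
        mask[2:5, 2:5] = True          # 9 px²
        mask[8:12, 20:24] = True       # 16 px²
        table = ops.analyze_particles(mask, 10, 1000)
        assert len(table) == 1
        assert table.iloc[0]["area_px2"] == 16

    def test_disk_circularity_near_one(self):
        yy, xx = np.mgrid[:30, :30]
        disk = (xx - 15) ** 2 + (yy - 15) ** 2 <= 100
        table = ops.analyze_particles(disk)
        assert 0.85 <= table.iloc[0]["circularity"] <= 1.0

    def test_circularity_gate_rejects_bar_keeps_square(self):
        mask = np.zeros((40, 60), bool)
        mask[4:6, 10:40] = True        # 2×30 bar
        mask[20:28, 20:28] = True      # 8×8 square
        table = ops.analyze_particles(mask, 0, np.inf, circ_min=0.6)
        assert len(table) == 1
        assert table.iloc[0]["area_px2"] == 64

    def test_partition_invariant(self, rng):
        mask = rng.random((40, 40)) > 0.6
        table = ops.analyze_particles(mask)
        assert table["area_px2"].sum() == mask.sum()
        assert table["label"].is_unique
        assert (table["circularity"] <= 1.0).all()

    def test_min_over_max_raises(self):
        with pytest.raises(ValueError):
            ops.analyze_particles(np.zeros((5, 5), bool), 10, 5)


# ---------------------------------------------------------------------------
# mask / image arithmetic
# ---------------------------------------------------------------------------

class TestArithmetic:
    def test_combine_masks(self, rng):
        a = rng.random((10, 10)) > 0.5
        empty = np.zeros((10, 10), bool)
        assert np.array_equal(ops.combine_masks(a, empty), a)
        assert np.array_equal(ops.combine_masks(a, a), a)
        b = ~a
        assert ops.combine_masks(a, b).sum() == a.sum() + b.sum()
        with pytest.raises(ValueError):
            ops.combine_masks(a, np.zeros((9, 9), bool))

    def test_max_intensity_projection(self, rng):
        base = rng.uniform(0, 10, (12, 12))
        impulse = np.zeros((12, 12))
        impulse[4, 4] = 99.0
        assert np.array_equal(ops.max_intensity_projection([base, base]), base)
        assert np.array_equal(ops.max_intensity_projection([base], [0]), base)
        out = ops.max_intensity_projection([np.zeros((12, 12)), impulse])
        assert np.array_equal(out, impulse)
        with pytest.raises(ValueError):
            ops.max_intensity_projection([base], [])

    def test_subtract_constant(self):
        img = np.array([[10.0, 20.0]])
        assert np.array_equal(ops.subtract_constant(img, 0), img)
        assert np.allclose(ops.subtract_constant(np.full((3, 3), 5.0), 5), 0.0)
        assert ops.subtract_constant(img, 15).tolist() == [[0.0, 5.0]]

    def test_average_images(self, rng):
        a, b = rng.uniform(0, 9, (6, 6)), rng.uniform(0, 9, (6, 6))
        assert np.allclose(ops.average_images(a, a), a)
        assert np.allclose(ops.average_images(np.zeros_like(a), a), a / 2)
        assert np.allclose(ops.average_images(a, b), ops.average_images(b, a))
        with pytest.raises(ValueError):
            ops.average_images(a, np.zeros((5, 5)))


class TestShapeAndMetadataPreservation:
    @pytest.mark.parametrize("op", [
        lambda im: ops.rolling_ball_subtract(im, 4),
        lambda im: ops.unsharp_mask(im, 2.0, 0.5),
        lambda im: ops.mean_filter(im, 1),
        lambda im: ops.median_filter(im, 1),
        lambda im: ops.tubeness(im, 1.5),
        lambda im: ops.subtract_constant(im, 1.0),
    ])
    def test_image2d_round_trip(self, rng, op):
        img = Image2D(rng.uniform(0, 100, (24, 26)), pixel_size=0.065)
        out = op(img)
        assert isinstance(out, Image2D)
        assert out.shape == img.shape
        assert out.pixel_size == img.pixel_size
        assert np.all(np.isfinite(out.pixels)) and out.pixels.min() >= 0
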