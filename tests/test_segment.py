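import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from zoneassay.segment import (
    BinaryMask,
    GrayFrame,
    PipelineParams,
    RGBFrame,
    binarize,
    center_crop,
    crop,
    erode,
    extract_cellfree,
    fill_holes,
    find_edges,
    max_entropy_threshold,
    run_pipeline,
    to_grayscale,
)
from zoneassay.simulate import render_frame

SCALE = 0.3525


def gray(arr, scale=SCALE):
    return GrayFrame(np.asarray(arr, dtype=np.uint8), scale)


def mask(arr, scale=SCALE):
    return BinaryMask(np.asarray(arr, dtype=bool), scale)


# ---------------------------------------------------------------- grayscale

class TestToGrayscale:
    def test_unweighted_mean(self):
        rgb = RGBFrame(np.full((4, 4, 3), (30, 60, 90), dtype=np.uint8), SCALE)
        assert np.all(to_grayscale(rgb).pixels == 60)

    def test_idempotent_on_gray_for_every_level(self):
        v = np.arange(256, dtype=np.uint8).reshape(16, 16)
        rgb = RGBFrame(np.repeat(v[:, :, None], 3, axis=2), SCALE)
        assert np.array_equal(to_grayscale(rgb).pixels, v)

    def test_truncation_not_rounding(self):
        rgb = RGBFrame(np.full((3, 3, 3), (255, 0, 0), dtype=np.uint8), SCALE)
        assert np.all(to_grayscale(rgb).pixels == 85)  # floor(255/3)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            RGBFrame(np.zeros((4, 4, 4), dtype=np.uint8), SCALE)


# --------------------------------------------------------------------- crop

class TestCrop:
    def test_full_frame_identity(self):
        f = gray(np.arange(100).reshape(10, 10) % 256)
        out = crop(f, 0, 0, 10, 10)
        assert np.array_equal(out.pixels, f.pixels)
        assert out.pixel_scale_px_per_um == f.pixel_scale_px_per_um

    def test_subregion_preserves_scale(self):
        f = gray(np.zeros((100, 100)))
        out = crop(f, 5, 7, 10, 10)
        assert out.shape == (10, 10)
        assert out.pixel_scale_px_per_um == SCALE

    @pytest.mark.parametrize("top,left,h,w", [(95, 0, 10, 5), (0, 0, 0, 5), (-1, 0, 5, 5)])
    def test_out_of_bounds_rejected(self, top, left, h, w):
        f = gray(np.zeros((100, 100)))
        with pytest.raises(ValueError):
            crop(f, top, left, h, w)

    def test_center_crop_fraction(self):
        f = gray(np.zeros((100, 100)))
        assert center_crop(f, 0.8).shape == (80, 80)
        assert center_crop(f, 1.0).shape == (100, 100)


# -------------------------------------------------------------------- Sobel

def sobel_oracle(img: np.ndarray) -> np.ndarray:
    """Direct 3x3 convolution with replicated borders (independent route)."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    padded = np.pad(img.astype(float), 1, mode="edge")
    h, w = img.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win = padded[i : i + 3, j : j + 3]
            gx = (win * kx).sum()
            gy = (win * kx.T).sum()
            out[i, j] = math.hypot(gx, gy)
    return np.clip(out, 0, 255).astype(np.uint8)


class TestFindEdges:
    def test_constant_frame_gives_zero(self):
        assert np.all(find_edges(gray(np.full((8, 8), 77))).pixels == 0)

    def test_vertical_step_response_localised(self):
        img = np.zeros((9, 9))
        img[:, 5:] = 255
        out = find_edges(gray(img)).pixels
        assert np.all(out[:, [4, 5]] == 255)  # clipped maximal response
        assert np.all(out[:, :3] == 0) and np.all(out[:, 7:] == 0)

    def test_matches_hand_convolution_on_integer_grid(self, rng):
        img = rng.integers(0, 256, size=(5, 5)).astype(np.uint8)
        assert np.array_equal(find_edges(gray(img)).pixels, sobel_oracle(img))

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            find_edges(gray(np.zeros((2, 5))))


# ------------------------------------------------------- max-entropy split

def kapur_oracle(hist) -> int:
    """Brute-force exhaustive scan in pure Python (independent route)."""
    total = float(sum(hist))
    p = [h / total for h in hist]
    best_t, best_psi = -1, -math.inf
    for t in range(256):
        p_low = sum(p[: t + 1])
        p_high = sum(p[t + 1 :])
        if p_low <= 0 or p_high <= 0:
            continue
        psi = 0.0
        for i in range(t + 1):
            if p[i] > 0:
                q = p[i] / p_low
                psi -= q * math.log(q)
        for i in range(t + 1, 256):
            if p[i] > 0:
                q = p[i] / p_high
                psi -= q * math.log(q)
        if psi > best_psi:
            best_psi, best_t = psi, t
    return best_t


class TestMaxEntropyThreshold:
    def test_symmetric_bimodal_ties_resolve_low(self):
        hist = np.zeros(256)
        hist[0:64] = 10
        hist[192:256] = 10
        # psi is constant (2 ln 64) for every split through the gap
        assert max_entropy_threshold(hist) == 63

    def test_degenerate_single_bin_rejected(self):
        hist = np.zeros(256)
        hist[42] = 1000
        with pytest.raises(ValueError, match="occupied bins"):
            max_entropy_threshold(hist)

    def test_matches_bruteforce_oracle_on_random_histograms(self, rng):
        for _ in range(200):
            hist = np.zeros(256)
            n_occ = rng.integers(2, 40)
            bins = rng.choice(256, size=n_occ, replace=False)
            hist[bins] = rng.integers(1, 1000, size=n_occ)
            assert max_entropy_threshold(hist) == kapur_oracle(hist)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            max_entropy_threshold(np.zeros(100))
        bad = np.ones(256)
        bad[0] = -1
        with pytest.raises(ValueError):
            max_entropy_threshold(bad)


# ----------------------------------------------------------------- binarize

class TestBinarize:
    def test_threshold_255_leaves_everything_cellfree(self):
        f = gray(np.arange(64).reshape(8, 8) * 4 % 256)
        assert np.all(binarize(f, 255).foreground)

    def test_threshold_0_on_bright_frame_empties_mask(self):
        f = gray(np.full((8, 8), 1))
        assert not np.any(binarize(f, 0).foreground)

    def test_polarity_is_complement_of_edges(self):
        f = gray([[0, 200], [200, 0]])
        fg = binarize(f, 100).foreground
        assert np.array_equal(fg, np.array([[True, False], [False, True]]))


# --------------------------------------------------------------- morphology

class TestErodeAndFill:
    def test_isolated_pixel_removed(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert not np.any(erode(mask(m)).foreground)

    def test_solid_3x3_block_leaves_centre(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        out = erode(mask(m)).foreground
        expected = np.zeros((5, 5), bool)
        expected[2, 2] = True
        assert np.array_equal(out, expected)

    def test_border_foreground_is_eroded(self):
        out = erode(mask(np.ones((4, 4), bool))).foreground
        assert not np.any(out[0]) and not np.any(out[:, 0])

    def test_zero_iterations_is_identity(self):
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        assert np.array_equal(erode(mask(m), 0).foreground, m)

    def test_negative_iterations_rejected(self):
        with pytest.raises(ValueError):
            erode(mask(np.zeros((3, 3), bool)), -1)

    def test_ring_fills_to_disc(self):
        m = np.zeros((7, 7), bool)
        m[1, 1:6] = m[5, 1:6] = m[1:6, 1] = m[1:6, 5] = True
        out = fill_holes(mask(m)).foreground
        assert np.all(out[1:6, 1:6])

    def test_border_connected_background_untouched(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        assert np.array_equal(fill_holes(mask(m)).foreground, m)

    def test_nested_rings_fill_against_floodfill_oracle(self):
        m = np.zeros((13, 13), bool)
        for lo, hi in [(1, 11), (4, 8)]:  # two concentric square rings
            m[lo, lo : hi + 1] = m[hi, lo : hi + 1] = True
            m[lo : hi + 1, lo] = m[lo : hi + 1, hi] = True
        out = fill_holes(mask(m)).foreground
        assert np.array_equal(out, _floodfill_oracle(m))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(m=hnp.arrays(bool, (16, 16)))
    def test_erosion_shrinks_and_fill_grows(self, m):
        bm = mask(m)
        filled = fill_holes(bm)
        assert np.all(filled.foreground >= bm.foreground)  # never removes
        eroded = erode(filled)
        assert np.all(eroded.foreground <= filled.foreground)  # never adds

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(m=hnp.arrays(bool, (16, 16)))
    def test_fill_holes_matches_floodfill_oracle(self, m):
        assert np.array_equal(fill_holes(mask(m)).foreground, _floodfill_oracle(m))


def _floodfill_oracle(m: np.ndarray) -> np.ndarray:
    """4-connected BFS from the border over background (independent route)."""
    h, w = m.shape
    reach = np.zeros((h, w), bool)
    stack = [
        (i, j)
        for i in range(h)
        for j in range(w)
        if (i in (0, h - 1) or j in (0, w - 1)) and not m[i, j]
    ]
    for p in stack:
        reach[p] = True
    while stack:
        i, j = stack.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and not m[ni, nj] and not reach[ni, nj]:
                reach[ni, nj] = True
                stack.append((ni, nj))
    return m | ~reach


# -------------------------------------------------------- particle analysis

class TestExtractCellfree:
    def test_speck_below_minimum_is_discarded(self):
        # 19.6 mm^2 disc plus a 0.05 mm^2 speck at the reference scale
        m = np.zeros((1900, 1900), bool)
        yy, xx = np.ogrid[:1900, :1900]
        r_disc = math.sqrt(19.6e6 / math.pi) * SCALE  # px
        m[(yy - 950) ** 2 + (xx - 950) ** 2 <= r_disc**2] = True
        r_speck = math.sqrt(0.05e6 / math.pi) * SCALE
        m[(yy - 60) ** 2 + (xx - 60) ** 2 <= r_speck**2] = True
        res = extract_cellfree(mask(m))
        assert res.n_components_in_range == 1
        assert res.area_mm2 == pytest.approx(19.6, rel=0.01)

    def test_empty_mask_warns_zero_area(self):
        res = extract_cellfree(mask(np.zeros((10, 10), bool)))
        assert res.area_um2 == 0.0 and res.n_components_in_range == 0
        assert res.warnings

    def test_single_pixel_below_minimum(self):
        m = np.zeros((10, 10), bool)
        m[5, 5] = True
        res = extract_cellfree(mask(m))
        assert res.n_components_in_range == 0
        # raw single-pixel area would be 1/scale^2 ~ 8.05 um^2, below 1e5
        assert (1 / SCALE**2) == pytest.approx(8.05, abs=0.01)

    def test_multiple_survivors_are_unioned(self):
        m = np.zeros((800, 1600), bool)
        yy, xx = np.ogrid[:800, :1600]
        for cx in (400, 1200):
            m[(yy - 400) ** 2 + (xx - cx) ** 2 <= 200**2] = True
        res = extract_cellfree(mask(m), min_um2=1e5, max_um2=7e8)
        assert res.n_components_in_range == 2
        expected_um2 = 2 * m[:, :800].sum() / SCALE**2
        assert res.area_um2 == pytest.approx(expected_um2, rel=1e-6)


# ------------------------------------------------------------ full pipeline

class TestRunPipeline:
    def test_calibrated_disc_measurement(self, small_config, small_series):
        series, truth = small_series
        res = run_pipeline(series.frame(0))
        # the measured contour may sit anywhere inside the soft front ramp
        # (plus one erosion pixel), so the area tolerance scales with
        # ramp-width / zone-radius — significant for this scaled-down zone
        scale = small_config.pixel_scale_px_per_um
        r_px = truth.radius_um[0] * scale
        ramp_px = (
            small_config.front_ramp_cell_diameters
            * small_config.texture_cell_diameter_um
            * scale
        )
        rel_tol = 2 * (ramp_px / 2 + 2) / r_px
        assert res.area_mm2 == pytest.approx(truth.true_area_mm2[0], rel=rel_tol)

    def test_deterministic_for_identical_input(self, small_series):
        series, _ = small_series
        frame = series.frame(0)
        r1 = run_pipeline(frame)
        r2 = run_pipeline(RGBFrame(frame.pixels.copy(), frame.pixel_scale_px_per_um))
        assert r1.area_um2 == r2.area_um2
        assert np.array_equal(r1.component_mask.foreground, r2.component_mask.foreground)

    def test_pure_monolayer_yields_no_component(self, small_config):
        # front fully closed: fast promoter at the final frame
        import dataclasses

        cfg = dataclasses.replace(
            small_config, front_velocity_um_per_h=200.0, duration_h=6.0
        )
        rgb, truth_mask = render_frame(cfg, 6.0)  # r = 750 - 1200 -> closed
        assert not truth_mask.foreground.any()
        res = run_pipeline(rgb)
        assert res.n_components_in_range == 0 and res.area_um2 == 0.0

    def test_debris_shifts_area_by_under_one_percent(self, small_config):
        import dataclasses

        clean = dataclasses.replace(small_config, debris_density_per_mm2=0.0)
        dirty = dataclasses.replace(small_config, debris_density_per_mm2=8.0)
        a_clean = run_pipeline(render_frame(clean, 0.0)[0]).area_um2
        a_dirty = run_pipeline(render_frame(dirty, 0.0)[0]).area_um2
        assert a_dirty == pytest.approx(a_clean, rel=0.01)

    def test_intermediates_retrievable(self, small_series):
        series, _ = small_series
        params = PipelineParams(keep_intermediates=True)
        res = run_pipeline(series.frame(0), params)
        assert set(res.stages) >= {"gray", "cropped", "edges", "threshold", "binary", "eroded", "filled"}

    def test_degenerate_frame_downgraded_to_zero_area(self):
        rgb = RGBFrame(np.full((32, 32, 3), 128, dtype=np.uint8), SCALE)
        with pytest.warns(UserWarning, match="degenerate"):
            res = run_pipeline(rgb)
        assert res.area_um2 == 0.0 and res.warnings
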