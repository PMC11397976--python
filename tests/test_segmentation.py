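"""Valley thresholding, automatic bounds, binarization and despeckling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopyscope.errors import ConfigurationError, NotBimodalError
from canopyscope.image_model import BinaryMask, WavebandImage
from canopyscope.segmentation import (
    DespeckleParams,
    SegmentationConfig,
    auto_bounds,
    despeckle_mask,
    find_valley_threshold,
    segment,
    smooth_histogram,
    threshold_mask,
)
from canopyscope.synthetic_scenes import generate

from conftest import (
    brute_components,
    brute_peaks,
    brute_smooth,
    brute_valley,
    make_hist,
    triangular_bump,
)


class TestSmoothHistogram:
    def test_window_one_is_identity(self):
        counts = np.arange(256)
        np.testing.assert_array_equal(
            smooth_histogram(make_hist(counts), 1), counts.astype(float)
        )

    def test_hand_moving_average(self):
        counts = np.zeros(256, dtype=int)
        counts[100:105] = [5, 1, 9, 1, 5]
        smoothed = smooth_histogram(make_hist(counts), 3)
        assert smoothed[101] == pytest.approx(5.0)
        assert smoothed[102] == pytest.approx(11 / 3)
        assert smoothed[103] == pytest.approx(5.0)

    @pytest.mark.parametrize("window", [1, 3, 5, 9])
    def test_constant_histogram_unchanged(self, window):
        counts = np.full(256, 17)
        np.testing.assert_allclose(
            smooth_histogram(make_hist(counts), window), 17.0
        )

    @pytest.mark.parametrize("window", [0, 2, 4, -1])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ConfigurationError):
            smooth_histogram(make_hist(np.zeros(256)), window)


class TestFindValleyThreshold:
    def test_v_shaped_valley(self):
        # V-shaped counts over [60,180] with minimum at 117
        counts = np.zeros(256, dtype=int)
        for i in range(256):
            counts[i] = abs(i - 117) + 3
        res = find_valley_threshold(make_hist(counts), 60, 180, window=1)
        assert res.threshold == brute_valley(counts, 60, 180, 1) == 117
        assert res.method == "bounded_valley"

    def test_uniform_ties_break_to_lowest_intensity(self):
        counts = np.full(256, 5)
        res = find_valley_threshold(make_hist(counts), 30, 200, window=5)
        assert res.threshold == 30

    def test_smoothed_argmin_includes_bound_bins(self):
        # the bins at the bounds are smoothed with their outside neighbours
        # (zeros here), so the minimum lands on the bound itself
        counts = np.zeros(256, dtype=int)
        counts[100:105] = [5, 1, 9, 1, 5]
        res = find_valley_threshold(make_hist(counts), 100, 104, window=3)
        assert res.threshold == brute_valley(counts, 100, 104, 3) == 100

    def test_bad_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            find_valley_threshold(make_hist(np.zeros(256)), 180, 60)

    @settings(derandomize=True, max_examples=200)
    @given(
        counts=st.lists(st.integers(0, 10_000), min_size=256, max_size=256),
        bounds=st.tuples(st.integers(0, 255), st.integers(0, 255)),
        window=st.sampled_from([1, 3, 5, 7, 9]),
    )
    def test_matches_brute_force_oracle(self, counts, bounds, window):
        lo, hi = min(bounds), max(bounds)
        res = find_valley_threshold(make_hist(counts), lo, hi, window)
        assert res.threshold == brute_valley(counts, lo, hi, window)


class TestAutoBounds:
    def test_two_clean_modes(self):
        counts = np.zeros(256, dtype=int)
        triangular_bump(counts, 12, 1000, 6)
        triangular_bump(counts, 200, 600, 6)
        assert auto_bounds(make_hist(counts), window=5) == (12, 200)

    def test_unimodal_raises(self):
        counts = np.zeros(256, dtype=int)
        triangular_bump(counts, 80, 1000, 10)
        with pytest.raises(NotBimodalError, match="manual threshold bounds"):
            auto_bounds(make_hist(counts), window=5)

    def test_three_modes_takes_two_leftmost(self):
        counts = np.zeros(256, dtype=int)
        triangular_bump(counts, 10, 800, 6)
        triangular_bump(counts, 90, 1000, 6)
        triangular_bump(counts, 220, 900, 6)
        assert auto_bounds(make_hist(counts), window=5) == (10, 90)

    def test_agrees_with_brute_force_peak_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = np.zeros(256, dtype=int)
            centers = sorted(rng.choice(np.arange(8, 248, 16), 3, replace=False))
            for c in centers:
                triangular_bump(counts, int(c), int(rng.integers(200, 1000)), 6)
            from canopyscope.segmentation import find_histogram_peaks

            smoothed = smooth_histogram(make_hist(counts), 5)
            assert list(find_histogram_peaks(smoothed, 0.05)) == brute_peaks(
                smoothed, 0.05
            )


class TestThresholdMask:
    def test_extremes_and_strictness(self):
        img = WavebandImage(pixels=np.array([[10, 200]], dtype=np.uint8), waveband="cfi")
        assert threshold_mask(img, 255).pixels.tolist() == [[False, False]]
        assert threshold_mask(img, 100).pixels.tolist() == [[False, True]]
        assert threshold_mask(img, 10).pixels.tolist() == [[False, True]]  # strict >
        ones = WavebandImage(pixels=np.ones((3, 3), dtype=np.uint8), waveband="cfi")
        assert threshold_mask(ones, 0).pixels.all()

    @settings(derandomize=True, max_examples=50)
    @given(
        seed=st.integers(0, 10_000),
        t1=st.integers(0, 255),
        t2=st.integers(0, 255),
    )
    def test_monotone_in_threshold(self, seed, t1, t2):
        t1, t2 = min(t1, t2), max(t1, t2)
        rng = np.random.default_rng(seed)
        img = WavebandImage(
            pixels=rng.integers(0, 256, (12, 12), dtype=np.uint8), waveband="cfi"
        )
        high = threshold_mask(img, t2).pixels
        low = threshold_mask(img, t1).pixels
        assert (high & ~low).sum() == 0  # mask(t2) subset of mask(t1)


class TestDespeckle:
    def test_empty_mask_stays_empty(self):
        m = BinaryMask(pixels=np.zeros((5, 5), dtype=bool))
        out = despeckle_mask(m, DespeckleParams(min_component_px=5))
        assert out.n_foreground == 0

    def test_small_components_removed(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[1:4, 1:5] = True  # 12-px blob
        mask[6, 0] = mask[6, 1] = True  # 2-px speckle
        mask[0, 7] = mask[1, 7] = True  # 2-px speckle
        out = despeckle_mask(
            BinaryMask(pixels=mask), DespeckleParams(min_component_px=5, connectivity=8)
        )
        assert out.n_foreground == 12
        assert out.pixels[1:4, 1:5].all()

    def test_diagonal_chain_connectivity(self):
        mask = np.zeros((8, 8), dtype=bool)
        for i in range(6):
            mask[i, i] = True
        kept8 = despeckle_mask(
            BinaryMask(pixels=mask), DespeckleParams(min_component_px=5, connectivity=8)
        )
        kept4 = despeckle_mask(
            BinaryMask(pixels=mask), DespeckleParams(min_component_px=5, connectivity=4)
        )
        assert kept8.n_foreground == 6  # one 6-px component
        assert kept4.n_foreground == 0  # six 1-px components
        # cross-check component structure with the flood-fill oracle
        assert len(brute_components(mask, 8)) == 1
        assert len(brute_components(mask, 4)) == 6

    @settings(derandomize=True, max_examples=40)
    @given(
        seed=st.integers(0, 10_000),
        min_px=st.integers(1, 10),
        connectivity=st.sampled_from([4, 8]),
    )
    def test_idempotent_and_subset(self, seed, min_px, connectivity):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16)) < 0.3
        params = DespeckleParams(min_component_px=min_px, connectivity=connectivity)
        once = despeckle_mask(BinaryMask(pixels=mask), params)
        twice = despeckle_mask(once, params)
        assert (once.pixels & ~mask).sum() == 0
        np.testing.assert_array_equal(once.pixels, twice.pixels)
        # surviving components match the oracle's size filter
        expected = sum(
            len(c) for c in brute_components(mask, connectivity) if len(c) >= min_px
        )
        assert once.n_foreground == expected


class TestSegment:
    def test_noiseless_scene_recovers_ground_truth(self, clean_scene):
        image_set, truth = clean_scene
        mask, res = segment(image_set, SegmentationConfig(lo=40, hi=160))
        np.testing.assert_array_equal(mask.pixels, truth.mask.pixels)
        assert 10 < res.threshold < 180

    def test_speckles_removed_by_size_filter(self, suite_specs):
        image_set, truth = generate(suite_specs["speckled"], set_id="speckled")
        mask, _ = segment(image_set, SegmentationConfig(lo=40, hi=160))
        np.testing.assert_array_equal(mask.pixels, truth.mask.pixels)

    def test_auto_bounds_path(self, clean_scene):
        image_set, truth = clean_scene
        mask, res = segment(image_set, SegmentationConfig())
        assert res.method == "auto_peaks"
        assert res.peaks[0] < res.threshold < res.peaks[1] or res.threshold in res.bounds
        np.testing.assert_array_equal(mask.pixels, truth.mask.pixels)

    def test_blank_scene_gives_empty_mask(self, suite_specs):
        image_set, truth = generate(suite_specs["blank"], set_id="blank")
        assert truth.n_plant_px == 0
        mask, _ = segment(image_set, SegmentationConfig(lo=40, hi=160))
        assert mask.n_foreground == 0

    def test_no_bounds_and_no_auto_is_config_error(self, clean_scene):
        image_set, _ = clean_scene
        with pytest.raises(ConfigurationError):
            segment(image_set, SegmentationConfig(auto_bounds=False))

    def test_median_prefilter_suppresses_salt_noise(self, suite_specs):
        # lone hot pixels inside the background vanish under the 3x3 median
        from dataclasses import replace

        image_set, truth = generate(suite_specs["clean"], set_id="clean")
        px = image_set["cfi"].pixels.copy()
        px[2, 2] = 255
        image_set.images["cfi"] = WavebandImage(pixels=px, waveband="cfi")
        cfg = SegmentationConfig(
            lo=40,
            hi=160,
            despeckle=DespeckleParams(min_component_px=1, median_prefilter=True),
        )
        mask, _ = segment(image_set, cfg)
        assert not mask.pixels[2, 2]
        # the median also smooths the plant outline, so compare by overlap
        inter = (mask.pixels & truth.mask.pixels).sum()
        union = (mask.pixels | truth.mask.pixels).sum()
        assert inter / union > 0.95
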