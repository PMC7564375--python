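"""Thresholded channel masks, the clonal region and area proportions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonescreen.hcs import (
    ChannelMasks,
    ClassifierConfig,
    CloneRegion,
    SmoothingSpec,
    WellMosaic,
    area_proportions,
    clone_region,
    compute_masks,
    gaussian_lowpass,
)

from conftest import gaussian_lowpass_oracle


def _mosaic(blue, green, red):
    return WellMosaic("X1", np.asarray(blue), np.asarray(green), np.asarray(red))


def _uniform_mosaic(value: float, shape=(64, 64)):
    z = np.zeros(shape, dtype=int)
    return _mosaic(z, z, np.full(shape, value, dtype=int))


class TestThresholding:
    def test_strictly_above_threshold_is_positive(self, default_config):
        masks = compute_masks(_uniform_mosaic(126), default_config)
        assert masks.red_positive.all()

    def test_exactly_at_threshold_is_negative(self, default_config):
        """Comparisons are strict: a flat raster at 125 yields an empty red mask."""
        masks = compute_masks(_uniform_mosaic(125), default_config)
        assert not masks.red_positive.any()

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            _mosaic(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((5, 5)))

    def test_disc_mask_matches_oracle_thresholding(self, default_config):
        """The red mask equals the 125-crossing of the oracle-smoothed disc."""
        shape = (120, 120)
        rows, cols = np.ogrid[: shape[0], : shape[1]]
        disc = ((rows - 60) ** 2 + (cols - 60) ** 2 <= 30**2) * 1000
        mosaic = _mosaic(np.zeros(shape, int), np.zeros(shape, int), disc)
        masks = compute_masks(mosaic, default_config)
        oracle = gaussian_lowpass_oracle(disc.astype(float), default_config.red_spec) > 125
        assert np.array_equal(masks.red_positive, oracle)
        assert masks.red_positive.sum() > disc.astype(bool).sum()  # mask spreads past the disc

    @given(data=st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mask_monotone_in_intensity(self, data):
        """Raising intensities anywhere never switches a positive pixel off."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        img = rng.integers(0, 300, size=(32, 32))
        bump = rng.integers(0, 50, size=(32, 32))
        spec = SmoothingSpec(9, 3.0)
        before = gaussian_lowpass(img, spec) > 125
        after = gaussian_lowpass(img + bump, spec) > 125
        assert np.all(after[before])


class TestCloneRegion:
    def _masks(self, red, green, blue=None):
        shape = np.asarray(red).shape
        blue = np.zeros(shape, bool) if blue is None else blue
        return ChannelMasks(np.asarray(red), np.asarray(green), blue)

    def test_region_is_red_when_green_empty(self):
        red = np.zeros((50, 50), bool)
        red[:10, :50] = True
        region = clone_region(self._masks(red, np.zeros((50, 50), bool)))
        assert region.area == 500
        assert np.array_equal(region.mask, red)

    def test_disjoint_masks_add(self):
        red = np.zeros((50, 50), bool)
        red[:4, :50] = True  # 200 px
        green = np.zeros((50, 50), bool)
        green[10:16, :50] = True  # 300 px
        assert clone_region(self._masks(red, green)).area == 500

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_union_area_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        red = rng.random((50, 50)) < 0.3
        green = rng.random((50, 50)) < 0.3
        region = clone_region(self._masks(red, green))
        assert region.area == int(red.sum() + green.sum() - (red & green).sum())
        # an all-positive blue mask never enlarges the region
        with_blue = clone_region(self._masks(red, green, np.ones((50, 50), bool)))
        assert np.array_equal(with_blue.mask, region.mask)


class TestAreaProportions:
    def test_subset_counts(self):
        region_mask = np.zeros((20, 20), bool)
        region_mask[:10, :10] = True  # 100 px
        red = region_mask.copy()
        red[0, :10] = False  # 90 px subset
        masks = ChannelMasks(red, region_mask.copy(), np.zeros((20, 20), bool))
        ap_red, ap_green, ap_blue = area_proportions(masks, CloneRegion(region_mask, 100))
        assert (ap_red, ap_green, ap_blue) == (0.90, 1.00, 0.0)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_pixel_count_oracle_and_sum_rule(self, seed):
        rng = np.random.default_rng(seed)
        red = rng.random((50, 50)) < 0.25
        green = rng.random((50, 50)) < 0.25
        blue = rng.random((50, 50)) < 0.25
        red[0, 0] = True  # non-empty region
        masks = ChannelMasks(red, green, blue)
        region = clone_region(masks)
        ap_red, ap_green, ap_blue = area_proportions(masks, region)
        n = region.area
        assert ap_red == sum(red.flat) / n
        assert ap_green == sum(green.flat) / n
        assert ap_blue == int((blue & region.mask).sum()) / n
        # each region pixel is red or green, so the proportions overlap-count to >= 1
        assert ap_red + ap_green >= 1.0
        assert max(ap_red, ap_green, ap_blue) <= 1.0

    def test_empty_region_rejected(self):
        empty = np.zeros((5, 5), bool)
        masks = ChannelMasks(empty, empty, empty)
        with pytest.raises(ValueError, match="undefined"):
            area_proportions(masks, CloneRegion(empty, 0))
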