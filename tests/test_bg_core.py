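import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leukoseg import (
    SegmentationParams,
    bg_difference,
    binarize,
    label_regions,
    size_filter,
)
from conftest import random_binary_mask
from oracles import flood_fill_components


def _pixel(r, g, b):
    return np.array([[[r, g, b]]], dtype=np.uint8)


class TestSegmentationParams:
    def test_defaults(self):
        p = SegmentationParams()
        assert p.t0 == 80
        assert p.min_nucleus_area_px == 500
        assert p.connectivity == 8

    @pytest.mark.parametrize("t0", [-1, 256])
    def test_t0_out_of_range(self, t0):
        with pytest.raises(ValueError):
            SegmentationParams(t0=t0)

    @pytest.mark.parametrize("t0", [10, 200])
    def test_t0_outside_band_warns(self, t0):
        with pytest.warns(UserWarning):
            SegmentationParams(t0=t0)

    def test_bad_connectivity(self):
        with pytest.raises(ValueError):
            SegmentationParams(connectivity=6)

    def test_bad_min_area(self):
        with pytest.raises(ValueError):
            SegmentationParams(min_nucleus_area_px=0)


class TestBgDifference:
    def test_forced_arithmetic(self):
        assert bg_difference(_pixel(200, 15, 135))[0, 0] == 120

    def test_saturation_clamp(self):
        assert bg_difference(_pixel(180, 120, 100))[0, 0] == 0

    def test_equal_channels(self):
        assert bg_difference(_pixel(42, 99, 99))[0, 0] == 0

    def test_dtype_and_shape(self, rng):
        img = rng.integers(0, 256, size=(17, 23, 3), dtype=np.uint8)
        diff = bg_difference(img)
        assert diff.dtype == np.uint8
        assert diff.shape == (17, 23)

    def test_against_widened_integer_oracle(self, rng):
        for _ in range(100):
            img = rng.integers(0, 256, size=(12, 12, 3), dtype=np.uint8)
            diff = bg_difference(img)
            for r in range(12):
                for c in range(12):
                    expected = max(int(img[r, c, 2]) - int(img[r, c, 1]), 0)
                    assert int(diff[r, c]) == expected

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            bg_difference(np.zeros((4, 4), dtype=np.uint8))


class TestBinarize:
    def test_all_zero_map(self):
        for t0 in (50, 80, 100):
            assert binarize(np.zeros((5, 5), dtype=np.uint8), t0).sum() == 0

    @pytest.mark.parametrize("t0", [50, 80, 100])
    def test_nucleus_value_is_foreground(self, t0):
        # nucleus-interior pixels carry values above 110, hence above any
        # threshold in the empirical band
        diff = np.full((3, 3), 111, dtype=np.uint8)
        assert binarize(diff, t0).all()

    def test_stain_value_below_band_floor(self):
        diff = np.full((3, 3), 49, dtype=np.uint8)
        assert binarize(diff, 50).sum() == 0

    def test_inclusive_threshold(self):
        diff = np.array([[79, 80, 81]], dtype=np.uint8)
        assert binarize(diff, 80).tolist() == [[0, 1, 1]]

    def test_monotone_in_threshold(self, rng):
        for _ in range(50):
            diff = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
            lo = binarize(diff, 55)
            hi = binarize(diff, 90)
            assert not (hi & ~lo).any()  # foreground(hi t0) subset of lower

    @given(st.integers(min_value=0, max_value=255), st.integers(min_value=0, max_value=255))
    @settings(max_examples=50, deadline=None)
    def test_single_pixel_contract(self, value, t0):
        out = binarize(np.array([[value]], dtype=np.uint8), t0)
        assert out[0, 0] == (1 if value >= t0 else 0)


class TestLabelRegions:
    def test_empty_mask(self):
        lab = label_regions(np.zeros((6, 6), dtype=np.uint8))
        assert lab.n_labels == 0
        assert lab.labels.sum() == 0

    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[1, 1] = mask[2, 2] = 1
        assert label_regions(mask, connectivity=8).n_labels == 1
        assert label_regions(mask, connectivity=4).n_labels == 2

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            label_regions(np.full((3, 3), 2, dtype=np.uint8))

    def test_labels_contiguous_and_raster_ordered(self, rng):
        mask = random_binary_mask(rng, (30, 30), 0.3)
        lab = label_regions(mask)
        values = np.unique(lab.labels)
        assert values.tolist() == list(range(lab.n_labels + 1)) or \
            values.tolist() == list(range(1, lab.n_labels + 1))
        # first occurrence of label k precedes first occurrence of k+1
        flat = lab.labels.ravel()
        firsts = [np.flatnonzero(flat == k)[0] for k in range(1, lab.n_labels + 1)]
        assert firsts == sorted(firsts)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_partition_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(30):
            mask = random_binary_mask(rng, (25, 25), 0.4)
            lab = label_regions(mask, connectivity=connectivity)
            comps = flood_fill_components(mask, connectivity)
            assert lab.n_labels == len(comps)
            for k, comp in enumerate(comps, start=1):
                got = set(zip(*np.nonzero(lab.labels == k)))
                assert got == comp


class TestSizeFilter:
    def test_small_component_removed(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[2, 2:5] = 1  # 3 px
        out = size_filter(label_regions(mask), 50)
        assert out.n_labels == 0
        assert out.labels.sum() == 0

    def test_exact_boundary_kept(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[1:3, 1:4] = 1  # 6 px
        out = size_filter(label_regions(mask), 6)
        assert out.n_labels == 1

    def test_survivors_match_area_census_oracle(self, rng):
        for _ in range(30):
            mask = random_binary_mask(rng, (30, 30), 0.4)
            min_area = int(rng.integers(1, 12))
            lab = label_regions(mask)
            out = size_filter(lab, min_area)
            surviving = {
                frozenset(zip(*np.nonzero(out.labels == k)))
                for k in range(1, out.n_labels + 1)
            }
            expected = {
                frozenset(comp)
                for comp in flood_fill_components(mask, 8)
                if len(comp) >= min_area
            }
            assert surviving == expected

    def test_idempotent(self, rng):
        for _ in range(25):
            mask = random_binary_mask(rng, (25, 25), 0.4)
            once = size_filter(label_regions(mask), 5)
            twice = size_filter(once, 5)
            assert np.array_equal(once.labels, twice.labels)
            assert once.n_labels == twice.n_labels

    def test_no_pixel_gains_foreground(self, rng):
        mask = random_binary_mask(rng, (20, 20), 0.5)
        out = size_filter(label_regions(mask), 4)
        assert not ((out.labels > 0) & (mask == 0)).any()


def test_pipeline_stages_are_local(rng):
    """No global statistics: editing one corner never changes the other."""
    img = rng.integers(0, 256, size=(40, 40, 3), dtype=np.uint8)
    edited = img.copy()
    edited[:10, :10] = rng.integers(0, 256, size=(10, 10, 3), dtype=np.uint8)
    a = binarize(bg_difference(img), 80)
    b = binarize(bg_difference(edited), 80)
    assert np.array_equal(a[20:, 20:], b[20:, 20:])
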