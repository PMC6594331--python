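import numpy as np
import pytest

from leukoseg import (
    GroupingParams,
    extract_regions,
    group_lobes,
    label_regions,
    locate_nuclei,
    project_bbox,
)
from leukoseg.grouping import Region, group_mask
from conftest import random_binary_mask
from oracles import closure_partition, minmax_bbox


def _region(label, x, y, area=10):
    return Region(
        label=label, area_px=area, centroid_x=float(x), centroid_y=float(y),
        pixels=(np.array([int(y)]), np.array([int(x)])),
    )


class TestExtractRegions:
    def test_single_pixel(self):
        mask = np.zeros((8, 10), dtype=np.uint8)
        mask[4, 7] = 1
        (region,) = extract_regions(label_regions(mask))
        assert region.area_px == 1
        assert region.centroid_x == 7.0
        assert region.centroid_y == 4.0

    def test_square_block(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[0:2, 0:2] = 1
        (region,) = extract_regions(label_regions(mask))
        assert region.area_px == 4
        assert region.centroid_x == 0.5
        assert region.centroid_y == 0.5

    def test_against_per_pixel_accumulation_oracle(self, rng):
        for _ in range(25):
            mask = random_binary_mask(rng, (20, 20), 0.35)
            lab = label_regions(mask)
            regions = extract_regions(lab)
            assert len(regions) == lab.n_labels
            for region in regions:
                rows, cols = np.nonzero(lab.labels == region.label)
                assert region.area_px == len(rows)
                assert region.centroid_x == pytest.approx(sum(cols) / len(cols))
                assert region.centroid_y == pytest.approx(sum(rows) / len(rows))


class TestGroupLobes:
    PARAMS = GroupingParams(s0_px=100, d0_px=10.0)

    def test_two_distant_regions_independent(self):
        groups = group_lobes([_region(1, 0, 0), _region(2, 50, 0)], self.PARAMS)
        assert len(groups) == 2

    def test_single_region(self):
        assert len(group_lobes([_region(1, 3, 3)], self.PARAMS)) == 1

    def test_empty(self):
        assert group_lobes([], self.PARAMS) == []

    def test_chain_transitivity(self):
        # A-B and B-C within d0, A-C beyond: one nucleus
        a, b, c = _region(1, 0, 0), _region(2, 9, 0), _region(3, 18, 0)
        groups = group_lobes([a, b, c], self.PARAMS)
        assert len(groups) == 1
        assert [r.label for r in groups[0]] == [1, 2, 3]

    def test_large_region_exempt_from_merging(self):
        big = _region(1, 0, 0, area=101)
        small = _region(2, 5, 0, area=10)
        groups = group_lobes([big, small], self.PARAMS)
        assert len(groups) == 2

    def test_tie_at_exactly_d0_merges(self):
        groups = group_lobes([_region(1, 0, 0), _region(2, 10, 0)], self.PARAMS)
        assert len(groups) == 1

    def test_order_invariance(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            regions = [
                _region(i + 1, rng.uniform(0, 60), rng.uniform(0, 60),
                        area=int(rng.integers(1, 150)))
                for i in range(n)
            ]
            ref = group_lobes(regions, self.PARAMS)
            perm = list(regions)
            rng.shuffle(perm)
            assert group_lobes(perm, self.PARAMS) == ref

    def test_against_transitive_closure_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 12))
            centroids = [(rng.uniform(0, 50), rng.uniform(0, 50)) for _ in range(n)]
            areas = [int(rng.integers(1, 150)) for _ in range(n)]
            regions = [
                _region(i + 1, centroids[i][0], centroids[i][1], areas[i])
                for i in range(n)
            ]
            got = [
                frozenset(r.label - 1 for r in g)
                for g in group_lobes(regions, self.PARAMS)
            ]
            expected = closure_partition(centroids, areas,
                                         self.PARAMS.s0_px, self.PARAMS.d0_px)
            assert sorted(got, key=min) == expected

    def test_param_validation(self):
        with pytest.raises(ValueError):
            GroupingParams(s0_px=0)
        with pytest.raises(ValueError):
            GroupingParams(d0_px=0)


class TestProjectBbox:
    def test_single_pixel(self):
        mask = np.zeros((12, 12), dtype=np.uint8)
        mask[5, 9] = 1
        box = project_bbox(mask)
        assert (box.x_l, box.x_r, box.y_t, box.y_b) == (9, 9, 5, 5)
        assert (box.x_c, box.y_c, box.w, box.h) == (9, 5, 0, 0)

    def test_filled_rectangle(self):
        mask = np.zeros((40, 60), dtype=np.uint8)
        mask[10:21, 30:52] = 1
        box = project_bbox(mask)
        assert (box.x_l, box.x_r, box.y_t, box.y_b) == (30, 51, 10, 20)
        assert box.x_c == 40  # floor of 40.5
        assert box.y_c == 15
        assert (box.w, box.h) == (21, 10)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            project_bbox(np.zeros((4, 4), dtype=np.uint8))

    def test_equals_minmax_oracle(self, rng):
        for _ in range(200):
            mask = random_binary_mask(rng, (30, 30), 0.1)
            if not mask.any():
                continue
            box = project_bbox(mask)
            assert (box.x_l, box.x_r, box.y_t, box.y_b) == minmax_bbox(mask)

    def test_all_pixels_inside_box(self, rng):
        mask = random_binary_mask(rng, (25, 25), 0.2)
        if not mask.any():
            mask[3, 3] = 1
        box = project_bbox(mask)
        rows, cols = np.nonzero(mask)
        assert (cols >= box.x_l).all() and (cols <= box.x_r).all()
        assert (rows >= box.y_t).all() and (rows <= box.y_b).all()

    def test_union_never_shrinks_bbox(self, rng):
        a = random_binary_mask(rng, (20, 20), 0.15)
        b = random_binary_mask(rng, (20, 20), 0.15)
        a[2, 2] = b[15, 15] = 1
        box_a = project_bbox(a)
        box_ab = project_bbox(a | b)
        assert box_ab.x_l <= box_a.x_l and box_ab.x_r >= box_a.x_r
        assert box_ab.y_t <= box_a.y_t and box_ab.y_b >= box_a.y_b


class TestLocateNuclei:
    def test_detection_invariants(self, rng):
        mask = random_binary_mask(rng, (50, 50), 0.25)
        lab = label_regions(mask)
        params = GroupingParams(s0_px=30, d0_px=8.0)
        dets = locate_nuclei(lab, params)
        regions = extract_regions(lab)
        assert sum(d.n_lobes for d in dets) == len(regions)
        for det in dets:
            assert det.x_l <= det.x_r and det.y_t <= det.y_b
            assert det.w == det.x_r - det.x_l
            assert det.h == det.y_b - det.y_t
            assert det.x_c == (det.x_l + det.x_r) // 2
            assert det.y_c == (det.y_t + det.y_b) // 2
            assert det.n_lobes == len(det.member_labels)
            assert det.area_px >= det.n_lobes

    def test_group_mask_matches_members(self, rng):
        mask = random_binary_mask(rng, (30, 30), 0.3)
        lab = label_regions(mask)
        regions = extract_regions(lab)
        rendered = group_mask(regions, lab.shape)
        assert np.array_equal(rendered, mask.astype(bool))
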