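"""Threshold/largest-component/bounding-box cropping rules."""

import numpy as np
import pytest

from lumbarseg.errors import BoundsError, EmptyROIError, ParameterError
from lumbarseg.grids import BoundingBox3D, Heatmap
from lumbarseg.phantom import PhantomConfig, generate_phantom
from lumbarseg.preprocess import make_heatmap
from lumbarseg.roi_crop import (
    bbox_from_mask,
    crop_to_bbox,
    largest_component,
    roi_from_heatmap,
    threshold_mask,
)


def flood_fill_components(mask):
    """Oracle: exhaustive BFS flood fill with 6-face adjacency."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp, stack = [], [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for ax in range(3):
                for dd in (-1, 1):
                    w = list(v)
                    w[ax] += dd
                    w = tuple(w)
                    if all(0 <= w[k] < mask.shape[k] for k in range(3)) \
                            and mask[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
        comps.append(comp)
    return comps


class TestThreshold:
    def test_fraction_of_maximum_kept(self):
        hm = np.zeros((4, 4, 4), dtype=np.float32)
        hm[0, 0, 0] = 1.0
        hm[1, 1, 1] = 0.31
        hm[2, 2, 2] = 0.30
        hm[3, 3, 3] = 0.29
        mask = threshold_mask(Heatmap(values=hm, spacing=(1, 1, 1)), 0.3)
        assert mask[0, 0, 0] and mask[1, 1, 1]
        assert not mask[2, 2, 2] and not mask[3, 3, 3]  # strict inequality

    def test_zero_heatmap_empty_by_strictness(self):
        # 0 > 0.3 * 0 is false, so a flat zero heatmap selects nothing
        assert not threshold_mask(np.zeros((5, 5, 5)), 0.3).any()

    def test_exact_threshold_value_excluded(self):
        hm = np.zeros((3, 3, 3), dtype=np.float64)
        hm[0, 0, 0] = 1.0
        hm[1, 1, 1] = 0.3  # equals frac * max exactly: strict > excludes it
        assert not threshold_mask(hm, 0.3)[1, 1, 1]

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction(self, frac):
        with pytest.raises(ParameterError):
            threshold_mask(np.ones((2, 2, 2)), frac)


class TestLargestComponent:
    def test_two_boxes_keeps_larger(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[1:4, 1:4, 1:4] = True    # 27 voxels
        mask[8:10, 8:10, 8:10] = True  # 8 voxels
        out = largest_component(mask)
        assert out.sum() == 27
        assert out[2, 2, 2] and not out[8, 8, 8]

    def test_single_component_identity(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 3:5, 1:7] = True
        np.testing.assert_array_equal(largest_component(mask), mask)

    def test_diagonal_contact_is_not_connected(self):
        """Face adjacency: diagonal neighbors belong to separate components."""
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True
        mask[1, 1, 2] = True
        out = largest_component(mask)
        assert out.sum() == 2 and not out[0, 0, 0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((10, 10, 10)) < 0.25
        comps = flood_fill_components(mask)
        if not comps:
            with pytest.raises(EmptyROIError):
                largest_component(mask)
            return
        best = max(len(c) for c in comps)
        out = largest_component(mask)
        assert out.sum() == best
        winners = [c for c in comps if len(c) == best]
        assert any(all(out[v] for v in c) for c in winners)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyROIError):
            largest_component(np.zeros((4, 4, 4), dtype=bool))


class TestBBox:
    def test_published_expansion_example(self):
        """Support on [20, 40) of a 100-long axis expands to [10, 50)."""
        mask = np.zeros((100, 100, 100), dtype=bool)
        mask[20:40, 20:40, 20:40] = True
        box = bbox_from_mask(mask, expand_frac=0.1)
        assert box.lo == (10, 10, 10)
        assert box.hi == (50, 50, 50)

    def test_clamped_at_grid_edge(self):
        mask = np.zeros((50, 50, 50), dtype=bool)
        mask[0:5, 10:20, 45:50] = True
        box = bbox_from_mask(mask, expand_frac=0.1)
        assert box.lo[0] == 0 and box.hi[2] == 50

    def test_zero_expansion_is_tight(self):
        mask = np.zeros((30, 30, 30), dtype=bool)
        mask[4:9, 7:8, 12:25] = True
        box = bbox_from_mask(mask, expand_frac=0.0)
        assert box.lo == (4, 7, 12) and box.hi == (9, 8, 25)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyROIError):
            bbox_from_mask(np.zeros((4, 4, 4), dtype=bool))

    @pytest.mark.parametrize("seed", range(3))
    def test_invariant_to_smaller_disjoint_component(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((24, 24, 24), dtype=bool)
        mask[6:14, 6:14, 6:14] = True  # 512 voxels
        box_before = bbox_from_mask(largest_component(mask))
        extra = np.zeros_like(mask)
        c = rng.choice([0, 20], size=3)  # corner clumps, strictly disjoint
        extra[c[0]:c[0] + 2, c[1]:c[1] + 2, c[2]:c[2] + 2] = True
        box_after = bbox_from_mask(largest_component(mask | extra))
        assert box_before == box_after


class TestCrop:
    def test_crop_and_reembed_identity(self):
        rng = np.random.default_rng(0)
        grid = rng.normal(size=(12, 14, 10)).astype(np.float32)
        box = BoundingBox3D(lo=(2, 3, 1), hi=(9, 10, 8))
        crop = crop_to_bbox(grid, box)
        assert crop.shape == box.shape
        rebuilt = np.zeros_like(grid)
        rebuilt[box.slices()] = crop
        np.testing.assert_array_equal(rebuilt[box.slices()], grid[box.slices()])

    def test_full_extent_box(self):
        grid = np.arange(60).reshape(3, 4, 5).astype(float)
        box = BoundingBox3D(lo=(0, 0, 0), hi=(3, 4, 5))
        np.testing.assert_array_equal(crop_to_bbox(grid, box), grid)

    def test_out_of_bounds_box_rejected(self):
        grid = np.zeros((5, 5, 5))
        with pytest.raises(BoundsError):
            crop_to_bbox(grid, BoundingBox3D(lo=(0, 0, 0), hi=(6, 5, 5)))


class TestEndToEnd:
    def test_gt_heatmap_roi_contains_all_foreground(self):
        """The expanded box from the truth-derived heatmap misses nothing."""
        for seed in (0, 1, 2):
            _, lm, hm = generate_phantom(PhantomConfig(seed=seed))
            box = roi_from_heatmap(hm)
            fg = np.argwhere(lm.labels > 0)
            assert np.all(fg >= box.lo) and np.all(fg < box.hi)

    def test_deterministic(self):
        _, lm, hm = generate_phantom(PhantomConfig(seed=5))
        assert roi_from_heatmap(hm) == roi_from_heatmap(hm)

    def test_masked_out_heatmap_raises(self):
        hm = Heatmap(values=np.zeros((8, 8, 8), np.float32), spacing=(1, 1, 1))
        with pytest.raises(EmptyROIError):
            roi_from_heatmap(hm)
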