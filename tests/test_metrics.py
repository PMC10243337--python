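"""Overlap and surface metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumbarseg.errors import AlignmentError, UndefinedMetricError, UndefinedSurfaceError
from lumbarseg.metrics import (
    ConfusionCounts,
    confusion_counts,
    evaluate_case,
    extract_surface,
    overlap_metrics,
    surface_distances,
    write_report_csv,
)


# ------------------------------------------------------------ oracles -----
def brute_confusion(pred, gt, label):
    tp = fn = fp = 0
    for idx in np.ndindex(pred.shape):
        p, g = pred[idx] == label, gt[idx] == label
        tp += p and g
        fn += (not p) and g
        fp += p and (not g)
    return tp, fn, fp


def brute_surface(mask):
    """All foreground voxels with a background or out-of-grid 6-neighbor."""
    pts = []
    for idx in np.ndindex(mask.shape):
        if not mask[idx]:
            continue
        for ax in range(3):
            for dd in (-1, 1):
                w = list(idx)
                w[ax] += dd
                if not (0 <= w[ax] < mask.shape[ax]) or not mask[tuple(w)]:
                    pts.append(idx)
                    break
            else:
                continue
            break
    return np.asarray(pts, dtype=float)


def brute_surface_distances(a_pts, b_pts, spacing):
    a = a_pts * np.asarray(spacing)
    b = b_pts * np.asarray(spacing)
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    d_ab, d_ba = d.min(axis=1), d.min(axis=0)
    msd = max(d_ab.max(), d_ba.max())
    asd = np.concatenate([d_ab, d_ba]).mean()
    return msd, asd


# ------------------------------------------------------------ overlap -----
class TestOverlap:
    def test_perfect_overlap(self):
        assert overlap_metrics(ConfusionCounts(40, 0, 0)) == (1.0, 0.0, 0.0)

    def test_hand_computed_counts(self):
        dsc, fnd, fpd = overlap_metrics(ConfusionCounts(TP=3, FN=1, FP=2))
        assert (round(dsc, 4), round(fnd, 4), round(fpd, 4)) == (0.6667, 0.2222, 0.4444)

    def test_disjoint_masks(self):
        pred = np.zeros((4, 4, 4), np.int16)
        gt = np.zeros((4, 4, 4), np.int16)
        pred[0, 0, :1] = 1
        pred[1, 1, :4] = 1
        gt[3, 3, :4] = 1
        gt[2, 2, :3] = 1
        c = confusion_counts(pred, gt, 1)
        assert (c.TP, c.FN, c.FP) == (0, 7, 5)

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedMetricError):
            overlap_metrics(ConfusionCounts(0, 0, 0))

    def test_shape_mismatch(self):
        with pytest.raises(AlignmentError):
            confusion_counts(np.zeros((3, 3, 3), int), np.zeros((4, 4, 4), int), 1)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=200, deadline=None)
    def test_dice_identity(self, tp, fn, fp):
        """DSC + (FND + FPD)/2 = 1 whenever any count is positive."""
        if tp + fn + fp == 0:
            return
        dsc, fnd, fpd = overlap_metrics(ConfusionCounts(tp, fn, fp))
        assert dsc + (fnd + fpd) / 2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_counts_match_voxel_loop(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 3, size=(8, 8, 8))
        gt = rng.integers(0, 3, size=(8, 8, 8))
        for label in (1, 2):
            c = confusion_counts(pred, gt, label)
            assert (c.TP, c.FN, c.FP) == brute_confusion(pred, gt, label)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(9)
        pred = rng.integers(0, 2, size=(6, 6, 6))
        gt = rng.integers(0, 2, size=(6, 6, 6))
        d1, fnd1, fpd1 = overlap_metrics(confusion_counts(pred, gt, 1))
        d2, fnd2, fpd2 = overlap_metrics(confusion_counts(gt, pred, 1))
        assert d1 == d2 and fnd1 == fpd2 and fpd1 == fnd2

    def test_growing_pred_toward_gt_never_decreases_dsc(self):
        rng = np.random.default_rng(4)
        gt = (rng.random((8, 8, 8)) < 0.3).astype(int)
        pred = gt.copy()
        missing = np.argwhere((gt == 1))
        rng.shuffle(missing)
        for v in missing[:20]:
            pred[tuple(v)] = 0
        prev = overlap_metrics(confusion_counts(pred, gt, 1))[0]
        for v in missing[:20]:
            pred[tuple(v)] = 1
            cur = overlap_metrics(confusion_counts(pred, gt, 1))[0]
            assert cur >= prev
            prev = cur


# ------------------------------------------------------------ surface -----
class TestSurface:
    def test_solid_cube_surface(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        s = extract_surface(mask, (1, 1, 1))
        assert len(s.points) == 26  # all but the center voxel

    def test_single_voxel_is_its_own_surface(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        s = extract_surface(mask, (2.0, 2.0, 2.0))
        np.testing.assert_array_equal(s.points, [[2.0, 2.0, 2.0]])

    def test_thin_sheet_entirely_surface(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[:, :, 3] = True
        s = extract_surface(mask, (1, 1, 1))
        assert len(s.points) == 36

    def test_empty_mask_raises(self):
        with pytest.raises(UndefinedSurfaceError):
            extract_surface(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))

    def test_identical_surfaces_zero_distance(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        s = extract_surface(mask, (1, 1, 1))
        assert surface_distances(s, s) == (0.0, 0.0)

    def test_two_voxels_three_apart(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[2, 2, 2] = True
        b[2, 2, 5] = True
        msd, asd = surface_distances(extract_surface(a, (1, 1, 1)),
                                     extract_surface(b, (1, 1, 1)))
        assert msd == pytest.approx(3.0) and asd == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spacing = (0.7, 1.0, 1.3)
        a = rng.random((10, 10, 10)) < 0.2
        b = rng.random((10, 10, 10)) < 0.2
        if not (a.any() and b.any()):
            return
        sa, sb = extract_surface(a, spacing), extract_surface(b, spacing)
        msd, asd = surface_distances(sa, sb)
        o_msd, o_asd = brute_surface_distances(brute_surface(a), brute_surface(b), spacing)
        assert msd == pytest.approx(o_msd)
        assert asd == pytest.approx(o_asd)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(11)
        a = rng.random((8, 8, 8)) < 0.3
        b = rng.random((8, 8, 8)) < 0.3
        sa, sb = extract_surface(a, (1, 1, 1)), extract_surface(b, (1, 1, 1))
        assert surface_distances(sa, sb) == surface_distances(sb, sa)

    def test_directed_means_mode(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[1, 1, 1] = True
        b[1, 1, 3] = True
        b[1, 1, 4] = True
        sa, sb = extract_surface(a, (1, 1, 1)), extract_surface(b, (1, 1, 1))
        _, pooled = surface_distances(sa, sb, asd_mode="pooled")
        _, directed = surface_distances(sa, sb, asd_mode="directed_means")
        # pooled: mean(2, 2, 3) = 7/3; directed: (2 + 5/2)/2 = 9/4
        assert pooled == pytest.approx(7 / 3)
        assert directed == pytest.approx(9 / 4)


# ------------------------------------------------------- case reports -----
class TestEvaluateCase:
    def _five_label_map(self, seed=0):
        rng = np.random.default_rng(seed)
        lm = np.zeros((12, 12, 20), dtype=np.int16)
        for c in range(1, 6):
            z = 3 * c
            lm[4:8, 4:8, z:z + 3] = c
        return lm

    def test_identical_maps_are_perfect(self):
        lm = self._five_label_map()
        rep = evaluate_case(lm, lm, (1, 1, 1))
        for label in range(1, 6):
            row = rep.rows[label]
            assert row["valid"]
            assert row["DSC"] == 1.0 and row["MSD"] == 0.0 and row["ASD"] == 0.0
        assert rep.mean["DSC"] == 1.0

    def test_label_absent_from_both_flagged_invalid(self):
        lm = self._five_label_map()
        pred, gt = lm.copy(), lm.copy()
        pred[pred == 4] = 0
        gt[gt == 4] = 0
        rep = evaluate_case(pred, gt, (1, 1, 1))
        assert not rep.rows[4]["valid"]
        assert all(rep.rows[c]["valid"] for c in (1, 2, 3, 5))

    def test_mean_is_average_of_valid_rows(self):
        rng = np.random.default_rng(2)
        gt = self._five_label_map()
        pred = gt.copy()
        flip = rng.random(gt.shape) < 0.05
        pred[flip] = (pred[flip] + 1) % 6
        rep = evaluate_case(pred, gt, (1, 1, 1))
        valid = [rep.rows[c] for c in range(1, 6) if rep.rows[c]["valid"]]
        for col in ("DSC", "FND", "FPD"):
            assert rep.mean[col] == pytest.approx(np.mean([r[col] for r in valid]))

    def test_one_sided_label_has_overlap_but_no_surface(self):
        gt = self._five_label_map()
        pred = gt.copy()
        pred[pred == 2] = 0
        rep = evaluate_case(pred, gt, (1, 1, 1))
        row = rep.rows[2]
        assert row["valid"] and row["DSC"] == 0.0 and row["FND"] == 2.0
        assert np.isnan(row["MSD"]) and np.isnan(row["ASD"])

    def test_report_identity_holds_rowwise(self):
        rng = np.random.default_rng(3)
        gt = self._five_label_map()
        pred = gt.copy()
        flip = rng.random(gt.shape) < 0.1
        pred[flip] = rng.integers(0, 6, size=flip.sum())
        rep = evaluate_case(pred, gt, (1, 1, 1))
        for row in rep.rows.values():
            if row["valid"]:
                assert row["DSC"] + (row["FND"] + row["FPD"]) / 2 == pytest.approx(1.0)

    def test_csv_column_order(self, tmp_path):
        lm = self._five_label_map()
        rep = evaluate_case(lm, lm, (1, 1, 1))
        table = write_report_csv({"case0": rep}, tmp_path / "report.csv")
        assert list(table.columns) == ["case", "label", "DSC", "FND", "FPD",
                                       "MSD", "ASD", "valid"]
        assert (tmp_path / "report.csv").exists()
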