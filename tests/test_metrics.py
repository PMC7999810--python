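"""Overlap and surface metrics against brute-force oracles; component labeling."""

import itertools

import numpy as np
import pytest

from infarctseg import (
    BinaryMask,
    assd,
    connected_components_26,
    dsc,
    evaluate,
    iou,
    refine_segmentation,
)
from infarctseg.errors import InputError, UndefinedMeasureError


def brute_force_assd(x, y, spacing=(1.0, 1.0, 1.0)):
    """O(n^2) oracle: explicit double loop over boundary voxel pairs."""

    def boundary(mask):
        pts = []
        for idx in np.argwhere(mask):
            for axis in range(3):
                for step in (-1, 1):
                    nb = idx.copy()
                    nb[axis] += step
                    if (nb < 0).any() or (nb >= np.array(mask.shape)).any() or not mask[tuple(nb)]:
                        pts.append(idx)
                        break
                else:
                    continue
                break
        return np.array(pts, dtype=float)

    bx, by = boundary(x), boundary(y)
    sp = np.asarray(spacing)

    def dmin(points, targets):
        return [np.sqrt((((p - targets) * sp) ** 2).sum(axis=1)).min() for p in points]

    dists = dmin(bx, by) + dmin(by, bx)
    return float(np.mean(dists))


def flood_fill_components(mask, connectivity):
    """Oracle: BFS flood fill at 6- or 26-connectivity."""
    if connectivity == 26:
        neighbors = [d for d in itertools.product((-1, 0, 1), repeat=3) if any(d)]
    else:
        neighbors = [d for d in itertools.product((-1, 0, 1), repeat=3) if sum(map(abs, d)) == 1]
    seen = np.zeros(mask.shape, dtype=bool)
    count = 0
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            cur = stack.pop()
            for d in neighbors:
                nb = tuple(c + o for c, o in zip(cur, d))
                if all(0 <= n < s for n, s in zip(nb, mask.shape)) and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
    return count


class TestOverlapMeasures:
    def test_identical_masks(self, random_mask_pair):
        x, _ = random_mask_pair()
        assert iou(x, x) == 1.0
        assert dsc(x, x) == 1.0

    def test_disjoint_masks(self):
        x = np.zeros((4, 4, 4), dtype=np.uint8)
        y = np.zeros((4, 4, 4), dtype=np.uint8)
        x[0, 0, 0] = 1
        y[3, 3, 3] = 1
        assert iou(x, y) == 0.0
        assert dsc(x, y) == 0.0

    def test_counting_example(self):
        x = np.zeros((4, 4, 4), dtype=np.uint8)
        y = np.zeros((4, 4, 4), dtype=np.uint8)
        x[0, 0, 0] = x[0, 0, 1] = 1
        y[0, 0, 1] = y[0, 0, 2] = 1
        assert iou(x, y) == pytest.approx(1 / 3)
        assert dsc(x, y) == pytest.approx(0.5)

    def test_both_empty_is_undefined(self):
        empty = np.zeros((3, 3, 3), dtype=np.uint8)
        with pytest.raises(UndefinedMeasureError):
            iou(empty, empty)
        with pytest.raises(UndefinedMeasureError):
            dsc(empty, empty)

    def test_dsc_iou_identity_and_symmetry(self, random_mask_pair):
        for _ in range(20):
            x, y = random_mask_pair()
            i, d = iou(x, y), dsc(x, y)
            assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)
            assert iou(y, x) == i and dsc(y, x) == d


class TestAssd:
    def test_identical_masks_give_zero(self, random_mask_pair):
        x, _ = random_mask_pair()
        assert assd(x, x) == 0.0

    def test_two_voxels_three_apart(self):
        x = np.zeros((8, 8, 8), dtype=np.uint8)
        y = np.zeros((8, 8, 8), dtype=np.uint8)
        x[2, 4, 4] = 1
        y[5, 4, 4] = 1
        assert assd(x, y) == pytest.approx(3.0)

    def test_matches_brute_force_on_random_masks(self, random_mask_pair):
        for _ in range(20):
            x, y = random_mask_pair(shape=(8, 8, 8), p=0.15)
            got = assd(x, y)
            want = brute_force_assd(x.data.astype(bool), y.data.astype(bool))
            assert got == pytest.approx(want, abs=1e-9)

    def test_spacing_scales_linearly(self, random_mask_pair):
        x, y = random_mask_pair()
        base = assd(x.data, y.data, spacing=(1.0, 1.0, 1.0))
        scaled = assd(x.data, y.data, spacing=(2.0, 2.0, 2.0))
        assert scaled == pytest.approx(2.0 * base)

    def test_translation_invariance(self):
        x = np.zeros((12, 12, 12), dtype=np.uint8)
        y = np.zeros((12, 12, 12), dtype=np.uint8)
        x[2:4, 2:4, 2:4] = 1
        y[3:5, 2:4, 2:4] = 1
        a1 = assd(x, y)
        a2 = assd(np.roll(x, 5, axis=2), np.roll(y, 5, axis=2))
        assert a2 == pytest.approx(a1)

    def test_empty_mask_is_undefined(self):
        x = np.zeros((4, 4, 4), dtype=np.uint8)
        y = np.zeros((4, 4, 4), dtype=np.uint8)
        y[1, 1, 1] = 1
        with pytest.raises(UndefinedMeasureError):
            assd(x, y)


class TestConnectedComponents:
    def test_solid_cube_is_one_component(self):
        m = np.zeros((6, 6, 6), dtype=np.uint8)
        m[1:4, 1:4, 1:4] = 1
        _, n = connected_components_26(m)
        assert n == 1

    def test_corner_touching_voxels_merge_at_26_not_6(self):
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        m[0, 0, 0] = m[1, 1, 1] = 1
        _, n26 = connected_components_26(m)
        assert n26 == 1
        assert flood_fill_components(m.astype(bool), 26) == 1
        assert flood_fill_components(m.astype(bool), 6) == 2

    def test_empty_mask_has_zero_components(self):
        _, n = connected_components_26(np.zeros((4, 4, 4), dtype=np.uint8))
        assert n == 0

    def test_count_matches_flood_fill_oracle(self, rng):
        for _ in range(15):
            m = (rng.random((8, 8, 8)) < 0.15).astype(np.uint8)
            _, n = connected_components_26(m)
            assert n == flood_fill_components(m.astype(bool), 26)

    def test_labels_in_raster_first_encounter_order(self):
        m = np.zeros((3, 5, 5), dtype=np.uint8)
        m[0, 0, 4] = 1  # encountered first in raster scan
        m[2, 4, 0] = 1
        labels, n = connected_components_26(m)
        assert n == 2
        assert labels[0, 0, 4] == 1
        assert labels[2, 4, 0] == 2


class TestRefine:
    def test_min_size_zero_is_identity(self, random_mask_pair):
        x, _ = random_mask_pair()
        np.testing.assert_array_equal(refine_segmentation(x, 0).data, x.data)

    def test_small_components_dropped(self):
        m = np.zeros((12, 12, 12), dtype=np.uint8)
        m[0, 0, 0:2] = 1  # 2 voxels
        m[5:8, 5:8, 5:8] = 1  # 27 voxels, 30 with the tail below
        m[8, 5, 5:8] = 1
        out = refine_segmentation(m, min_size=10)
        assert out.data[0, 0, 0] == 0
        assert out.data[6, 6, 6] == 1

    def test_output_subset_of_input(self, random_mask_pair):
        x, _ = random_mask_pair()
        out = refine_segmentation(x, min_size=3)
        assert not np.any(out.data & ~x.data)


class TestEvaluate:
    def test_perfect_prediction_row(self, random_mask_pair):
        x, _ = random_mask_pair()
        report = evaluate([x], [x], ["s1"])
        row = report.per_subject.iloc[0]
        assert row["iou"] == 1.0 and row["dsc"] == 1.0 and row["assd_mm"] == 0.0

    def test_summary_mean_and_sample_std(self):
        # construct DSC 0.4 and 0.6: |X|=|Y|=5 with 2 and 3 shared voxels
        def pair(shared):
            x = np.zeros((4, 4, 4), dtype=np.uint8)
            y = np.zeros((4, 4, 4), dtype=np.uint8)
            x.flat[:5] = 1
            y.flat[5 - shared : 10 - shared] = 1
            return BinaryMask(data=x), BinaryMask(data=y)

        (x1, y1), (x2, y2) = pair(2), pair(3)
        assert dsc(x1, y1) == pytest.approx(0.4)
        assert dsc(x2, y2) == pytest.approx(0.6)
        report = evaluate([x1, x2], [y1, y2], ["a", "b"])
        assert report.summary["dsc_mean"] == pytest.approx(0.5)
        assert report.summary["dsc_std"] == pytest.approx(np.std([0.4, 0.6], ddof=1))

    def test_summary_matches_recomputed_rows(self, random_mask_pair):
        pairs = [random_mask_pair() for _ in range(4)]
        report = evaluate([p[0] for p in pairs], [p[1] for p in pairs], list("abcd"))
        recomputed = [iou(x, y) for x, y in pairs]
        assert report.summary["iou_mean"] == pytest.approx(np.mean(recomputed))

    def test_undefined_rows_flagged_and_excluded(self, random_mask_pair):
        x, y = random_mask_pair()
        empty = BinaryMask(data=np.zeros((10, 10, 10), dtype=np.uint8))
        report = evaluate([x, empty], [y, empty], ["ok", "empty"])
        assert report.summary["n_undefined"] == 1
        assert not report.per_subject.iloc[1]["defined"]
        assert report.summary["iou_mean"] == pytest.approx(iou(x, y))

    def test_length_mismatch_rejected(self, random_mask_pair):
        x, y = random_mask_pair()
        with pytest.raises(InputError):
            evaluate([x], [y, y], ["a", "b"])
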