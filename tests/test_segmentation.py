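import math
import warnings

import numpy as np
import pytest

from clonoscope.segmentation import (
    DegenerateHistogramError,
    DetectionConfig,
    ThresholdSet,
    choose_optimal_n,
    compute_histogram,
    detect_cells,
    psnr,
    reconstruct,
    select_thresholds,
)
from conftest import match_detected_to_truth


def _img(values):
    return np.asarray(values, dtype=np.uint8)


def _rmse(a, b):
    return float(np.sqrt(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2)))


class TestHistogram:
    def test_constant_image_counts(self):
        h = compute_histogram(_img([[7, 7], [7, 7], [7, 7], [7, 7], [7, 7]]))
        assert h.counts[7] == 10 and h.counts.sum() == 10

    def test_extreme_values(self):
        h = compute_histogram(_img([0, 255]))
        assert h.counts[0] == 1 and h.counts[255] == 1

    def test_counts_sum_to_pixel_count(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(13, 17)).astype(np.uint8)
        h = compute_histogram(img)
        # independent recount by direct iteration
        manual = {}
        for v in img.ravel():
            manual[int(v)] = manual.get(int(v), 0) + 1
        assert all(h.counts[v] == c for v, c in manual.items())
        assert h.counts.sum() == img.size

    def test_non_uint8_rejected(self):
        with pytest.raises(TypeError):
            compute_histogram(np.zeros((3, 3), dtype=np.uint16))


class TestSelectThresholds:
    def test_bimodal_single_threshold_separates_masses(self):
        img = _img([50] * 30 + [200] * 30)
        ts = select_thresholds(compute_histogram(img), 1)
        (t,) = ts.thresholds
        assert 50 <= t < 200  # all 50s on one side, all 200s on the other
        seg = reconstruct(img, ts)
        assert set(seg.labels[img == 50]) == {0}
        assert set(seg.labels[img == 200]) == {1}

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_thresholds_distinct_and_increasing(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            vals = rng.choice(np.arange(256), size=n + 1 + rng.integers(1, 5),
                              replace=False)
            img = np.repeat(vals, rng.integers(1, 10, size=len(vals))).astype(np.uint8)
            ts = select_thresholds(compute_histogram(img), n)
            assert len(set(ts.thresholds)) == len(ts.thresholds)
            assert list(ts.thresholds) == sorted(ts.thresholds)

    def test_w_zero_splits_at_interval_mean(self):
        img = _img([50] * 30 + [200] * 30)
        ts = select_thresholds(compute_histogram(img), 1, w=0)
        assert ts.thresholds == (125,)

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            select_thresholds(compute_histogram(np.full((4, 4), 9, np.uint8)), 1)


class TestReconstructAndPsnr:
    def test_saturated_thresholds_reproduce_image(self):
        img = _img([10, 10, 80, 80, 160])
        ts = ThresholdSet(2, (10, 80))  # one occupied value per segment
        assert psnr(img, reconstruct(img, ts).reconstruction) == math.inf

    def test_single_segment_is_global_mean(self):
        img = _img([[0, 100], [50, 50]])
        seg = reconstruct(img, ThresholdSet(0, ()))
        assert np.allclose(seg.reconstruction, 50.0)

    def test_two_value_split_recovers_both_values(self):
        img = _img([30] * 5 + [220] * 3)
        seg = reconstruct(img, ThresholdSet(1, (100,)))
        assert np.allclose(np.unique(seg.reconstruction), [30.0, 220.0])

    def test_segment_means_monotone_in_segment_index(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        ts = select_thresholds(compute_histogram(img), 5)
        seg = reconstruct(img, ts)
        occupied = np.unique(seg.labels)
        reps = seg.representatives[occupied]
        assert np.all(np.diff(reps) >= 0)

    def test_psnr_closed_form(self):
        a = np.full((4, 4), 100, np.uint8)
        b = np.full((4, 4), 110, np.uint8)
        assert psnr(a, b) == pytest.approx(20 * math.log10(25.5), abs=1e-9)

    def test_psnr_identical_and_worst_case(self):
        img = _img([[1, 2], [3, 4]])
        assert psnr(img, img) == math.inf
        assert psnr(_img([[0]]), _img([[255]])) == 0.0

    def test_psnr_shape_mismatch(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_psnr_joint_translation_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 200, (8, 8)).astype(float)
        b = a + rng.normal(0, 5, (8, 8))
        assert psnr(a + 30, b + 30) == pytest.approx(psnr(a, b))


class TestRefinementInvariant:
    def test_subdividing_a_segment_never_increases_rmse(self):
        """Segment-mean reconstruction: any added threshold refines the
        partition, so RMSE is non-increasing (checked on random images)."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            base = sorted(rng.choice(np.arange(1, 255), size=3, replace=False))
            ts1 = ThresholdSet(3, tuple(int(t) for t in base))
            extra = int(rng.choice([t for t in range(1, 255) if t not in base]))
            ts2 = ThresholdSet(4, tuple(sorted(base + [extra])))
            r1 = _rmse(img, reconstruct(img, ts1).reconstruction)
            r2 = _rmse(img, reconstruct(img, ts2).reconstruction)
            assert r2 <= r1 + 1e-12


class TestChooseOptimalN:
    def test_three_value_image_saturates_early(self):
        img = _img([0] * 20 + [100] * 20 + [200] * 20)
        res = choose_optimal_n(img)
        assert res.selected_n <= 2
        assert res.threshold_set.psnr_db == math.inf

    def test_constant_image_returns_zero_thresholds(self):
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            res = choose_optimal_n(np.full((6, 6), 3, np.uint8))
        assert res.selected_n == 0
        assert any("degenerate" in str(w.message) for w in rec)

    def test_selected_n_within_range_on_realistic_image(self, rendered_fixture):
        _, _, image, _ = rendered_fixture
        res = choose_optimal_n(image[0], n_range=(2, 15))
        assert 2 <= res.selected_n <= 15
        # PSNR curve is recorded and non-decreasing up to the selection
        psnrs = [res.psnr_by_n[n] for n in sorted(res.psnr_by_n)]
        assert all(b >= a - 1e-9 for a, b in zip(psnrs, psnrs[1:]))


class TestDetectCells:
    def test_blank_image_yields_no_cells(self):
        img = np.full((2, 40, 40), 8, np.uint8)
        cells, _ = detect_cells(img)
        assert len(cells) == 0

    def test_well_separated_blobs_recovered_exactly(self, rendered_fixture):
        cells, truth, image, _ = rendered_fixture
        detected, _ = detect_cells(image)
        assert len(detected) == len(cells)
        matched = match_detected_to_truth(detected, cells)
        assert len(set(matched)) == len(cells)

    def test_interior_centroids_within_one_pixel_of_truth(self, rendered_fixture):
        """Blobs not clipped by the field border localize to within 1 px."""
        cells, _, image, model = rendered_fixture
        detected, _ = detect_cells(image)
        from scipy.spatial.distance import cdist

        margin = 10.0  # soma radius + edge falloff, um
        interior = cells[
            cells["x_um"].between(margin, model.slab_width - margin)
            & cells["y_um"].between(margin, model.cortical_thickness - margin)
        ]
        d = cdist(interior[["x_um", "y_um"]], detected[["x_um", "y_um"]])
        assert d.min(axis=1).max() < 1.0

    def test_speckle_below_min_area_removed(self):
        img = np.full((40, 40), 0, np.uint8)
        img[5, 5] = 200  # single-pixel speckle
        img[20:26, 20:26] = 180  # a real cell
        cells, _ = detect_cells(
            img, DetectionConfig(min_area=2),
            threshold_sets=[ThresholdSet(1, (50,))],
        )
        assert len(cells) == 1
        assert cells["area_px"].iloc[0] == 36

    def test_count_invariant_to_channel_permutation(self, rendered_fixture):
        _, _, image, _ = rendered_fixture
        a, _ = detect_cells(image)
        b, _ = detect_cells(image[::-1].copy())
        assert len(a) == len(b)
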