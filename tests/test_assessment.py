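import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from cvcroparea import (
    MASK,
    BinaryCropMap,
    ConfusionMatrix,
    CVRaster,
    TruthPolygon,
    accuracy_metrics,
    classify_cv,
    confusion_from_polygons,
    extract_polygon_pixels,
    pixelwise_agreement,
    polygon_majority_classify,
    recover_count,
    roc_sweep,
    select_threshold_apriori,
    summarize_report,
)
from cvcroparea.containers import rectangle_polygon


def _cv_raster(grid, cv):
    cv = np.asarray(cv, dtype=float)
    return CVRaster(grid, cv=cv, sigma=np.zeros_like(cv), mu=np.ones_like(cv),
                    n_valid_dates=np.full(cv.shape, 2))


def _ray_cast(poly_coords, x, y):
    """Even-odd point-in-polygon oracle (generic position)."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xi:
                inside = not inside
    return inside


class TestExtractPolygonPixels:
    def test_square_covering_nine_centers(self, crop_map_factory):
        cmap = crop_map_factory(np.ones((10, 10)))
        poly = TruthPolygon("p", "crop", rectangle_polygon(2.0, -2.0, 5.0, -5.0))
        labels, n_masked = extract_polygon_pixels(cmap, poly)
        assert labels.size == 9 and n_masked == 0

    def test_polygon_between_centers_is_empty(self, crop_map_factory):
        cmap = crop_map_factory(np.ones((10, 10)))
        poly = TruthPolygon("p", "crop", rectangle_polygon(2.6, -2.6, 3.4, -3.4))
        labels, _ = extract_polygon_pixels(cmap, poly)
        assert labels.size == 0

    def test_polygon_outside_raster_is_empty(self, crop_map_factory):
        cmap = crop_map_factory(np.ones((5, 5)))
        poly = TruthPolygon("p", "crop", rectangle_polygon(100.0, -100.0, 110.0, -110.0))
        labels, _ = extract_polygon_pixels(cmap, poly)
        assert labels.size == 0

    def test_mask_pixels_counted_separately(self, crop_map_factory):
        labels = np.ones((6, 6), dtype=np.uint8)
        labels[3, 3] = MASK
        cmap = crop_map_factory(labels)
        poly = TruthPolygon("p", "crop", rectangle_polygon(2.0, -2.0, 5.0, -5.0))
        got, n_masked = extract_polygon_pixels(cmap, poly)
        assert got.size == 8 and n_masked == 1

    def test_matches_brute_force_scan_on_random_polygons(self, crop_map_factory):
        rng = np.random.default_rng(77)
        cmap = crop_map_factory(rng.integers(0, 2, size=(20, 20)))
        for _ in range(15):
            center = rng.uniform(3, 17, size=2)
            angles = np.sort(rng.uniform(0, 2 * np.pi, size=6))
            radius = rng.uniform(1.0, 5.0, size=6)
            coords = [
                (center[0] + r * np.cos(a), -(center[1] + r * np.sin(a)))
                for a, r in zip(angles, radius)
            ]
            shp = Polygon(coords)
            if not shp.is_valid:
                continue
            poly = TruthPolygon("p", "crop", shp)
            got, _ = extract_polygon_pixels(cmap, poly)
            expected = []
            for r in range(20):
                for c in range(20):
                    if _ray_cast(coords, c + 0.5, -(r + 0.5)):
                        expected.append(cmap.labels[r, c])
            assert sorted(got.tolist()) == sorted(expected)


class TestMajorityRule:
    def _map_with_counts(self, crop_map_factory, n_crop, n_noncrop, n_mask=0):
        labels = np.array([1] * n_crop + [0] * n_noncrop + [MASK] * n_mask,
                          dtype=np.uint8).reshape(1, -1)
        cmap = crop_map_factory(labels)
        poly = TruthPolygon(
            "p", "crop", rectangle_polygon(0.0, 0.0, labels.size, -1.0)
        )
        return polygon_majority_classify(cmap, [poly])

    def test_seven_of_ten_crop_is_crop(self, crop_map_factory):
        table = self._map_with_counts(crop_map_factory, 7, 3)
        assert table.predicted.iloc[0] == "crop"
        assert table.mean_value.iloc[0] == pytest.approx(0.7)

    def test_exact_half_is_non_crop(self, crop_map_factory):
        # mean of exactly 0.5 fails the strict > 0.5 rule
        table = self._map_with_counts(crop_map_factory, 5, 5)
        assert table.predicted.iloc[0] == "non-crop"

    def test_all_mask_polygon_flagged(self, crop_map_factory):
        table = self._map_with_counts(crop_map_factory, 0, 0, 10)
        assert bool(table.flagged.iloc[0])

    def test_mask_pixels_excluded_from_mean(self, crop_map_factory):
        table = self._map_with_counts(crop_map_factory, 3, 2, 5)
        assert table.mean_value.iloc[0] == pytest.approx(0.6)
        assert table.n_masked.iloc[0] == 5


class TestConfusion:
    def test_perfect_classification(self):
        cats = ["crop"] * 54 + ["built-up"] * 26 + ["forest"] * 13
        polys = [
            TruthPolygon(f"p{i}", c, rectangle_polygon(i, 0, i + 0.5, -0.5))
            for i, c in enumerate(cats)
        ]
        preds = ["crop"] * 54 + ["non-crop"] * 39
        cm = confusion_from_polygons(preds, polys)
        assert (cm.TP, cm.FP, cm.FN, cm.TN) == (54, 0, 0, 39)

    def test_matches_hand_count_on_random_assignment(self):
        rng = np.random.default_rng(5)
        cats = rng.choice(["crop", "built-up", "forest"], size=200)
        preds = rng.choice(["crop", "non-crop"], size=200)
        polys = [
            TruthPolygon(f"p{i}", c, rectangle_polygon(i, 0, i + 0.5, -0.5))
            for i, c in enumerate(cats)
        ]
        cm = confusion_from_polygons(list(preds), polys)
        tp = sum(1 for c, p in zip(cats, preds) if c == "crop" and p == "crop")
        fn = sum(1 for c, p in zip(cats, preds) if c == "crop" and p == "non-crop")
        fp = sum(1 for c, p in zip(cats, preds) if c != "crop" and p == "crop")
        tn = sum(1 for c, p in zip(cats, preds) if c != "crop" and p == "non-crop")
        assert (cm.TP, cm.FP, cm.FN, cm.TN) == (tp, fp, fn, tn)


class TestAccuracyMetrics:
    def test_year_2017_polygon_tally(self):
        # 48 of 54 crop polygons correct, all 39 non-crop correct
        rep = accuracy_metrics(ConfusionMatrix(TP=48, FP=0, FN=6, TN=39))
        assert round(rep.oa_percent, 1) == 93.5

    def test_degenerate_single_class_reports_not_available(self):
        rep = accuracy_metrics(ConfusionMatrix(TP=0, FP=0, FN=0, TN=10))
        assert rep.oa_percent == 100.0
        assert rep.sensitivity is None
        assert rep.youden_j is None

    def test_matches_independent_formulas_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(1, 100, size=4)
            rep = accuracy_metrics(ConfusionMatrix(int(tp), int(fp), int(fn), int(tn)))
            n = tp + fp + fn + tn
            assert rep.oa_percent == pytest.approx(100 * (tp + tn) / n, rel=1e-12)
            assert rep.sensitivity == pytest.approx(tp / (tp + fn), rel=1e-12)
            assert rep.specificity == pytest.approx(tn / (tn + fp), rel=1e-12)
            assert rep.youden_j == pytest.approx(
                rep.sensitivity + rep.specificity - 1, rel=1e-9
            )
            po = (tp + tn) / n
            pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
            assert rep.kappa == pytest.approx((po - pe) / (1 - pe), rel=1e-9)

    def test_kappa_is_one_iff_perfect_with_both_classes(self):
        assert accuracy_metrics(ConfusionMatrix(10, 0, 0, 5)).kappa == pytest.approx(1.0)
        assert accuracy_metrics(ConfusionMatrix(10, 1, 0, 5)).kappa < 1.0


class TestPixelwiseAgreement:
    def test_self_agreement_is_100(self, crop_map_factory):
        rng = np.random.default_rng(2)
        cmap = crop_map_factory(rng.integers(0, 2, size=(10, 10)))
        assert pixelwise_agreement(cmap, cmap) == 100.0

    def test_complement_agreement_is_0(self, crop_map_factory):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, size=(10, 10)).astype(np.uint8)
        a = crop_map_factory(labels)
        b = crop_map_factory(1 - labels)
        assert pixelwise_agreement(a, b) == 0.0

    def test_matches_hand_count_with_masks(self, crop_map_factory):
        rng = np.random.default_rng(8)
        la = rng.choice([0, 1, MASK], size=(10, 10), p=[0.4, 0.4, 0.2]).astype(np.uint8)
        lb = rng.choice([0, 1, MASK], size=(10, 10), p=[0.4, 0.4, 0.2]).astype(np.uint8)
        got = pixelwise_agreement(crop_map_factory(la), crop_map_factory(lb))
        valid = (la != MASK) & (lb != MASK)
        expected = 100.0 * (la[valid] == lb[valid]).sum() / valid.sum()
        assert got == pytest.approx(expected)


class TestROCSweep:
    def test_perfect_separation(self, unit_grid):
        grid = unit_grid(1, 10)
        cv = np.array([[0.05, 0.1, 0.15, 0.18, 0.19, 0.31, 0.35, 0.4, 0.5, 0.9]])
        truth = BinaryCropMap(grid, np.array([[0] * 5 + [1] * 5], dtype=np.uint8))
        table, best = roc_sweep(_cv_raster(grid, cv), truth)
        perfect = table[(table.threshold > 0.2) & (table.threshold <= 0.3)]
        assert (perfect.youden_j == 1.0).all()
        assert best == pytest.approx(0.2)  # smallest threshold reaching max J

    def test_single_class_truth_rejected(self, unit_grid):
        grid = unit_grid(1, 4)
        truth = BinaryCropMap(grid, np.ones((1, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="both"):
            roc_sweep(_cv_raster(grid, [[0.1, 0.2, 0.3, 0.4]]), truth)

    def test_oa_consistent_with_classify_cv(self, unit_grid):
        rng = np.random.default_rng(6)
        grid = unit_grid(20, 20)
        cv = rng.uniform(0, 0.8, size=(20, 20))
        truth = BinaryCropMap(grid, rng.integers(0, 2, size=(20, 20)).astype(np.uint8))
        cvr = _cv_raster(grid, cv)
        table, _ = roc_sweep(cvr, truth)
        for thr in (0.1, 0.25, 0.5):
            predicted = classify_cv(cvr, thr)
            agree = (predicted.labels == truth.labels).mean() * 100
            row = table[np.isclose(table.threshold, thr)].iloc[0]
            assert row.oa_percent == pytest.approx(agree)


class TestAprioriThreshold:
    def test_coarse_to_fine_adjustment_reaches_study_value(self):
        # published coarse value 0.20 at 150 m maps to 0.25 at 30 m
        assert select_threshold_apriori(0.20, 150.0, 30.0) == pytest.approx(0.25, abs=5e-3)

    def test_equal_pixel_sizes_return_base(self):
        assert select_threshold_apriori(0.3, 30.0, 30.0) == pytest.approx(0.3)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=10.0, max_value=500.0),
           st.floats(min_value=10.0, max_value=500.0))
    def test_finer_pixels_never_decrease_threshold(self, fine_a, fine_b):
        lo, hi = sorted([fine_a, fine_b])
        assert select_threshold_apriori(0.2, 150.0, lo) >= select_threshold_apriori(
            0.2, 150.0, hi
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            select_threshold_apriori(0.2, -1.0, 30.0)
        with pytest.raises(ValueError):
            select_threshold_apriori(0.0, 150.0, 30.0)


class TestRecoverCount:
    @pytest.mark.parametrize("pct,n,k", [
        (63.0, 54, 34), (100.0, 26, 26), (92.3, 26, 24), (88.9, 54, 48),
        (85.2, 54, 46), (96.2, 26, 25), (92.6, 54, 50), (87.0, 54, 47),
    ])
    def test_table_cells_invert_uniquely(self, pct, n, k):
        assert recover_count(pct, n) == k

    def test_no_solution_rejected(self):
        with pytest.raises(ValueError, match="no count"):
            recover_count(50.0, 3)

    def test_ambiguous_solution_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            recover_count(50.0, 10000)


class TestSummarizeReport:
    def test_average_row_of_yearly_accuracies(self):
        years = [2017, 2018, 2019, 2020, 2021]
        table = pd.DataFrame(
            {"oa_all_ca": [93.5, 97.8, 97.8, 91.4, 97.8],
             "oa_crop_cdl": [63.0, 63.0, 85.2, 85.2, 87.0]},
            index=years,
        )
        out = summarize_report(table)
        assert out.loc["AVG", "oa_all_ca"] == 95.7
        assert out.loc["AVG", "oa_crop_cdl"] == 76.7

    def test_single_year_average_is_that_year(self):
        table = pd.DataFrame({"oa": [91.4]}, index=[2020])
        out = summarize_report(table)
        assert out.loc["AVG", "oa"] == 91.4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_report(pd.DataFrame({"oa": []}))
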