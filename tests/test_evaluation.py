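import numpy as np
import pytest

from eomseg.evaluation import (
    dice_iou,
    mae_mape,
    regional_metrics,
    split_regions,
)
from eomseg.volume import LabelVolume


def _lv(arr):
    return LabelVolume(np.asarray(arr, dtype=np.uint8), (1.0, 1.0), 3.0)


class TestDiceIoU:
    def test_identical(self):
        a = np.zeros((2, 8, 8), np.uint8)
        a[0, :3, :3] = 1
        assert dice_iou(_lv(a), _lv(a), 1) == (1.0, 1.0)

    def test_counting_example(self):
        """|P| = |G| = 10 with overlap 6 → Dice 0.6, IoU 6/14."""
        p = np.zeros((1, 10, 10), np.uint8)
        g = np.zeros((1, 10, 10), np.uint8)
        p[0, 0, :10] = 2
        g[0, 0, 4:10] = 2
        g[0, 1, :4] = 2
        d, i = dice_iou(_lv(p), _lv(g), 2)
        assert d == pytest.approx(0.6)
        assert i == pytest.approx(6 / 14)

    def test_disjoint(self):
        p = np.zeros((1, 4, 4), np.uint8)
        g = np.zeros((1, 4, 4), np.uint8)
        p[0, 0, 0] = 1
        g[0, 1, 1] = 1
        assert dice_iou(_lv(p), _lv(g), 1) == (0.0, 0.0)

    def test_both_empty_undefined(self):
        z = np.zeros((1, 4, 4), np.uint8)
        d, i = dice_iou(_lv(z), _lv(z), 5)
        assert np.isnan(d) and np.isnan(i)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            dice_iou(np.zeros((1, 4, 4)), np.zeros((1, 5, 5)), 1)

    def test_iou_dice_relation(self, rng):
        for _ in range(10):
            p = (rng.random((2, 12, 12)) < 0.3).astype(np.uint8)
            g = (rng.random((2, 12, 12)) < 0.3).astype(np.uint8)
            d, i = dice_iou(p, g, 1)
            if np.isnan(d) or d == 0:
                continue
            assert i == pytest.approx(d / (2 - d), abs=1e-9)


class TestRegionSplit:
    def _slab(self, n_bearing, lead=2, trail=3):
        arr = np.zeros((lead + n_bearing + trail, 6, 6), np.uint8)
        arr[lead : lead + n_bearing, 2, 2] = 1
        return _lv(arr)

    @pytest.mark.parametrize(
        "n,expected", [(9, (3, 3, 3)), (10, (3, 4, 3)), (11, (3, 4, 4))]
    )
    def test_near_equal_thirds(self, n, expected):
        split = split_regions(self._slab(n))
        assert split.lengths() == expected

    def test_ranges_cover_slab_contiguously(self):
        split = split_regions(self._slab(10, lead=4))
        assert split.insertion[0] == 4
        assert split.insertion[1] == split.central[0]
        assert split.central[1] == split.origin[0]
        assert split.origin[1] == 14

    def test_invariant_to_empty_margins(self):
        a = split_regions(self._slab(9, lead=0, trail=0))
        b = split_regions(self._slab(9, lead=5, trail=1))
        assert a.lengths() == b.lengths()

    def test_too_few_slices(self):
        with pytest.raises(ValueError, match="3 muscle-bearing"):
            split_regions(self._slab(2))


class TestRegionalMetrics:
    def _pair(self, rng):
        g = np.zeros((9, 12, 12), np.uint8)
        for s in range(9):
            g[s, 2:6, 2:6] = 1
            g[s, 7:10, 7:10] = 5
        p = g.copy()
        return _lv(p), _lv(g)

    def test_perfect_prediction(self, rng):
        p, g = self._pair(rng)
        split = split_regions(g)
        reg = regional_metrics(p, g, split)
        for r in ("insertion", "central", "origin"):
            assert reg[r][1] == (1.0, 1.0)
            assert reg[r][5] == (1.0, 1.0)

    def test_origin_corruption_is_local(self, rng):
        p, g = self._pair(rng)
        split = split_regions(g)
        p.labels[split.origin[0] :, :, :] = 0  # destroy the origin third
        reg = regional_metrics(p, g, split)
        assert reg["insertion"][1] == (1.0, 1.0)
        assert reg["central"][1] == (1.0, 1.0)
        assert reg["origin"][1][0] == 0.0

    def test_equals_whole_volume_metric_on_sliced_arrays(self, rng):
        g = (rng.random((9, 10, 10)) < 0.2).astype(np.uint8)
        p = (rng.random((9, 10, 10)) < 0.2).astype(np.uint8)
        g[0, 0, 0] = 1  # ensure bearing slices exist at both ends
        g[8, 0, 0] = 1
        gv, pv = _lv(g), _lv(p)
        split = split_regions(gv)
        reg = regional_metrics(pv, gv, split)
        a, b = split.central
        assert reg["central"][1] == dice_iou(p[a:b], g[a:b], 1)


class TestMaeMape:
    def test_hand_arithmetic(self):
        mae, mape = mae_mape([5, 4], [4, 5])
        assert mae == pytest.approx(1.0)
        assert mape == pytest.approx(22.5)

    def test_identical(self):
        assert mae_mape([3.3, 4.4], [3.3, 4.4]) == (0.0, 0.0)

    def test_single_pair(self):
        mae, mape = mae_mape([4.4], [4.0])
        assert mae == pytest.approx(0.4)
        assert mape == pytest.approx(10.0)

    def test_zero_ground_truth_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero ground truth"):
            mae, mape = mae_mape([1.0, 2.0], [0.0, 4.0])
        assert mae == pytest.approx(1.5)
        assert mape == pytest.approx(50.0)

    def test_matches_bruteforce_loop(self, rng):
        for _ in range(5):
            pr = rng.uniform(1, 10, 17)
            gt = rng.uniform(1, 10, 17)
            mae, mape = mae_mape(pr, gt)
            mae_ref = sum(abs(a - b) for a, b in zip(pr, gt)) / 17
            mape_ref = sum(abs(a - b) / b for a, b in zip(pr, gt)) / 17 * 100
            assert mae == pytest.approx(mae_ref)
            assert mape == pytest.approx(mape_ref)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mae_mape([], [])


class TestReportTables:
    def _report(self, rng):
        from eomseg.evaluation import evaluate_cohort

        g = np.zeros((9, 12, 12), np.uint8)
        for s in range(9):
            g[s, 2:6, 2:6] = 1
            g[s, 7:10, 7:10] = 5
        return evaluate_cohort([(_lv(g.copy()), _lv(g))])

    def test_per_class_frame_has_pooled_row(self, rng):
        df = self._report(rng).per_class_frame()
        assert df.iloc[-1]["name"] == "all"
        assert df.iloc[-1]["dice_mean"] == 1.0

    def test_regional_frame_layout(self, rng):
        df = self._report(rng).regional_frame()
        assert len(df) == 8
        assert {"insertion_dice", "central_dice", "origin_dice"} <= set(df.columns)

    def test_json_bundle_parses(self, rng):
        import json

        bundle = json.loads(self._report(rng).to_json())
        assert bundle["pooled_dice"] == 1.0
        assert bundle["thickness"]["mape_percent"] == 0.0

    def test_measurement_table_pools_classes(self, rng):
        from eomseg.evaluation import measurement_table
        from eomseg.morphometry import measure_volume

        g = np.zeros((3, 20, 20), np.uint8)
        g[:, 4:9, 4:14] = 1
        g[:, 12:16, 4:12] = 5
        p = g.copy()
        p[:, 4:9, 13] = 0  # shave one column from class 1
        reps_p = [measure_volume(_lv(p))]
        reps_g = [measure_volume(_lv(g))]
        df = measurement_table(reps_p, reps_g)
        assert list(df["class"])[-1] == -1
        row1 = df[df["class"] == 1].iloc[0]
        assert row1["area_mae_mm2"] > 0
        row5 = df[df["class"] == 5].iloc[0]
        assert row5["thickness_mae_mm"] == 0.0


class TestWelch:
    def test_identical_groups_high_p(self, rng):
        from eomseg.evaluation import welch_test

        a = rng.normal(0.9, 0.02, 30)
        t, p = welch_test(a, a)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_low_p(self, rng):
        from eomseg.evaluation import welch_test

        a = rng.normal(0.9, 0.01, 30)
        b = rng.normal(0.7, 0.01, 30)
        _, p = welch_test(a, b)
        assert p < 1e-6

    def test_matches_scipy_reference(self, rng):
        from scipy import stats

        from eomseg.evaluation import welch_test

        a = rng.normal(0.8, 0.05, 12)
        b = rng.normal(0.82, 0.08, 9)
        t, p = welch_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))
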