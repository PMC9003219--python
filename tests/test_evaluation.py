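"""Evaluation: distances, IoU/AP, and the statistical battery vs oracles."""


import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from plantarfpa import evaluation as ev
from plantarfpa.errors import (
    DegenerateTestError,
    EmptyEvaluationError,
    InvalidInputError,
    UndefinedAPError,
)
from plantarfpa.geometry import GroundTruthPoints, PixelCornerPair


def box(x1, y1, x2, y2):
    return PixelCornerPair(x1, y1, x2, y2)


class TestPointDistance:
    @pytest.mark.parametrize(
        "g, p, d",
        [((0, 0), (3, 4), 5.0), ((7, 7), (7, 7), 0.0), ((10, 20), (13, 24), 5.0)],
    )
    def test_examples(self, g, p, d):
        assert ev.point_distance(g, p) == pytest.approx(d, abs=1e-12)

    def test_metric_axioms_random_triples(self):
        rng = np.random.default_rng(17)
        pts = rng.uniform(-100, 100, size=(50, 3, 2))
        for a, b, c in pts:
            dab, dba = ev.point_distance(a, b), ev.point_distance(b, a)
            assert dab >= 0 and dab == dba
            assert ev.point_distance(a, a) == 0
            assert ev.point_distance(a, c) <= dab + ev.point_distance(b, c) + 1e-9


class TestIoU:
    def test_identical(self):
        assert ev.iou(box(0, 0, 2, 2), box(0, 0, 2, 2)) == 1.0

    def test_disjoint(self):
        assert ev.iou(box(0, 0, 1, 1), box(5, 5, 6, 6)) == 0.0

    def test_hand_example(self):
        # inter 1, union 4+4-1=7
        assert ev.iou(box(0, 0, 2, 2), box(1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_zero_area_boxes(self):
        assert ev.iou(box(1, 1, 1, 1), box(1, 1, 1, 1)) == 0.0


def _brute_force_ap(tp_flags, n_gt):
    """Independent all-point AP: integrate max-precision envelope directly."""
    pairs = []
    tp = 0
    for i, flag in enumerate(tp_flags, start=1):
        tp += flag
        pairs.append((tp / n_gt, tp / i))
    ap = 0.0
    prev_r = 0.0
    for r, _ in pairs:
        if r > prev_r:
            best_p = max(p for rr, p in pairs if rr >= r)
            ap += (r - prev_r) * best_p
            prev_r = r
    return ap


class TestAveragePrecision:
    GT = {"i1": box(0, 0, 10, 10), "i2": box(0, 0, 10, 10)}

    def test_perfect_detection(self):
        dets = [ev.Detection("i1", 0.9, box(0, 0, 10, 10))]
        assert ev.average_precision(dets, {"i1": box(0, 0, 10, 10)}) == 1.0

    def test_worked_example_matches_brute_force(self):
        dets = [
            ev.Detection("i1", 0.9, box(0, 0, 10, 10)),      # TP
            ev.Detection("i1", 0.8, box(50, 50, 60, 60)),    # FP (gt already matched)
            ev.Detection("i2", 0.7, box(0, 0, 10, 10)),      # TP
        ]
        ap = ev.average_precision(dets, self.GT)
        assert ap == pytest.approx(_brute_force_ap([1, 0, 1], 2), abs=1e-12)
        assert ap == pytest.approx(5 / 6, abs=1e-9)

    def test_all_false_positives(self):
        dets = [ev.Detection("i1", 0.9, box(90, 90, 99, 99))]
        assert ev.average_precision(dets, self.GT) == 0.0

    def test_confidence_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        dets = [
            ev.Detection(f"i{k}", float(c), box(0, 0, 10, 10) if k % 2 else box(50, 50, 60, 60))
            for k, c in enumerate(rng.uniform(0.1, 0.9, 8))
        ]
        gts = {f"i{k}": box(0, 0, 10, 10) for k in range(8)}
        ap1 = ev.average_precision(dets, gts)
        rescaled = [
            ev.Detection(d.image_id, math.tanh(3 * d.confidence), d.corners) for d in dets
        ]
        assert ev.average_precision(rescaled, gts) == pytest.approx(ap1, abs=1e-12)

    def test_no_ground_truth_undefined(self):
        with pytest.raises(UndefinedAPError):
            ev.average_precision([], {})

    def test_map_unweighted_mean(self):
        assert ev.mean_average_precision({"l": 1.0, "r": 0.5}) == 0.75


class TestBasicStats:
    def test_mean_se_examples(self):
        assert ev.mean_se([5, 5, 5]) == (5.0, 0.0)
        m, se = ev.mean_se([1, 2, 3])
        assert (m, se) == (2.0, pytest.approx(1 / math.sqrt(3), abs=1e-9))
        with pytest.raises(InvalidInputError):
            ev.mean_se([4.0])

    def test_paired_t_hand_example(self):
        r = ev.paired_t_test([10, 12, 9, 11], [8, 11, 7, 10])
        # d = [2,1,2,1]: mean 1.5, sd sqrt(1/3), t = 1.5/(sd/2)
        assert r.statistic == pytest.approx(1.5 / (math.sqrt(1 / 3) / 2), abs=1e-9)
        assert r.df == (3.0,)
        assert r.p_value == pytest.approx(0.0138, abs=2e-3)
        assert not r.significant  # alpha = 0.01

    def test_paired_t_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.normal(size=8)
            b = a + rng.normal(0.3, 1.0, size=8)
            ours = ev.paired_t_test(a, b)
            ref = sps.ttest_rel(a, b)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_paired_t_degenerate_and_zero_mean(self):
        with pytest.raises(DegenerateTestError):
            ev.paired_t_test([1, 2, 3], [1, 2, 3])
        r = ev.paired_t_test([1, 2, 3, 4], [2, 1, 4, 3])
        assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)


class TestAnovaLSD:
    def test_hand_example(self):
        r = ev.one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert r.statistic == pytest.approx(3.0, abs=1e-9)
        assert r.df == (2.0, 6.0)

    def test_identical_groups_f_zero(self):
        r = ev.one_way_anova([[1, 2, 3]] * 3)
        assert r.statistic == 0.0

    def test_all_identical_degenerate(self):
        with pytest.raises(DegenerateTestError):
            ev.one_way_anova([[2, 2], [2, 2]])

    def test_matches_scipy_random(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            groups = [rng.normal(m, 1, size=rng.integers(3, 9)) for m in (0, 0.5, 1)]
            ours = ev.one_way_anova(groups)
            ref = sps.f_oneway(*groups)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        f = ev.one_way_anova([a, b]).statistic
        t = sps.ttest_ind(a, b).statistic
        assert f == pytest.approx(t**2, abs=1e-9)

    def test_lsd_pairwise_unadjusted(self):
        groups = [[1, 2, 3], [2, 3, 4], [6, 7, 8]]
        r = ev.fisher_lsd(groups, alpha=0.01)
        assert len(r.pairwise) == 3
        # oracle: direct pooled-variance pairwise t
        mse = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups) / 6
        for cmp_ in r.pairwise:
            i = int(cmp_.label_a[-1])
            j = int(cmp_.label_b[-1])
            diff = np.mean(groups[i]) - np.mean(groups[j])
            t = diff / math.sqrt(mse * (1 / 3 + 1 / 3))
            assert cmp_.statistic == pytest.approx(t, abs=1e-9)
            assert cmp_.p_value == pytest.approx(2 * sps.t.sf(abs(t), 6), abs=1e-12)

    def test_lsd_equal_means_p_one(self):
        r = ev.fisher_lsd([[1, 2, 3], [3, 1, 2], [2, 3, 1]])
        for cmp_ in r.pairwise:
            assert cmp_.p_value == pytest.approx(1.0)


def _measurement_frame(ids, thetas, fronts, rears, missing=None):
    missing = missing or [False] * len(ids)
    return pd.DataFrame(
        {
            "image_id": ids,
            "side": ["left"] * len(ids),
            "toeing": ["out"] * len(ids),
            "theta": thetas,
            "front_x": [f[0] for f in fronts],
            "front_y": [f[1] for f in fronts],
            "rear_x": [r[0] for r in rears],
            "rear_y": [r[1] for r in rears],
            "missing": missing,
        }
    )


class TestEvaluateRun:
    def _gt(self, n):
        return {
            f"i{k}": GroundTruthPoints((50.0 + k, 150.0), (60.0, 320.0)) for k in range(n)
        }

    def test_identity_predictions(self):
        gt = self._gt(4)
        df = _measurement_frame(
            [f"i{k}" for k in range(4)],
            [5.0, 6.0, 7.0, 8.0],
            [gt[f"i{k}"].g1 for k in range(4)],
            [gt[f"i{k}"].g2 for k in range(4)],
        )
        angles = {f"i{k}": t for k, t in zip(range(4), [5.0, 6.0, 7.0, 8.0])}
        report = ev.evaluate_run({"m": df}, gt, angles)
        assert report["n_excluded"] == 0
        for row in report["distances"]["per_model"]:
            assert row["d_front_mean"] == 0.0 and row["d_rear_mean"] == 0.0
        # identical groups: zero between-group variance, F = 0
        assert report["fpa"]["anova_lsd"]["statistic"] == pytest.approx(0.0, abs=1e-12)
        # zero-variance distance differences are flagged degenerate
        assert report["front_vs_rear"]["m"].get("degenerate") is True

    def test_constant_offset_distance_five(self):
        gt = self._gt(6)
        ids = [f"i{k}" for k in range(6)]
        fronts = [(gt[i].g1[0] + 3, gt[i].g1[1] + 4) for i in ids]
        rears = [(gt[i].g2[0] + 3, gt[i].g2[1] + 4) for i in ids]
        df = _measurement_frame(ids, [5.0 + 0.1 * k for k in range(6)], fronts, rears)
        report = ev.evaluate_run({"m": df}, gt)
        row = report["distances"]["per_model"][0]
        assert row["d_front_mean"] == pytest.approx(5.0, abs=1e-9)
        assert row["d_rear_mean"] == pytest.approx(5.0, abs=1e-9)

    def test_missing_rows_counted(self):
        gt = self._gt(5)
        ids = [f"i{k}" for k in range(5)]
        df = _measurement_frame(
            ids, [5, 6, np.nan, 7, np.nan],
            [gt[i].g1 for i in ids], [gt[i].g2 for i in ids],
            missing=[False, False, True, False, True],
        )
        report = ev.evaluate_run({"m": df}, gt)
        assert report["n_excluded"] == 2
        assert report["n_used"] == 3
        assert report["excluded_per_model"]["m"] == 2

    def test_no_overlap_raises(self):
        df = _measurement_frame(["zz"], [5.0], [(0, 0)], [(0, 1)])
        with pytest.raises(EmptyEvaluationError):
            ev.evaluate_run({"m": df}, self._gt(2))
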