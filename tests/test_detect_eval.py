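"""Detection extraction, 5 mm adjudication, FROC, AUC, CV splits."""

import numpy as np
import pytest

from symzone import detect_eval as de


def _point(voxel, score, spacing=(1.0, 1.0, 1.0)):
    world = tuple(v * s for v, s in zip(voxel, spacing))
    return de.DetectionPoint(voxel, score, world)


class TestExtraction:
    def test_single_gaussian_bump_gives_one_peak_at_argmax(self):
        z, y, x = np.mgrid[0:8, 0:16, 0:16]
        bump = np.exp(-(((z - 4) ** 2) / 4 + ((y - 8) ** 2) / 9
                        + ((x - 8) ** 2) / 9))
        pts = de.extract_detections(bump, min_score=0.1, spacing=(1, 1, 1))
        assert len(pts) == 1 and pts[0].voxel == (4, 8, 8)

    def test_constant_map_has_no_detections(self):
        assert de.extract_detections(np.full((4, 8, 8), 0.7),
                                     spacing=(1, 1, 1)) == []

    def test_saturated_plateau_is_one_detection(self):
        v = np.zeros((4, 8, 8))
        v[1:3, 2:5, 2:5] = 1.0
        pts = de.extract_detections(v, spacing=(1, 1, 1))
        assert len(pts) == 1 and pts[0].score == 1.0

    def test_two_separated_bumps_give_two_detections_sorted(self):
        v = np.zeros((4, 16, 16))
        v[2, 3, 3], v[2, 12, 12] = 0.8, 0.9
        pts = de.extract_detections(v, min_separation_mm=5, spacing=(1, 1, 1))
        assert [p.score for p in pts] == [0.9, 0.8]

    def test_nms_suppresses_nearby_weaker_peak(self):
        v = np.zeros((4, 16, 16))
        v[2, 3, 3], v[2, 3, 6] = 0.9, 0.8
        pts = de.extract_detections(v, min_separation_mm=5, spacing=(1, 1, 1))
        assert len(pts) == 1 and pts[0].voxel == (2, 3, 3)

    def test_two_channel_map_uses_p0_by_default(self):
        v = np.zeros((2, 4, 8, 8))
        v[0, 2, 4, 4] = 0.9
        v[1, 2, 4, 6] = 0.95
        pts = de.extract_detections(v, spacing=(1, 1, 1))
        assert len(pts) == 1 and pts[0].score == pytest.approx(0.9)


class TestAdjudication:
    spacing = (3.0, 0.625, 0.625)

    def _mask(self):
        m = np.zeros((8, 64, 64), dtype=np.uint8)
        m[4, 30:34, 30:34] = 1
        return m

    def test_point_on_lesion_is_tp(self):
        pts = [_point((4, 31, 31), 0.9, self.spacing)]
        ds = de.adjudicate(pts, self._mask(), self.spacing)
        assert ds.is_tp.tolist() == [True] and ds.n_lesions == 1

    def test_point_ten_mm_away_is_fp(self):
        # 16 in-plane voxels x 0.625 mm = 10 mm > 5 mm
        pts = [_point((4, 31, 49), 0.9, self.spacing)]
        ds = de.adjudicate(pts, self._mask(), self.spacing)
        assert ds.is_tp.tolist() == [False]

    def test_empty_detection_list(self):
        ds = de.adjudicate([], self._mask(), self.spacing)
        assert ds.n_lesions == 1
        assert np.all(ds.lesion_detection_scores() == -np.inf)

    def test_multiple_tps_on_one_lesion_do_not_create_fps(self):
        pts = [_point((4, 31, 31), 0.9, self.spacing),
               _point((4, 32, 32), 0.7, self.spacing)]
        ds = de.adjudicate(pts, self._mask(), self.spacing)
        assert ds.is_tp.sum() == 2 and (~ds.is_tp).sum() == 0

    def test_order_independent(self, rng):
        mask = self._mask()
        pts = [_point((4, 31, 31), 0.9, self.spacing),
               _point((4, 31, 49), 0.8, self.spacing),
               _point((0, 5, 5), 0.3, self.spacing)]
        a = de.adjudicate(pts, mask, self.spacing)
        order = rng.permutation(3)
        b = de.adjudicate([pts[i] for i in order], mask, self.spacing)
        assert sorted(zip(a.scores, a.is_tp)) == sorted(zip(b.scores, b.is_tp))

    def test_missing_spacing_raises(self):
        with pytest.raises(ValueError, match="spacing"):
            de.adjudicate([], self._mask(), None)


def _toy_sets():
    """Patient A: one lesion, TP@0.9, FP@0.4.  Patient B: no lesion, FP@0.6."""
    a = de.DetectionSet("A", [_point((0, 0, 0), 0.9), _point((0, 5, 5), 0.4)],
                        np.array([True, False]), np.array([0, -1]), 1)
    b = de.DetectionSet("B", [_point((0, 3, 3), 0.6)],
                        np.array([False]), np.array([-1]), 0)
    return [a, b]


class TestFROC:
    def test_hand_enumerated_threshold_sweep(self):
        """Thresholds 0.9/0.6/0.4 give (FP/pt, sens) = (0,1), (0.5,1), (1,1)."""
        res = de.froc(_toy_sets())
        np.testing.assert_allclose(res.thresholds, [0.9, 0.6, 0.4])
        np.testing.assert_allclose(res.sensitivity, [1.0, 1.0, 1.0])
        np.testing.assert_allclose(res.fp_per_patient, [0.0, 0.5, 1.0])
        assert res.operating_sensitivity[0.5] == 1.0

    def test_perfect_detector_saturates_sensitivity(self):
        sets = [de.DetectionSet(f"c{i}", [_point((0, 0, 0), 0.9)],
                                np.array([True]), np.array([0]), 1)
                for i in range(3)]
        res = de.froc(sets)
        assert all(v == 1.0 for v in res.operating_sensitivity.values())

    def test_monotone_in_fp_budget(self, rng):
        sets = []
        for i in range(6):
            n_pts = int(rng.integers(1, 6))
            scores = rng.uniform(0, 1, n_pts)
            tp = rng.integers(0, 2, n_pts).astype(bool)
            lid = np.where(tp, 0, -1)
            pts = [_point((0, int(k), 0), float(s))
                   for k, s in enumerate(scores)]
            sets.append(de.DetectionSet(f"c{i}", pts, tp, lid, 1))
        res = de.froc(sets)
        ops = [res.operating_sensitivity[f] for f in de.OPERATING_POINTS]
        assert ops == sorted(ops)
        assert res.operating_sensitivity[2.5] >= res.operating_sensitivity[0.5]

    def test_zero_lesion_cohort_raises(self):
        b = _toy_sets()[1]
        with pytest.raises(ValueError, match="no lesions"):
            de.froc([b])


class TestPatientLevel:
    def test_patient_score_is_max_and_mirror_invariant(self, rng):
        pm = rng.uniform(0, 0.8, size=(2, 4, 8, 8))
        pm[0, 2, 3, 5] = 0.93
        assert de.patient_score(pm) == pytest.approx(0.93)
        assert de.patient_score(pm[:, :, :, ::-1]) == pytest.approx(0.93)
        assert de.patient_score(np.zeros((2, 2, 2, 2))) == 0.0

    def test_auc_toy_values_and_pair_enumeration(self, rng):
        assert de.roc_auc([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0]) == 1.0
        assert de.roc_auc([0.9, 0.4, 0.8, 0.2], [1, 1, 0, 0]) == 0.75
        scores = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        brute = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert de.roc_auc(scores, labels) == pytest.approx(float(brute), abs=1e-12)

    def test_auc_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            de.roc_auc([0.1, 0.2], [1, 1])

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200)
        labels = (scores + rng.normal(size=200) > 0).astype(int)
        assert de.roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        scores = np.concatenate([rng.normal(1.0, 1.0, 40), rng.normal(0, 1, 40)])
        labels = np.array([1] * 40 + [0] * 40)
        cases = list(zip(scores, labels))

        def metric(cs):
            return de.roc_auc([c[0] for c in cs], [c[1] for c in cs])

        lo, hi = de.bootstrap_ci(metric, cases, n_boot=200, seed=0)
        assert 0.5 < lo <= metric(cases) <= hi <= 1.0
        lo2, hi2 = de.bootstrap_ci(metric, cases, n_boot=200, seed=0)
        assert (lo, hi) == (lo2, hi2)


class TestCVSplits:
    def test_652_cases_give_131_131_130_130_130(self):
        folds = de.make_cv_splits(list(range(652)), k=5, seed=0)
        assert sorted(len(f) for f in folds) == [130, 130, 130, 131, 131]

    def test_partition_properties_and_reproducibility(self):
        ids = [f"case{i}" for i in range(23)]
        folds = de.make_cv_splits(ids, k=5, seed=7)
        flat = np.concatenate(folds)
        assert sorted(flat) == sorted(ids)
        assert len(set(flat)) == len(ids)
        folds2 = de.make_cv_splits(ids, k=5, seed=7)
        for a, b in zip(folds, folds2):
            np.testing.assert_array_equal(a, b)

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            de.make_cv_splits([1, 2], k=5)
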