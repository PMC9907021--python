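import numpy as np
import pytest

from contourbench import (
    case_level_performance,
    class_consensus_evaluation,
    correlate_case_performance,
    dice,
    staple_em,
    tertile_stratify,
)
from contourbench.benchmark import AcceptabilityThreshold
from contourbench.io import Expertise, ObserverContour
from contourbench.metrics import Metric
from contourbench.simulate import simulate_observer_boundary
from contourbench.stratify import (
    CaseLevelScore,
    DegenerateStratificationError,
    InsufficientOverlapError,
    NoScoreError,
)

from conftest import make_mask


def _scores(values, case_id="case", metric=Metric.DSC):
    return [
        CaseLevelScore(f"obs_{i:03d}", case_id, metric, float(v), 1)
        for i, v in enumerate(values)
    ]


class TestCaseLevelPerformance:
    def _contour(self, roi, mask):
        return ObserverContour("obs", Expertise.NONEXPERT, "case", roi, mask)

    def test_mean_over_rois(self, sphere_truth_32):
        # one ROI agrees perfectly (DSC 1), the other is half-overlapping
        half = np.array(sphere_truth_32.voxels)
        idx = np.argwhere(half)
        half[tuple(idx[: len(idx) // 2].T)] = False
        half_mask = make_mask(half, sphere_truth_32.spacing)
        consensus = {"roi_a": sphere_truth_32, "roi_b": sphere_truth_32}
        contours = [
            self._contour("roi_a", sphere_truth_32),
            self._contour("roi_b", half_mask),
        ]
        score = case_level_performance(contours, consensus, Metric.DSC)
        expected = 0.5 * (1.0 + float(dice(half_mask, sphere_truth_32)))
        assert score.value == pytest.approx(expected)
        assert score.n_rois_used == 2

    def test_single_roi(self, sphere_truth_32):
        score = case_level_performance(
            [self._contour("roi_a", sphere_truth_32)],
            {"roi_a": sphere_truth_32},
            Metric.DSC,
        )
        assert score.value == 1.0 and score.n_rois_used == 1

    def test_zero_rois_rejected(self):
        with pytest.raises(NoScoreError):
            case_level_performance([], {}, Metric.DSC)

    def test_undefined_rois_excluded(self, sphere_truth_32):
        empty = make_mask(np.zeros(sphere_truth_32.shape),
                          sphere_truth_32.spacing)
        contours = [
            self._contour("roi_a", sphere_truth_32),
            self._contour("roi_b", empty),  # undefined MSD
        ]
        consensus = {"roi_a": sphere_truth_32, "roi_b": sphere_truth_32}
        score = case_level_performance(contours, consensus, Metric.MSD)
        assert score.n_rois_used == 1


class TestCorrelation:
    def test_perfect_positive(self):
        a = _scores([0.1, 0.4, 0.5, 0.9])
        b = _scores([2 * s.value + 1 for s in a], case_id="other")
        r, p, n = correlate_case_performance(a, b)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_perfect_negative(self):
        a = _scores([0.1, 0.4, 0.5])
        b = _scores([-s.value for s in a], case_id="other")
        r, _, _ = correlate_case_performance(a, b)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        xs, ys = [1, 2, 3, 4, 5], [2, 1, 4, 3, 6]
        a, b = _scores(xs), _scores(ys, case_id="other")
        r, p, n = correlate_case_performance(a, b)
        x, y = np.array(xs, float), np.array(ys, float)
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        oracle = cov / (x.std() * y.std())
        assert r == pytest.approx(oracle)
        assert n == 5

    def test_only_overlapping_observers_used(self):
        a = _scores([0.1, 0.2, 0.3, 0.4])
        b = [
            CaseLevelScore(f"obs_{i:03d}", "other", Metric.DSC, v, 1)
            for i, v in [(0, 0.2), (1, 0.4), (2, 0.6), (9, 0.99)]
        ]
        _, _, n = correlate_case_performance(a, b)
        assert n == 3

    def test_insufficient_overlap(self):
        a = _scores([0.1, 0.2])
        b = _scores([0.3, 0.4], case_id="other")
        with pytest.raises(InsufficientOverlapError):
            correlate_case_performance(a, b)

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        xs = rng.random(10)
        ys = rng.random(10)
        a, b = _scores(xs), _scores(ys, case_id="other")
        r1, _, _ = correlate_case_performance(a, b)
        b_scaled = _scores(3.0 * ys + 0.2, case_id="other")
        r2, _, _ = correlate_case_performance(a, b_scaled)
        assert r1 == pytest.approx(r2)


class TestTertileStratification:
    def test_nine_equally_spaced_balanced(self):
        assignment = tertile_stratify(_scores(np.linspace(0.1, 0.9, 9)))
        assert assignment.class_sizes() == {"low": 3, "medium": 3, "high": 3}

    def test_124_distinct_scores_split_42_41_41(self):
        rng = np.random.default_rng(0)
        values = np.unique(rng.random(300))[:124]
        assert len(values) == 124
        assignment = tertile_stratify(_scores(values))
        assert assignment.class_sizes() == {"low": 42, "medium": 41, "high": 41}

    def test_66_distinct_scores_split_evenly(self):
        rng = np.random.default_rng(1)
        values = np.unique(rng.random(200))[:66]
        assignment = tertile_stratify(_scores(values))
        assert assignment.class_sizes() == {"low": 22, "medium": 22, "high": 22}

    def test_edges_ascending_and_boundary_convention(self):
        values = np.linspace(0.0, 1.0, 10)
        a = tertile_stratify(_scores(values))
        lo, t1, t2, hi = a.bin_edges
        assert lo < t1 < t2 < hi
        # low gets value <= t1, high gets value > t2
        by_obs = {f"obs_{i:03d}": v for i, v in enumerate(values)}
        for obs in a.members("low"):
            assert by_obs[obs] <= t1
        for obs in a.members("medium"):
            assert t1 < by_obs[obs] <= t2
        for obs in a.members("high"):
            assert by_obs[obs] > t2

    def test_order_invariant(self):
        rng = np.random.default_rng(3)
        values = rng.random(30)
        scores = _scores(values)
        shuffled = [scores[i] for i in rng.permutation(30)]
        assert tertile_stratify(scores).classes == tertile_stratify(shuffled).classes

    def test_degenerate_identical_scores(self):
        with pytest.raises(DegenerateStratificationError):
            tertile_stratify(_scores([0.5] * 10))


class TestClassConsensusEvaluation:
    def _assignment(self, classes):
        return __import__("contourbench").stratify.TertileAssignment(
            case_id="case", metric=Metric.DSC,
            bin_edges=(0.0, 0.3, 0.6, 1.0), classes=classes,
        )

    def test_expert_copies_all_cross(self, sphere_truth_32):
        truth = sphere_truth_32
        experts = [
            simulate_observer_boundary(truth, 1.0, 0.0, 6.0, seed=s)
            for s in range(6)
        ]
        expert_consensus = staple_em(experts).consensus_mask
        contours = [
            ObserverContour(f"obs_{j:02d}", Expertise.NONEXPERT, "case", "roi",
                            experts[j])
            for j in range(6)
        ]
        classes = {f"obs_{j:02d}": cls
                   for j, cls in enumerate(["low", "low", "medium", "medium",
                                            "high", "high"])}
        thresholds = {
            ("roi", "DSC"): AcceptabilityThreshold("case", "roi", Metric.DSC, 0.8)
        }
        table = class_consensus_evaluation(
            self._assignment(classes), {"roi": contours},
            {"roi": expert_consensus}, thresholds,
        )
        assert len(table) == 3  # 3 classes x 1 ROI x 1 metric
        assert table.crossed.all()

    def test_small_class_recorded_missing(self, sphere_truth_32):
        contours = [
            ObserverContour("obs_00", Expertise.NONEXPERT, "case", "roi",
                            sphere_truth_32),
            ObserverContour("obs_01", Expertise.NONEXPERT, "case", "roi",
                            sphere_truth_32),
        ]
        classes = {"obs_00": "low", "obs_01": "low"}
        thresholds = {
            ("roi", "DSC"): AcceptabilityThreshold("case", "roi", Metric.DSC, 0.8)
        }
        table = class_consensus_evaluation(
            self._assignment(classes), {"roi": contours},
            {"roi": sphere_truth_32}, thresholds,
        )
        missing = table[table["class"] != "low"]
        assert (~missing.crossed).all()
        assert missing.value.isna().all()

    @pytest.mark.parametrize("seed", range(5))
    def test_high_class_crosses_at_least_as_often_as_low(self, sphere_truth_32, seed):
        """A low-noise 'high' class beats a noisy over-segmenting 'low'
        class in per-class consensus evaluation."""
        truth = sphere_truth_32
        experts = [
            simulate_observer_boundary(truth, 1.0, 0.0, 6.0, seed=100 + seed * 10 + s)
            for s in range(5)
        ]
        expert_consensus = staple_em(experts).consensus_mask
        high = [
            simulate_observer_boundary(truth, 1.0, 0.0, 6.0, seed=200 + seed * 10 + s)
            for s in range(4)
        ]
        low = [
            simulate_observer_boundary(truth, 2.5, 2.0, 6.0, seed=300 + seed * 10 + s)
            for s in range(4)
        ]
        contours = [
            ObserverContour(f"h{j}", Expertise.NONEXPERT, "case", "roi", m)
            for j, m in enumerate(high)
        ] + [
            ObserverContour(f"l{j}", Expertise.NONEXPERT, "case", "roi", m)
            for j, m in enumerate(low)
        ]
        classes = {f"h{j}": "high" for j in range(4)}
        classes.update({f"l{j}": "low" for j in range(4)})
        thresholds = {
            ("roi", "DSC"): AcceptabilityThreshold("case", "roi", Metric.DSC, 0.9)
        }
        table = class_consensus_evaluation(
            self._assignment(classes), {"roi": contours},
            {"roi": expert_consensus}, thresholds,
        )
        crossed = table.set_index("class").crossed
        assert int(crossed["high"]) >= int(crossed["low"])

    def test_output_shape_three_classes_per_roi(self, sphere_truth_32):
        contours = {
            roi: [
                ObserverContour(f"obs_{j:02d}", Expertise.NONEXPERT, "case", roi,
                                sphere_truth_32)
                for j in range(6)
            ]
            for roi in ("roi_a", "roi_b")
        }
        classes = {f"obs_{j:02d}": cls
                   for j, cls in enumerate(["low", "low", "medium", "medium",
                                            "high", "high"])}
        thresholds = {
            (roi, "DSC"): AcceptabilityThreshold("case", roi, Metric.DSC, 0.5)
            for roi in contours
        }
        table = class_consensus_evaluation(
            self._assignment(classes), contours,
            {roi: sphere_truth_32 for roi in contours}, thresholds,
        )
        assert len(table) == 3 * 2
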