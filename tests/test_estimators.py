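import numpy as np
import pandas as pd
import pytest

from conftest import random_roc_instance, roc_oracle
from mpcsim import (
    EstimatorSettings,
    anchor_correlation,
    es_based,
    mean_change_minimal_group,
    mean_diff_adjacent,
    results_to_frame,
    roc_threshold,
    run_all,
    sem_based,
)


class TestAnchorCorrelation:
    def test_perfect_monotone_association(self):
        change = np.array([-3.0, -0.1, 0.0, 0.2, 2.0, 3.0])
        cats = np.array([-1, 0, 0, 0, 1, 1])
        assert anchor_correlation(change, cats) > 0.9

    def test_strictly_increasing_gives_one(self):
        change = np.array([-2.0, 0.0, 2.0])
        cats = np.array([-1, 0, 1])
        assert anchor_correlation(change, cats) == pytest.approx(1.0)

    def test_independent_permutation_is_near_zero(self):
        rng = np.random.default_rng(0)
        change = rng.normal(0, 1, 10_000)
        cats = rng.permutation(np.repeat([-1, 0, 1], 10_000 // 3 + 1)[:10_000])
        assert abs(anchor_correlation(change, cats)) < 0.05

    @pytest.mark.parametrize("cats", [[0, 0, 0], [1, 1, 1]])
    def test_constant_anchor_errors(self, cats):
        with pytest.raises(ValueError, match="undefined"):
            anchor_correlation([1.0, 2.0, 3.0], cats)

    def test_constant_change_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            anchor_correlation([2.0, 2.0, 2.0], [-1, 0, 1])


class TestGroupMeanEstimators:
    def test_minimal_group_mean(self):
        change = np.array([2.0, 4.0, 0.0])
        cats = np.array([1, 1, 0])
        res = mean_change_minimal_group(change, cats, "improvement")
        assert res.value == 3.0
        assert res.n_anchor_group == 2

    def test_single_subject_group(self):
        res = mean_change_minimal_group([5.0, 0.0], [1, 0], "improvement")
        assert res.value == 5.0

    def test_empty_group_not_estimable(self):
        res = mean_change_minimal_group([1.0, 2.0], [0, 0], "improvement")
        assert res.status == "not_estimable"
        assert np.isnan(res.value)

    def test_adjacent_difference(self):
        res = mean_diff_adjacent([3.0, 1.0], [1, 0], "improvement")
        assert res.value == 2.0

    def test_adjacent_difference_zero_when_means_equal(self):
        res = mean_diff_adjacent([2.0, 2.0], [1, 0], "improvement")
        assert res.value == 0.0

    def test_adjacent_deterioration_side(self):
        res = mean_diff_adjacent([-4.0, -2.0, 0.0], [-1, -1, 0], "deterioration")
        assert res.value == -3.0

    def test_adjacent_requires_both_groups(self):
        res = mean_diff_adjacent([1.0, 2.0], [1, 1], "improvement")
        assert res.status == "not_estimable"


class TestRocThreshold:
    def test_separated_classes(self):
        change = np.array([-1.0, 0.0, 1.0, 2.0, 3.0, 4.0])
        cats = np.array([0, 0, 0, 1, 1, 1])
        res = roc_threshold(change, cats, "improvement", "euclidean")
        assert res.value == 1.5
        assert res.details["sensitivity"] == 1.0
        assert res.details["specificity"] == 1.0

    def test_tie_broken_by_smallest_absolute_threshold(self):
        # candidates {0.5, 1.5, 2.5} give distances {0.5, sqrt(0.5), 0.5}
        change = np.array([0.0, 2.0, 1.0, 3.0])
        cats = np.array([0, 0, 1, 1])
        res = roc_threshold(change, cats, "improvement", "euclidean")
        assert res.value == 0.5

    def test_separated_singletons(self):
        res = roc_threshold([0.0, 10.0], [0, 1], "improvement")
        assert res.value == 5.0
        assert res.details["sensitivity"] == 1.0 and res.details["specificity"] == 1.0

    def test_pools_all_changed_categories(self):
        # category +2 subjects are part of the positive class
        change = np.array([0.0, 2.0, 5.0])
        cats = np.array([0, 1, 2])
        res = roc_threshold(change, cats, "improvement")
        assert res.n_anchor_group == 2

    def test_opposite_side_excluded(self):
        change = np.array([-9.0, 0.0, 2.0])
        cats = np.array([-1, 0, 1])
        res = roc_threshold(change, cats, "improvement")
        assert res.value == 1.0  # midpoint of {0, 2}; the -9 never enters

    def test_empty_class_not_estimable(self):
        res = roc_threshold([1.0, 2.0], [1, 1], "improvement")
        assert res.status == "not_estimable"

    @pytest.mark.parametrize("criterion", ["euclidean", "youden", "weighted"])
    @pytest.mark.parametrize("direction", ["improvement", "deterioration"])
    def test_matches_brute_force_oracle(self, criterion, direction):
        rng = np.random.default_rng(42)
        for _ in range(50):
            change, cats, pos, neg = random_roc_instance(rng)
            if direction == "deterioration":
                change, cats = -change, -cats
                pos, neg = [-x for x in pos], [-x for x in neg]
            res = roc_threshold(change, cats, direction, criterion, weight=0.7)
            thr, loss = roc_oracle(pos, neg, direction, criterion, weight=0.7)
            assert res.value == thr
            assert res.details["criterion_value"] == pytest.approx(loss, abs=1e-12)


class TestDistributionBased:
    def test_half_sd_rule(self):
        scores = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        assert es_based(scores).value == 0.5 * np.std(scores, ddof=1)

    def test_small_effect_multiplier(self):
        scores = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        assert es_based(scores, multiplier=0.2).value == pytest.approx(
            0.2 * np.std(scores, ddof=1)
        )

    def test_constant_baseline_gives_zero(self):
        assert es_based([3.0, 3.0, 3.0]).value == 0.0

    def test_sem_rule(self):
        scores = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        assert sem_based(scores, 0.84).value == pytest.approx(
            np.std(scores, ddof=1) * np.sqrt(0.16)
        )
        assert sem_based(scores, 1.0).value == 0.0
        assert sem_based(scores, 0.84, multiplier=2.0).value == pytest.approx(
            2.0 * np.std(scores, ddof=1) * np.sqrt(0.16)
        )

    def test_deterioration_is_negative(self):
        scores = np.array([0.0, 10.0])
        assert es_based(scores, direction="deterioration").value == -es_based(scores).value

    def test_invariant_to_anchor(self):
        # only the baseline scores matter; no guard fields attached
        scores = np.array([1.0, 4.0, 2.0, 8.0])
        res = es_based(scores)
        assert res.guard_correlation is None and res.guard_pass is None


class TestDirectionAntisymmetry:
    @pytest.mark.parametrize(
        "estimator",
        [mean_change_minimal_group, mean_diff_adjacent, roc_threshold],
    )
    def test_mirroring_negates_estimates(self, estimator):
        rng = np.random.default_rng(11)
        change = rng.normal(0.5, 1.0, 60)
        cats = rng.integers(-1, 2, 60)
        res_imp = estimator(change, cats, "improvement")
        res_det = estimator(-change, -cats, "deterioration")
        assert res_det.value == pytest.approx(-res_imp.value)


class TestRunAll:
    def _toy(self):
        scores = pd.DataFrame(
            {
                "subject_id": range(6),
                "score_t1": [10.0, 11.0, 9.0, 12.0, 10.5, 9.5],
                "score_t2": [10.5, 10.8, 13.0, 16.0, 7.0, 5.0],
            }
        )
        scores["change"] = scores["score_t2"] - scores["score_t1"]
        anchor = pd.DataFrame({"subject_id": range(6), "pgrc_category": [0, 0, 1, 1, -1, -1]})
        return scores, anchor

    def test_contains_exactly_configured_estimators(self):
        scores, anchor = self._toy()
        settings = EstimatorSettings(ids=["roc_threshold", "es_based"])
        results = run_all(scores, anchor, settings, reliability=0.9)
        assert [(r.estimator_id, r.direction) for r in results] == [
            ("roc_threshold", "improvement"),
            ("roc_threshold", "deterioration"),
            ("es_based", "improvement"),
            ("es_based", "deterioration"),
        ]

    def test_guard_attached_to_anchor_based_only(self):
        scores, anchor = self._toy()
        results = run_all(scores, anchor, reliability=0.9)
        for r in results:
            if r.estimator_id in ("es_based", "sem_based"):
                assert r.guard_correlation is None
            else:
                assert r.guard_correlation is not None
                assert r.guard_pass is not None

    def test_constant_anchor_disables_guard_but_keeps_distribution_based(self):
        scores, anchor = self._toy()
        anchor["pgrc_category"] = 0
        results = run_all(scores, anchor, reliability=0.9)
        by_id = {(r.estimator_id, r.direction): r for r in results}
        assert by_id[("roc_threshold", "improvement")].status == "not_estimable"
        assert by_id[("mean_change_minimal_group", "improvement")].status == "not_estimable"
        assert by_id[("es_based", "improvement")].status == "ok"
        assert by_id[("sem_based", "improvement")].status == "ok"

    def test_missing_reliability_marks_sem_not_estimable(self):
        scores, anchor = self._toy()
        results = run_all(scores, anchor, reliability=None)
        sems = [r for r in results if r.estimator_id == "sem_based"]
        assert all(r.status == "not_estimable" for r in sems)

    def test_result_csv_deterministic(self, tmp_path):
        scores, anchor = self._toy()
        frames = [results_to_frame(run_all(scores, anchor, reliability=0.9)) for _ in range(2)]
        a, b = (f.to_csv(index=False) for f in frames)
        assert a == b
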