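"""Evaluation-framework tests: matching, metrics, bootstrap, agreement."""

import numpy as np
import pytest

from hstarousal.events import EventList
from hstarousal.evaluation import (
    MatchCriterion,
    arousal_index,
    bland_altman,
    bootstrap_paired_test,
    holm_bonferroni,
    mask_wake,
    match_events,
    pointwise_metrics,
    recordwise_metrics,
    relative_confusion,
)


def _brute_force_match(gt, det, omega):
    """All-pairs oracle for the overlap criterion."""
    gt_found = [False] * len(gt)
    det_hit = [False] * len(det)
    for i, (ga, gb) in enumerate(gt):
        for j, (da, db) in enumerate(det):
            inter = max(0.0, min(gb, db) - max(ga, da))
            if inter / (gb - ga) > omega:
                gt_found[i] = True
                det_hit[j] = True
    return {
        "tp": sum(det_hit),
        "fp": len(det) - sum(det_hit),
        "fn": len(gt) - sum(gt_found),
        "gt_matched": sum(gt_found),
    }


def _random_event_list(rng, n_max=12, span=300.0):
    t, out = 0.0, []
    for _ in range(rng.integers(0, n_max)):
        t += rng.uniform(0.5, 15.0)
        d = rng.uniform(1.0, 12.0)
        if t + d > span:
            break
        out.append((t, t + d))
        t += d
    return EventList(out)


class TestMatchEvents:
    def test_sixty_percent_coverage_matches(self):
        rep = match_events(EventList([(10, 20)]), EventList([(14, 22)]))
        assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0)

    def test_exactly_half_coverage_does_not_match(self):
        """The overlap rate must strictly exceed the minimum."""
        rep = match_events(EventList([(10, 20)]), EventList([(15, 25)]))
        assert (rep.tp, rep.fp, rep.fn) == (0, 1, 1)

    def test_one_detection_credits_multiple_ground_truths(self):
        gt = EventList([(0, 4), (6, 10)])
        det = EventList([(0, 10)])
        rep = match_events(gt, det)
        assert rep.tp == 1 and rep.gt_matched == 2 and rep.fn == 0
        assert rep.recall == pytest.approx(1.0)
        assert rep.precision == pytest.approx(1.0)

    def test_agrees_with_all_pairs_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            gt = _random_event_list(rng)
            det = _random_event_list(rng)
            rep = match_events(gt, det)
            exp = _brute_force_match(list(gt), list(det), 0.5)
            assert (rep.tp, rep.fp, rep.fn, rep.gt_matched) == (
                exp["tp"],
                exp["fp"],
                exp["fn"],
                exp["gt_matched"],
            )

    def test_recall_monotone_in_omega(self):
        rng = np.random.default_rng(13)
        gt = _random_event_list(rng, n_max=15)
        det = _random_event_list(rng, n_max=15)
        recalls = [
            match_events(gt, det, MatchCriterion(omega_min=w)).recall
            for w in (0.9, 0.7, 0.5, 0.3, 0.1)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(recalls, recalls[1:]))

    def test_empty_lists(self):
        rep = match_events(EventList(), EventList([(0, 5)]))
        assert (rep.tp, rep.fp, rep.fn) == (0, 1, 0)
        rep = match_events(EventList([(0, 5)]), EventList())
        assert (rep.tp, rep.fp, rep.fn) == (0, 0, 1)


class TestMaskWake:
    def test_event_wholly_in_sleep_kept(self):
        mask = np.ones(60)
        assert len(mask_wake(EventList([(10, 15)]), mask)) == 1

    def test_event_wholly_in_wake_removed(self):
        mask = np.zeros(60)
        assert len(mask_wake(EventList([(10, 15)]), mask)) == 0

    def test_minority_wake_event_kept(self):
        mask = np.ones(60)
        mask[10:12] = 0  # 2 of 5 covered seconds in wake
        ev = mask_wake(EventList([(10.0, 15.0)]), mask)
        assert list(ev) == [(10.0, 15.0)]

    def test_exactly_half_wake_kept(self):
        mask = np.ones(60)
        mask[10:12] = 0  # 2 of 4 covered seconds
        assert len(mask_wake(EventList([(10.0, 14.0)]), mask)) == 1


class TestPointwise:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        rep = pointwise_metrics(y, y)
        assert (rep.precision, rep.recall, rep.f1) == (1.0, 1.0, 1.0)

    def test_inverted_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        rep = pointwise_metrics(1 - y, y)
        assert (rep.precision, rep.recall, rep.f1) == (0.0, 0.0, 0.0)

    def test_matches_direct_counting(self):
        rng = np.random.default_rng(14)
        y = (rng.random(10**4) < 0.15).astype(int)
        pred = (rng.random(10**4) < 0.2).astype(int)
        rep = pointwise_metrics(pred, y)
        tp = int(np.sum((pred == 1) & (y == 1)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        fn = int(np.sum((pred == 0) & (y == 1)))
        assert rep.precision == pytest.approx(tp / (tp + fp))
        assert rep.recall == pytest.approx(tp / (tp + fn))
        p, r = rep.precision, rep.recall
        assert rep.f1 == pytest.approx(2 * p * r / (p + r))

    def test_wake_seconds_ignored(self):
        y = np.array([1, 1, 0, 0])
        pred = np.array([0, 1, 0, 0])
        mask = np.array([0, 1, 1, 1])  # first second is wake
        rep = pointwise_metrics(pred, y, mask)
        assert rep.recall == pytest.approx(1.0)

    def test_auroc_of_perfect_and_anti_ranker(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        probs = np.array([0.1, 0.2, 0.8, 0.9, 0.15, 0.7])
        rep = pointwise_metrics((probs > 0.5).astype(int), y, probs=probs)
        assert rep.auroc == pytest.approx(1.0)
        rep = pointwise_metrics((probs > 0.5).astype(int), y, probs=1 - probs)
        assert rep.auroc == pytest.approx(0.0)

    def test_no_positive_seconds_flagged(self):
        rep = pointwise_metrics(np.zeros(10), np.zeros(10))
        assert not rep.recall_defined


class TestRecordwise:
    def test_identical_records_zero_sd(self):
        gt = EventList([(0, 5), (20, 25)])
        det = EventList([(0, 5)])
        report = recordwise_metrics([(gt, det)] * 4)
        assert report.sd("f1") == pytest.approx(0.0)

    def test_mean_of_known_f1_pair(self):
        # record A: tp=1, fp=2, fn=1 -> F1 = 2/(2+2+1) = 0.4
        gt_a = EventList([(0, 4), (20, 24)])
        det_a = EventList([(0, 4), (40, 44), (60, 64)])
        # record B: tp=3, fp=2, fn=2 -> F1 = 6/(6+2+2) = 0.6
        gt_b = EventList([(0, 4), (10, 14), (20, 24), (30, 34), (40, 44)])
        det_b = EventList([(0, 4), (10, 14), (20, 24), (60, 64), (70, 74)])
        report = recordwise_metrics([(gt_a, det_a), (gt_b, det_b)])
        assert report.per_record("f1") == pytest.approx([0.4, 0.6])
        assert report.mean("f1") == pytest.approx(0.5)

    def test_mean_and_sd_match_direct_arithmetic(self):
        rng = np.random.default_rng(15)
        pairs = [
            (_random_event_list(rng, n_max=8), _random_event_list(rng, n_max=8))
            for _ in range(20)
        ]
        pairs = [(g, d) for g, d in pairs if len(g)]
        report = recordwise_metrics(pairs)
        f1s = np.array([match_events(g, d).f1 for g, d in pairs])
        assert report.mean("f1") == pytest.approx(f1s.mean())
        assert report.sd("f1") == pytest.approx(f1s.std(ddof=1))

    def test_records_without_ground_truth_excluded(self):
        gt = EventList([(0, 5)])
        det = EventList([(0, 5)])
        report = recordwise_metrics(
            [(gt, det), (EventList(), det)], record_ids=["a", "b"]
        )
        assert report.excluded == ["b"]
        assert report.record_ids == ["a"]


class TestBootstrap:
    def test_identical_vectors_give_p_one(self):
        a = np.array([0.4, 0.5, 0.6, 0.7])
        res = bootstrap_paired_test(a, a.copy(), n_boot=200, seed=1)
        assert res.p_value == 1.0 and res.degenerate

    def test_large_shift_detected(self):
        rng = np.random.default_rng(16)
        b = rng.normal(0.5, 0.05, size=30)
        a = b + 0.5 + rng.normal(0, 0.01, size=30)
        res = bootstrap_paired_test(a, b, n_boot=2000, seed=2)
        assert res.p_value < 0.01

    def test_type_one_error_calibrated(self):
        """Under the null, rejections at alpha=0.05 stay near 5 %."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 1000
        for i in range(n_rep):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            res = bootstrap_paired_test(a, b, n_boot=500, seed=1000 + i)
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_paired_test(np.array([1.0]), np.array([2.0]))


class TestHolm:
    def test_step_down_stops_at_first_failure(self):
        # 0.01 <= 0.05/3; 0.03 > 0.05/2 stops the procedure
        assert holm_bonferroni([0.01, 0.03, 0.04], alpha=0.05) == [True, False, False]

    def test_all_ones_reject_nothing(self):
        assert holm_bonferroni([1.0, 1.0, 1.0]) == [False, False, False]

    def test_single_p_reduces_to_plain_test(self):
        assert holm_bonferroni([0.04], alpha=0.05) == [True]

    def test_empty_family(self):
        assert holm_bonferroni([]) == []


class TestRelativeConfusion:
    def test_identical_detectors_have_empty_off_diagonal(self):
        rng = np.random.default_rng(18)
        gt = [_random_event_list(rng, n_max=10)]
        det = [_random_event_list(rng, n_max=10)]
        cells = relative_confusion(gt, det, det)
        assert cells["only_a"] == 0 and cells["only_b"] == 0

    def test_empty_second_detector(self):
        gt = [EventList([(0, 5), (20, 25), (40, 45)])]
        det_a = [EventList([(0, 5), (20, 25)])]
        det_b = [EventList()]
        cells = relative_confusion(gt, det_a, det_b)
        assert cells == {"both": 0, "only_a": 2, "only_b": 0, "neither": 1}

    def test_cells_sum_to_ground_truth_count(self):
        rng = np.random.default_rng(19)
        gt = [_random_event_list(rng, n_max=10) for _ in range(5)]
        da = [_random_event_list(rng, n_max=10) for _ in range(5)]
        db = [_random_event_list(rng, n_max=10) for _ in range(5)]
        cells = relative_confusion(gt, da, db)
        assert sum(cells.values()) == sum(len(g) for g in gt)


class TestArI:
    def test_forty_events_in_eight_hours(self):
        ev = EventList([(i * 60.0, i * 60.0 + 10.0) for i in range(40)])
        assert arousal_index(ev, 8.0) == pytest.approx(5.0)

    def test_zero_events(self):
        assert arousal_index(EventList(), 6.0) == 0.0

    def test_zero_sleep_time_rejected(self):
        with pytest.raises(ValueError):
            arousal_index(EventList(), 0.0)


class TestBlandAltman:
    def test_identical_indices(self):
        t = np.array([5.0, 10.0, 15.0, 20.0])
        rep = bland_altman(t, t.copy())
        assert rep.mean_bias == 0.0
        assert rep.loa_low == rep.loa_high == 0.0
        assert rep.pearson_r == pytest.approx(1.0)

    def test_constant_shift(self):
        t = np.array([5.0, 10.0, 15.0])
        rep = bland_altman(t, t + 2.0)
        assert rep.mean_bias == pytest.approx(2.0)
        assert rep.loa_low == pytest.approx(2.0)
        assert rep.loa_high == pytest.approx(2.0)

    def test_limits_match_direct_arithmetic(self):
        rng = np.random.default_rng(20)
        t = rng.uniform(5, 40, size=30)
        e = t + rng.normal(0, 3, size=30)
        rep = bland_altman(t, e)
        bias = e - t
        assert rep.mean_bias == pytest.approx(bias.mean())
        assert rep.loa_low == pytest.approx(bias.mean() - 1.96 * bias.std(ddof=1))
        assert rep.loa_high == pytest.approx(bias.mean() + 1.96 * bias.std(ddof=1))

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]), np.array([1.0]))
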