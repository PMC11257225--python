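import numpy as np
import pytest

from bootair import (
    JumpEvent,
    MatchResult,
    ParameterError,
    UndefinedScoreError,
    match_events,
    overdetected_count,
    penalty_adjusted_score,
    penalty_score,
    pooled_scores,
    relative_ratio,
    score_report,
)

from _reference import ref_best_matching


def ev(start_s, flight_ms=600.0, label="detected"):
    return JumpEvent(
        start_s=start_s,
        end_s=start_s + flight_ms / 1000.0,
        flight_ms=flight_ms,
        label=label,
    )


def synthetic_match(n_matched, n_undetected, n_overdetected):
    """Assemble a MatchResult with the requested counts."""
    pairs = tuple((ev(10.0 * i, label="medium"), ev(10.0 * i + 0.05), 50.0) for i in range(n_matched))
    und = tuple(ev(1000.0 + 10.0 * i, label="medium") for i in range(n_undetected))
    over = tuple(ev(2000.0 + 10.0 * i) for i in range(n_overdetected))
    return MatchResult(
        matched_pairs=pairs,
        undetected_truth=und,
        overdetected=over,
        n_truth=n_matched + n_undetected,
    )


class TestMatchEvents:
    def test_boundary_within_tolerance(self):
        m = match_events([ev(1.000)], [ev(1.149)], 150.0)
        assert m.n_matched == 1
        assert m.matched_pairs[0][2] == pytest.approx(149.0)

    def test_outside_tolerance(self):
        m = match_events([ev(1.000)], [ev(1.200)], 150.0)
        assert m.n_matched == 0
        assert len(m.undetected_truth) == 1
        assert len(m.overdetected) == 1

    def test_tie_breaks_to_earlier_detected(self):
        m = match_events([ev(1.00), ev(1.10)], [ev(1.05)], 150.0)
        assert m.n_matched == 1
        _, det, delta = m.matched_pairs[0]
        assert det.start_s == 1.00
        assert delta == pytest.approx(50.0)
        assert m.overdetected[0].start_s == 1.10

    def test_negative_tolerance(self):
        with pytest.raises(ParameterError):
            match_events([], [], -1.0)

    def test_unsorted_input_ok(self):
        m = match_events([ev(20.0), ev(5.0)], [ev(5.01), ev(20.01)], 150.0)
        assert m.n_matched == 2

    def test_one_to_one(self):
        # one detection cannot satisfy two truths
        m = match_events([ev(1.0)], [ev(0.95), ev(1.05)], 150.0)
        assert m.n_matched == 1
        assert len(m.undetected_truth) == 1

    def test_matches_exhaustive_oracle_on_sparse_lists(self, rng):
        # truth events separated by > 2x tolerance: greedy is provably optimal
        for _ in range(200):
            n_truth = int(rng.integers(0, 5))
            truth_starts = np.cumsum(rng.uniform(1.0, 5.0, n_truth)) + 5.0
            n_det = int(rng.integers(0, 5))
            det_starts = []
            for _ in range(n_det):
                if n_truth and rng.random() < 0.7:
                    det_starts.append(float(rng.choice(truth_starts) + rng.normal(0, 0.12)))
                else:
                    det_starts.append(float(rng.uniform(0, 30)))
            m = match_events(
                [ev(s) for s in det_starts], [ev(s) for s in truth_starts], 150.0
            )
            k, total, _ = ref_best_matching(sorted(det_starts), list(truth_starts), 150.0)
            assert m.n_matched == k
            assert sum(p[2] for p in m.matched_pairs) == pytest.approx(total, abs=1e-6)

    def test_conservation(self, rng):
        for _ in range(100):
            dets = [ev(float(s)) for s in rng.uniform(0, 100, rng.integers(0, 10))]
            truths = [ev(float(s)) for s in rng.uniform(0, 100, rng.integers(0, 10))]
            m = match_events(dets, truths, 500.0)
            assert m.n_matched + len(m.undetected_truth) == m.n_truth == len(truths)
            assert m.n_matched + len(m.overdetected) == m.n_detected == len(dets)

    def test_shrinking_tolerance_never_gains_matches(self, rng):
        dets = [ev(float(s)) for s in rng.uniform(0, 50, 8)]
        truths = [ev(float(s)) for s in rng.uniform(0, 50, 8)]
        counts = [
            match_events(dets, truths, tol).n_matched for tol in (2000, 1000, 500, 150, 50, 0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_infinite_tolerance_equal_lengths(self, rng):
        dets = [ev(float(s)) for s in rng.uniform(0, 50, 6)]
        truths = [ev(float(s)) for s in rng.uniform(0, 50, 6)]
        assert match_events(dets, truths, float("inf")).n_matched == 6


class TestScores:
    def test_all_matched(self):
        assert relative_ratio(synthetic_match(15, 0, 0)) == 1.0

    def test_none_matched(self):
        assert relative_ratio(synthetic_match(0, 7, 0)) == 0.0

    def test_eight_of_eighteen(self):
        assert relative_ratio(synthetic_match(8, 10, 0)) == pytest.approx(8 / 18)
        assert round(relative_ratio(synthetic_match(8, 10, 0)) * 100) == 44

    def test_overdetected_count(self):
        assert overdetected_count(synthetic_match(1, 0, 2)) == 2
        assert overdetected_count(synthetic_match(3, 0, 0)) == 0

    def test_penalty(self):
        assert penalty_score(synthetic_match(39, 13, 13)) == pytest.approx(13 / 52)
        assert penalty_score(synthetic_match(0, 52, 52)) == 1.0
        assert penalty_score(synthetic_match(5, 0, 0)) == 0.0

    def test_penalty_adjusted_negative(self):
        # ratio 26/52 = 0.5, penalty 37/52 ~= 0.71 -> -0.21
        m = synthetic_match(26, 26, 37)
        assert penalty_adjusted_score(m) == pytest.approx(0.5 - 37 / 52)
        assert round(penalty_adjusted_score(m), 2) == -0.21

    def test_identity(self, rng):
        for _ in range(100):
            nm, nu, no = (int(x) for x in rng.integers(0, 10, 3))
            if nm + nu == 0:
                continue
            m = synthetic_match(nm, nu, no)
            assert penalty_adjusted_score(m) == pytest.approx(
                relative_ratio(m) - penalty_score(m), abs=1e-15
            )
            assert penalty_adjusted_score(m) == pytest.approx(
                (m.n_matched - len(m.overdetected)) / m.n_truth, abs=1e-12
            )

    def test_empty_truth_raises(self):
        m = synthetic_match(0, 0, 3)
        for fn in (relative_ratio, penalty_score, penalty_adjusted_score):
            with pytest.raises(UndefinedScoreError):
                fn(m)


class TestScoreReport:
    def test_empty_detected(self):
        r = score_report([], [ev(1.0), ev(10.0)], 150.0)
        assert (r.relative_ratio, r.n_overdetected, r.penalty, r.penalty_adjusted) == (
            0.0,
            0,
            0.0,
            0.0,
        )

    def test_perfect_detection(self):
        truth = [ev(1.0), ev(10.0), ev(20.0)]
        r = score_report(list(truth), truth, 150.0)
        assert (r.relative_ratio, r.n_overdetected, r.penalty, r.penalty_adjusted) == (
            1.0,
            0,
            0.0,
            1.0,
        )

    def test_agrees_with_direct_recomputation(self, rng):
        for _ in range(50):
            dets = [ev(float(s)) for s in rng.uniform(0, 100, rng.integers(0, 8))]
            truths = [ev(float(s)) for s in rng.uniform(0, 100, rng.integers(1, 8))]
            r = score_report(dets, truths, 150.0)
            m = match_events(dets, truths, 150.0)
            assert r.relative_ratio == m.n_matched / len(truths)
            assert r.n_overdetected == len(m.overdetected)
            assert r.penalty == len(m.overdetected) / len(truths)
            assert r.penalty_adjusted == r.relative_ratio - r.penalty

    def test_empty_truth_raises(self):
        with pytest.raises(UndefinedScoreError):
            score_report([ev(1.0)], [], 150.0)

    def test_percent_display(self):
        assert score_report([], [ev(1.0)], 150.0).relative_ratio_pct == 0


class TestPooledScores:
    def test_class_filter(self):
        truth = [ev(1.0, label="small"), ev(10.0, label="medium")]
        dets = [ev(1.01), ev(10.01), ev(50.0)]
        m = match_events(dets, truth, 150.0)
        small = pooled_scores([m], truth_labels=["small"])
        assert small.n_truth == 1 and small.n_matched == 1
        assert small.n_overdetected == 1  # overdetections are never class-filtered

    def test_pooling_sums_counts(self):
        truth_a = [ev(1.0, label="medium")]
        truth_b = [ev(1.0, label="medium"), ev(10.0, label="medium")]
        ma = match_events([ev(1.01), ev(30.0)], truth_a, 150.0)
        mb = match_events([ev(10.01)], truth_b, 150.0)
        r = pooled_scores([ma, mb])
        assert r.n_truth == 3
        assert r.n_matched == 2
        assert r.n_overdetected == 1
        assert r.penalty_adjusted == pytest.approx((2 - 1) / 3)

    def test_no_truth_in_class(self):
        m = match_events([], [ev(1.0, label="medium")], 150.0)
        with pytest.raises(UndefinedScoreError):
            pooled_scores([m], truth_labels=["big_air"])
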