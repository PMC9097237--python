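"""Penalized DP segmentation, merging, slope test and steadiness classes."""

import numpy as np
import pytest
from scipy import stats

from efmkit import (
    FlowTrace,
    SegmentationConfig,
    SegmentScorer,
    classify_steadiness,
    dp_segment,
    merge_invalid_segments,
    ols_slope_pvalue,
    segment_score,
    simulate_flow,
    slope_p_value,
    TraceDataError,
)
from conftest import brute_force_segmentation, dp_objective, family_spec


def _trace(flow, interval=3.0):
    flow = np.asarray(flow, float)
    t = np.arange(flow.size) * interval
    return FlowTrace(time_s=t, flow=flow, sampling_interval_s=interval)


class TestSegmentScore:
    def test_zero_on_linear_flow(self):
        trace = _trace(2.0 + 0.01 * np.arange(50))
        assert segment_score(trace, 5, 40) == pytest.approx(0.0, abs=1e-12)

    def test_step_scores_worse_than_either_level(self):
        flow = np.concatenate([np.full(25, 2.0), np.full(25, 8.0)])
        trace = _trace(flow)
        whole = segment_score(trace, 0, 49)
        assert whole < segment_score(trace, 0, 24)
        assert whole < segment_score(trace, 25, 49)

    def test_matches_direct_ols_oracle(self):
        rng = np.random.default_rng(11)
        flow = rng.normal(5.0, 1.0, 60)
        trace = _trace(flow)
        scorer = SegmentScorer(trace.time_s, trace.flow)
        for _ in range(20):
            i = int(rng.integers(0, 45))
            j = i + int(rng.integers(9, 14))
            tt, yy = trace.time_s[i : j + 1], flow[i : j + 1]
            res = stats.linregress(tt, yy)
            rss_direct = float(np.sum((yy - res.intercept - res.slope * tt) ** 2))
            assert scorer.rss(i, j) == pytest.approx(rss_direct, rel=1e-9, abs=1e-12)

    def test_degenerate_x_range_rejected(self):
        scorer = SegmentScorer([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(TraceDataError):
            scorer.score(1, 1)


class TestDpSegment:
    def test_constant_trace_single_segment(self):
        segs = dp_segment(_trace(np.full(80, 5.0)), SegmentationConfig(penalty_P=0.1))
        assert len(segs) == 1
        assert (segs[0].start_idx, segs[0].end_idx) == (0, 79)

    def test_two_plateau_step_found_exactly(self):
        flow = np.concatenate([np.full(50, 2.0), np.full(50, 8.0)])
        trace = _trace(flow)
        segs = dp_segment(trace, SegmentationConfig(penalty_P=0.01))
        assert len(segs) == 2
        assert segs[0].end_idx == 49 and segs[1].start_idx == 50
        # brute force over all single-breakpoint placements agrees
        scorer = SegmentScorer(trace.time_s, flow)
        objs = [
            float(scorer.score(0, b) + scorer.score(b + 1, 99))
            for b in range(2, 97)
        ]
        assert int(np.argmax(objs)) + 2 == 49

    def test_huge_penalty_forces_single_segment(self):
        flow = np.concatenate([np.full(50, 2.0), np.full(50, 8.0)])
        segs = dp_segment(_trace(flow), SegmentationConfig(penalty_P=1e6))
        assert len(segs) == 1

    def test_segments_tile_trace(self):
        tr, _ = simulate_flow(family_spec("A", 3))
        segs = dp_segment(tr, SegmentationConfig())
        assert segs[0].start_idx == 0 and segs[-1].end_idx == tr.n - 1
        for a, b in zip(segs, segs[1:]):
            assert b.start_idx == a.end_idx + 1
        assert all(s.n >= 3 for s in segs)

    def test_matches_exhaustive_enumeration_small_n(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(6, 16))
            flow = rng.normal(0, 1, n) + np.where(np.arange(n) > n // 2, 2.0, 0.0)
            trace = _trace(flow)
            penalty = float(rng.uniform(0.01, 1.0))
            cfg = SegmentationConfig(penalty_P=penalty)
            segs = dp_segment(trace, cfg)
            best, best_nseg = brute_force_segmentation(trace.time_s, flow, penalty)
            got = dp_objective(segs, penalty)
            assert got == pytest.approx(best, rel=1e-9, abs=1e-9)
            assert len(segs) == best_nseg

    def test_segment_count_nonincreasing_in_penalty(self):
        tr, _ = simulate_flow(family_spec("A", 7))
        counts = [
            len(dp_segment(tr, SegmentationConfig(penalty_P=p)))
            for p in [0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_trace_too_short_rejected(self):
        with pytest.raises(TraceDataError):
            dp_segment(_trace([1.0, 2.0]), SegmentationConfig())


class TestMergeInvalidSegments:
    def _segments_for(self, trace, bounds):
        scorer = SegmentScorer(trace.time_s, trace.flow)
        return [scorer.fit(a, b) for a, b in bounds]

    def test_sub_minute_segment_dissolved(self):
        # durations: 1200 s, 39 s, 1080 s  ->  the 1-min rule removes the middle
        flow = np.concatenate(
            [np.full(401, 2.0), np.full(13, 50.0), np.full(361, 2.2)]
        )
        trace = _trace(flow)
        segs = self._segments_for(trace, [(0, 400), (401, 413), (414, 774)])
        merged = merge_invalid_segments(segs, trace, SegmentationConfig())
        assert len(merged) == 2
        assert merged[0].start_idx == 0 and merged[-1].end_idx == 774

    def test_all_segments_long_is_identity(self):
        tr, _ = simulate_flow(family_spec("D", 0))
        segs = dp_segment(tr, SegmentationConfig())
        merged = merge_invalid_segments(segs, tr, SegmentationConfig())
        assert [(s.start_idx, s.end_idx) for s in merged] == [
            (s.start_idx, s.end_idx) for s in segs
        ]

    def test_single_segment_is_identity(self):
        trace = _trace(np.full(30, 1.0))
        segs = self._segments_for(trace, [(0, 29)])
        assert merge_invalid_segments(segs, trace, SegmentationConfig()) == segs

    def test_short_segment_joins_better_fitting_neighbor(self):
        # middle stub continues the left line exactly; must merge left
        flow = np.concatenate([np.full(30, 5.0), np.full(5, 5.0), np.full(30, 9.0)])
        trace = _trace(flow)
        segs = self._segments_for(trace, [(0, 29), (30, 34), (35, 64)])
        merged = merge_invalid_segments(segs, trace, SegmentationConfig())
        assert len(merged) == 2
        assert merged[0].end_idx == 34


class TestSlopePValue:
    def test_strict_linear_rise_is_maximally_significant(self):
        trace = _trace(1.0 + 0.01 * np.arange(100))
        assert slope_p_value(trace, (0, 99)) == 0.0

    def test_flat_window_p_one(self):
        trace = _trace(np.full(50, 3.3))
        assert slope_p_value(trace, (0, 49)) == 1.0

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(2)
        t = np.arange(300) * 3.0
        y = 5.0 + rng.normal(0, 0.1, 300)
        expected = stats.linregress(t, y).pvalue
        assert ols_slope_pvalue(t, y) == pytest.approx(expected, rel=1e-10)

    def test_null_pvalues_uniform(self):
        """Under H0 the p-values are U(0,1): KS check on 500 replicates."""
        rng = np.random.default_rng(123)
        t = np.arange(300) * 3.0
        pvals = [
            ols_slope_pvalue(t, rng.normal(0, 1, 300)) for _ in range(500)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestClassifySteadiness:
    def _classify(self, spec):
        tr, truth = simulate_flow(spec)
        cfg = SegmentationConfig()
        segs = merge_invalid_segments(dp_segment(tr, cfg), tr, cfg)
        return truth, classify_steadiness(segs, tr, cfg)

    def test_plateau_trace_is_steady_class_d(self):
        truth, sd = self._classify(family_spec("D", 1))
        assert truth.curve_class == "D"
        assert sd.curve_class == "D" and sd.steady
        assert sd.last_segment_duration_s >= 900.0
        assert sd.slope_p_value > 0.001
        assert sd.steady_window is not None

    def test_short_final_plateau_is_class_c(self):
        truth, sd = self._classify(family_spec("C", 1))
        assert truth.curve_class == "C"
        assert sd.curve_class == "C" and not sd.steady
        assert sd.last_segment_duration_s < 900.0

    def test_post_peak_decline_is_class_b(self):
        truth, sd = self._classify(family_spec("B", 1))
        assert truth.curve_class == "B"
        assert sd.curve_class == "B" and not sd.steady
        assert sd.slope_p_value <= 0.001

    def test_oscillating_trace_is_class_a(self):
        truth, sd = self._classify(family_spec("A", 1))
        assert truth.curve_class == "A"
        assert sd.curve_class == "A" and not sd.steady

    @pytest.mark.parametrize("scale", [0.01, 0.5, 3.7, 120.0])
    def test_invariant_to_uniform_flow_rescaling(self, scale):
        tr, _ = simulate_flow(family_spec("D", 4))
        cfg = SegmentationConfig()

        def verdict(trace):
            segs = merge_invalid_segments(dp_segment(trace, cfg), trace, cfg)
            return classify_steadiness(segs, trace, cfg)

        base = verdict(tr)
        scaled = verdict(tr.replace(flow=tr.flow * scale))
        assert scaled.curve_class == base.curve_class
        assert scaled.slope_p_value == pytest.approx(base.slope_p_value, rel=1e-9)
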