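"""Penalized piecewise-linear segmentation and steady-state identification.

The flow–time curve is decomposed into contiguous straight-line segments by
dynamic programming.  Each candidate segment [i, j] is scored by minus its
residual variance after an OLS line fit (``score = -rss/n``), and every
break point costs a penalty ``P``; the algorithm maximizes

    sum_k score(segment_k)  -  P * (number of break points)

over all segmentations whose segments contain at least ``min_seg_points``
samples.  A large ``P`` tolerates high within-segment variance and yields
few, long segments; a small ``P`` tracks the curve closely.  Scores are
computed from prefix sums, so each (i, j) evaluation is O(1) after a linear
pass and the whole DP is O(n²).

Steady-state identification then applies three rules to the merged
segmentation:

* the last segment must span at least 15 min (class C otherwise);
* the OLS slope of the trailing 15-min window (about 300 points at 3-s
  sampling) must not differ from zero at the 0.001 level of a two-sided
  t-test (non-steady otherwise);
* non-steady traces that passed the duration rule are split into
  oscillating (class A: the post-peak segment slopes change sign at least
  twice) and monotonically drifting (class B).

Class D — the only steady class — is the sole state from which a steady
flow E may be extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ParameterError, StateError, TraceDataError
from .trace import FlowTrace

__all__ = [
    "SegmentationConfig",
    "Segment",
    "SteadinessResult",
    "SegmentScorer",
    "segment_score",
    "dp_segment",
    "merge_invalid_segments",
    "ols_slope_pvalue",
    "slope_p_value",
    "classify_steadiness",
]

#: relative tolerance used to declare two DP objective values tied
_TIE_RTOL = 1e-9


@dataclass
class SegmentationConfig:
    """Tuning knobs of segmentation and steadiness classification.

    Parameters
    ----------
    penalty_P
        Break-point penalty in score units (flow² ).  ``None`` (default)
        auto-scales the penalty to ``penalty_scale`` times the global flow
        variance, which makes the trade-off dimensionless across traces.
    penalty_scale
        Fraction of global flow variance used when ``penalty_P`` is None.
        The default 0.02 is the largest scale (fewest segments) that still
        resolves rise curvature and stomatal oscillation into separate
        segments at the 15-min steady-window timescale while leaving a
        pure-noise plateau as a single segment.
    min_seg_points
        Minimum samples per segment (≥ 3 so each segment supports a line fit
        with a residual).
    merge_window_s
        Segments shorter than this are deemed invalid (outlier-induced) and
        dissolved into a neighbor; 60 s per the one-minute rule.
    steady_min_duration_s
        Required span of the last segment for a trace to qualify as steady.
    steady_window_s
        Width of the trailing window used for the slope t-test and for the
        steady-flow mean.
    slope_alpha
        Significance level of the slope t-test; the trace is steady only if
        p > slope_alpha.
    """

    penalty_P: float | None = None
    penalty_scale: float = 0.02
    min_seg_points: int = 3
    merge_window_s: float = 60.0
    steady_min_duration_s: float = 900.0
    steady_window_s: float = 900.0
    slope_alpha: float = 0.001

    def __post_init__(self) -> None:
        if self.min_seg_points < 3:
            raise ParameterError("min_seg_points must be >= 3")
        for name in ("merge_window_s", "steady_min_duration_s", "steady_window_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0 < self.slope_alpha < 1:
            raise ParameterError("slope_alpha must be in (0, 1)")
        if self.penalty_P is not None and self.penalty_P < 0:
            raise ParameterError("penalty_P must be >= 0")

    def resolve_penalty(self, flow: np.ndarray) -> float:
        """Numeric penalty for a given flow series (auto-scaled if unset)."""
        if self.penalty_P is not None:
            return float(self.penalty_P)
        return float(self.penalty_scale * np.var(flow))


@dataclass
class Segment:
    """One straight-line piece of the segmentation (indices inclusive)."""

    start_idx: int
    end_idx: int
    slope: float
    intercept: float
    rss: float
    n: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.end_idx - self.start_idx + 1 != self.n:
            raise ParameterError("segment index range inconsistent with n")
        if self.rss < 0:
            raise ParameterError("rss must be >= 0")

    def fitted(self, time_s: np.ndarray) -> np.ndarray:
        """Fitted line evaluated on the segment's own time stamps."""
        t = time_s[self.start_idx : self.end_idx + 1]
        return self.intercept + self.slope * t


@dataclass
class SteadinessResult:
    """Verdict of the steady-state rules for one trace.

    ``curve_class`` follows the four-way taxonomy: A oscillating, B
    monotonically drifting, C last segment too short, D steady.  ``steady``
    is True iff the class is D.  ``steady_window`` is the inclusive index
    range used for E extraction (class D only).
    """

    steady: bool
    curve_class: str
    last_segment_duration_s: float
    slope_p_value: float
    steady_window: tuple[int, int] | None = None
    segments: list[Segment] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.steady != (self.curve_class == "D"):
            raise ParameterError("steady flag must equal (curve_class == 'D')")


class SegmentScorer:
    """Constant-time OLS scores on arbitrary index ranges via prefix sums.

    Time and flow are centered once to keep the normal equations well
    conditioned even for long traces with large timestamps.
    """

    def __init__(self, time_s: np.ndarray, flow: np.ndarray):
        t = np.asarray(time_s, dtype=float)
        y = np.asarray(flow, dtype=float)
        if t.size != y.size or t.size < 2:
            raise TraceDataError("time and flow must be equal length >= 2")
        if not np.all(np.diff(t) > 0):
            raise TraceDataError("time must be strictly increasing")
        self._t0 = float(t.mean())
        self._y0 = float(y.mean())
        tc = t - self._t0
        yc = y - self._y0
        z = np.zeros(1)
        self._ct = np.concatenate((z, np.cumsum(tc)))
        self._ct2 = np.concatenate((z, np.cumsum(tc * tc)))
        self._cy = np.concatenate((z, np.cumsum(yc)))
        self._cy2 = np.concatenate((z, np.cumsum(yc * yc)))
        self._cty = np.concatenate((z, np.cumsum(tc * yc)))
        self._time = t

    def _moments(self, i, j):
        """Centered sums over inclusive ranges [i, j] (vectorized)."""
        i = np.asarray(i)
        j = np.asarray(j)
        n = (j - i + 1).astype(float)
        st = self._ct[j + 1] - self._ct[i]
        st2 = self._ct2[j + 1] - self._ct2[i]
        sy = self._cy[j + 1] - self._cy[i]
        sy2 = self._cy2[j + 1] - self._cy2[i]
        sty = self._cty[j + 1] - self._cty[i]
        sxx = st2 - st * st / n
        sxy = sty - st * sy / n
        syy = sy2 - sy * sy / n
        return n, st, sy, sxx, sxy, syy

    def rss(self, i, j):
        """Residual sum of squares of the OLS line over [i, j] (vectorized)."""
        n, _, _, sxx, sxy, syy = self._moments(i, j)
        if np.any(sxx <= 0):
            raise TraceDataError("degenerate x-range in segment")
        return np.maximum(syy - sxy * sxy / sxx, 0.0)

    def score(self, i, j):
        """Segment score ``-rss/n`` (negative residual variance)."""
        n = np.asarray(j) - np.asarray(i) + 1
        return -self.rss(i, j) / n

    def fit(self, i: int, j: int) -> Segment:
        """Full OLS fit of [i, j] as a :class:`Segment`."""
        n, st, sy, sxx, sxy, syy = self._moments(i, j)
        if sxx <= 0:
            raise TraceDataError("degenerate x-range in segment")
        slope = float(sxy / sxx)
        # back to uncentered coordinates
        mean_t = st / n + self._t0
        mean_y = sy / n + self._y0
        intercept = float(mean_y - slope * mean_t)
        rss = float(max(syy - sxy * sxy / sxx, 0.0))
        return Segment(
            start_idx=int(i),
            end_idx=int(j),
            slope=slope,
            intercept=intercept,
            rss=rss,
            n=int(n),
            duration_s=float(self._time[j] - self._time[i]),
        )


def segment_score(trace: FlowTrace, i: int, j: int) -> float:
    """Score (−residual variance) of fitting one line to flow over [i, j]."""
    if trace.flow is None:
        raise StateError("segment_score requires a flow series")
    if j - i + 1 < 3:
        raise ParameterError("segment must contain at least 3 points")
    return float(SegmentScorer(trace.time_s, trace.flow).score(i, j))


def dp_segment(trace: FlowTrace, config: SegmentationConfig | None = None) -> list[Segment]:
    """Optimal penalized piecewise-linear segmentation of the flow series.

    Maximizes ``sum(-rss_k/n_k) - P * breakpoints`` by dynamic programming
    over all segmentations with segments of at least ``min_seg_points``
    samples.  Segments tile the trace with no gaps or overlaps.  Objective
    ties are broken toward fewer segments, then toward a longer final
    segment, so the output is deterministic.
    """
    config = config or SegmentationConfig()
    if trace.flow is None:
        raise StateError("dp_segment requires a flow series")
    y = trace.flow
    t = trace.time_s
    n = t.size
    m = config.min_seg_points
    if n < m:
        raise TraceDataError(f"trace has {n} points; need >= {m}")
    penalty = config.resolve_penalty(y)
    scorer = SegmentScorer(t, y)

    neg_inf = -np.inf
    # best[i]: optimal objective for prefix ending at index i (inclusive)
    best = np.full(n, neg_inf)
    nseg = np.zeros(n, dtype=int)
    back = np.full(n, -2, dtype=int)  # predecessor end index; -1 = segment starts at 0

    for i in range(m - 1, n):
        # candidate predecessors: j = -1 (single first segment) and every
        # j >= m-1 leaving at least m points for the new segment (j+1..i)
        js = [-1]
        hi = i - m  # largest admissible j
        if hi >= m - 1:
            js.extend(range(m - 1, hi + 1))
        js = np.asarray(js, dtype=int)
        starts = js + 1
        sc = scorer.score(starts, i)
        prev = np.where(js < 0, 0.0, best[np.maximum(js, 0)])
        pen = np.where(js < 0, 0.0, penalty)
        totals = prev + sc - pen
        top = totals.max()
        if top == neg_inf:
            continue
        tol = _TIE_RTOL * (1.0 + abs(top))
        tied = np.flatnonzero(totals >= top - tol)
        cand_nseg = np.where(js[tied] < 0, 1, nseg[np.maximum(js[tied], 0)] + 1)
        min_nseg = cand_nseg.min()
        tied = tied[cand_nseg == min_nseg]
        choice = tied[np.argmin(js[tied])]  # earliest break => longest last segment
        best[i] = totals[choice]
        nseg[i] = 1 if js[choice] < 0 else nseg[js[choice]] + 1
        back[i] = js[choice]

    if not np.isfinite(best[n - 1]):
        raise TraceDataError("no admissible segmentation (trace too short)")

    bounds: list[tuple[int, int]] = []
    i = n - 1
    while i >= 0:
        j = int(back[i])
        bounds.append((j + 1, i))
        i = j
    bounds.reverse()
    return [scorer.fit(a, b) for a, b in bounds]


def merge_invalid_segments(
    segments: list[Segment],
    trace: FlowTrace,
    config: SegmentationConfig | None = None,
) -> list[Segment]:
    """Dissolve sub-minute segments into their better-fitting neighbor.

    Short segments separated by a few outliers are measurement artifacts,
    not flow-regime changes.  Each segment shorter than ``merge_window_s``
    is merged (shortest first) into whichever neighbor yields the smaller
    combined residual variance; merged segments are refitted.  Iterates
    until no sub-minute segment remains or only one segment is left.
    """
    config = config or SegmentationConfig()
    if trace.flow is None:
        raise StateError("merge_invalid_segments requires a flow series")
    segs = list(segments)
    scorer = SegmentScorer(trace.time_s, trace.flow)
    while len(segs) > 1:
        durations = [s.duration_s for s in segs]
        short = [k for k, d in enumerate(durations) if d < config.merge_window_s]
        if not short:
            break
        k = min(short, key=lambda idx: (durations[idx], idx))
        options = []
        if k > 0:
            merged = scorer.fit(segs[k - 1].start_idx, segs[k].end_idx)
            options.append((merged.rss / merged.n, k - 1, merged))
        if k < len(segs) - 1:
            merged = scorer.fit(segs[k].start_idx, segs[k + 1].end_idx)
            options.append((merged.rss / merged.n, k, merged))
        _, left, merged = min(options, key=lambda o: (o[0], o[1]))
        segs[left : left + 2] = [merged]
    return segs


def ols_slope_pvalue(time_s: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p-value of H0: slope = 0 for an OLS line fit.

    Uses the t statistic with n − 2 degrees of freedom.  Degenerate inputs
    follow the conventions: zero residual variance with a nonzero slope
    gives p = 0 (a perfect trend is maximally significant); zero slope with
    zero variance gives p = 1 (a perfectly flat window is maximally steady).
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(y, dtype=float)
    n = t.size
    if n < 3:
        raise ParameterError("slope test needs at least 3 points")
    tc = t - t.mean()
    yc = y - y.mean()
    sxx = float(tc @ tc)
    if sxx <= 0:
        raise TraceDataError("degenerate time values in slope window")
    sxy = float(tc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    rss = max(syy - sxy * sxy / sxx, 0.0)
    dof = n - 2
    scale = max(abs(syy), slope * slope * sxx, 1.0)
    if rss <= 1e-14 * scale:  # numerically perfect fit
        return 0.0 if abs(slope) * np.sqrt(sxx) > np.sqrt(1e-14 * scale) else 1.0
    se = np.sqrt(rss / dof / sxx)
    tstat = slope / se
    return float(2.0 * stats.t.sf(abs(tstat), dof))


def slope_p_value(trace: FlowTrace, window: tuple[int, int]) -> float:
    """Slope t-test p-value of flow vs time over an inclusive index window."""
    if trace.flow is None:
        raise StateError("slope_p_value requires a flow series")
    a, b = window
    return ols_slope_pvalue(trace.time_s[a : b + 1], trace.flow[a : b + 1])


def _steady_slope_pvalue(trace: FlowTrace, window: tuple[int, int]) -> float:
    """Slope t-test over the trailing window, honoring smoothing provenance.

    Flow derived from weight by a sliding OLS window is strongly serially
    correlated within one window width, which would make the standard
    t-test (independent residuals) wildly overpowered — it flags trends
    orders of magnitude below the noise floor.  For such traces the window
    is thinned to one sample per smoothing width before testing, which
    restores approximate independence while preserving the window span.
    Directly measured or simulated flow is tested on all samples.
    """
    a, b = window
    if trace.smoothing_window_s is None:
        return slope_p_value(trace, (a, b))
    dt = float(np.median(np.diff(trace.time_s[a : b + 1])))
    step = max(int(np.ceil(trace.smoothing_window_s / dt)), 1)
    idx = np.arange(a, b + 1, step)
    if idx.size < 3:
        idx = np.linspace(a, b, 3).astype(int)
    return ols_slope_pvalue(trace.time_s[idx], trace.flow[idx])


def _post_peak_sign_changes(segments: list[Segment], trace: FlowTrace) -> int:
    """Sign changes of segment slopes after the first crest of the fitted
    trajectory (oscillation detector for A/B disambiguation).

    The anchor is the first positive→negative slope transition of the
    fitted segments.  Anchoring at the first crest rather than the global
    flow maximum matters: a trace that rises and then oscillates has its
    global maximum at the *last* crest (the rise factor keeps growing), so
    a global-max anchor would leave at most one post-peak segment and could
    never register oscillation.  When no crest exists the anchor falls back
    to the segment holding the global fitted maximum.
    """
    slopes = [s.slope for s in segments]
    peak_seg = None
    for k in range(1, len(segments)):
        if slopes[k] < 0 and slopes[k - 1] > 0:
            peak_seg = k
            break
    if peak_seg is None:
        peak_val = -np.inf
        peak_seg = 0
        for k, seg in enumerate(segments):
            m = float(seg.fitted(trace.time_s).max())
            if m > peak_val:
                peak_val = m
                peak_seg = k
    signs = [np.sign(s) for s in slopes[peak_seg:] if s != 0]
    return int(sum(1 for a, b in zip(signs, signs[1:]) if a != b))


def classify_steadiness(
    segments: list[Segment],
    trace: FlowTrace,
    config: SegmentationConfig | None = None,
) -> SteadinessResult:
    """Apply the steady-state rules to a merged segmentation.

    Rules, in order: (1) last segment shorter than ``steady_min_duration_s``
    → class C; (2) slope t-test on the trailing ``steady_window_s`` window —
    p > ``slope_alpha`` → class D (steady); (3) otherwise class A when the
    post-peak segment slopes change sign at least twice (oscillation),
    class B when the post-peak trajectory drifts monotonically.

    Classification is invariant to uniform rescaling of the flow: neither
    the t statistic nor (with the auto-scaled penalty) the segmentation
    changes when flow is multiplied by a positive constant.
    """
    config = config or SegmentationConfig()
    if not segments:
        raise ParameterError("segments must be non-empty")
    last = segments[-1]
    window = trace.trailing_window(config.steady_window_s)
    p = _steady_slope_pvalue(trace, window)
    if last.duration_s < config.steady_min_duration_s:
        return SteadinessResult(
            steady=False,
            curve_class="C",
            last_segment_duration_s=last.duration_s,
            slope_p_value=p,
            segments=segments,
        )
    if p > config.slope_alpha:
        return SteadinessResult(
            steady=True,
            curve_class="D",
            last_segment_duration_s=last.duration_s,
            slope_p_value=p,
            steady_window=window,
            segments=segments,
        )
    cls = "A" if _post_peak_sign_changes(segments, trace) >= 2 else "B"
    return SteadinessResult(
        steady=False,
        curve_class=cls,
        last_segment_duration_s=last.duration_s,
        slope_p_value=p,
        segments=segments,
    )
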