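"""Simulate the four typical flow-curve families and classify each one.

Steady-state identification is the heart of the toolkit: a leaf only gets a
K_leaf if its flow trace ends in a >= 15-min segment whose trailing 15-min
slope is statistically indistinguishable from zero (t-test, p > 0.001).
This script generates one trace per family — steady plateau (D), post-peak
decline (B), stomatal oscillation (A), plateau reached too late (C) — and
shows that the segmentation pipeline recovers each label.
"""

from efmkit import (
    SegmentationConfig,
    TraceSpec,
    classify_steadiness,
    dp_segment,
    merge_invalid_segments,
    simulate_flow,
)

FAMILIES = {
    "steady plateau": TraceSpec(seed=1),
    "post-peak decline": TraceSpec(decline_rate=6e-5, seed=1),
    "stomatal oscillation": TraceSpec(
        duration_s=3450.0, osc_amplitude=0.08, osc_period_s=2000.0, seed=1
    ),
    "late plateau": TraceSpec(duration_s=1150.0, seed=1),
}

cfg = SegmentationConfig()
print(f"{'condition':<22} {'truth':>5} {'called':>6} {'segments':>8} "
      f"{'last seg (min)':>14} {'slope p':>9}")
for name, spec in FAMILIES.items():
    trace, truth = simulate_flow(spec)
    segments = merge_invalid_segments(dp_segment(trace, cfg), trace, cfg)
    verdict = classify_steadiness(segments, trace, cfg)
    print(
        f"{name:<22} {truth.curve_class:>5} {verdict.curve_class:>6} "
        f"{len(segments):>8} {verdict.last_segment_duration_s / 60:>14.1f} "
        f"{verdict.slope_p_value:>9.2g}"
    )

print(
    "\nOnly class D is steady: its last segment exceeds 15 min and the "
    "trailing-window slope test finds no trend (p > 0.001).\n"
    "Classes A-C never yield a K_leaf."
)
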