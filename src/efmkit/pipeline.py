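"""End-to-end processing of one leaf: balance log → report row.

Chains the stages in their canonical order — slope-window flow derivation,
blank-evaporation correction, area normalization, penalized segmentation,
sub-minute-segment merging, steadiness classification, and (for steady
traces only) steady-flow extraction and K_leaf computation with 25 °C
viscosity standardization.  Non-steady leaves still produce a report row,
carrying their curve class and diagnostics but no conductance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .exceptions import ValidationError
from .flow import EvaporationSetting, area_normalize, correct_evaporation, weight_to_flow
from .kleaf import KleafResult, compute_kleaf, extract_E
from .records import LeafRecord, ReportRecord
from .segmentation import (
    Segment,
    SegmentationConfig,
    SteadinessResult,
    classify_steadiness,
    dp_segment,
    merge_invalid_segments,
)
from .trace import FLOW_PER_AREA, FLOW_PER_LEAF, FlowTrace

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "process_trace"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one leaf."""

    record: ReportRecord
    trace: FlowTrace  # area-normalized flow trace actually classified
    segments: list[Segment] = field(repr=False, default_factory=list)
    steadiness: SteadinessResult | None = None
    kleaf: KleafResult | None = None


def process_trace(
    trace: FlowTrace,
    leaf: LeafRecord,
    leaf_id: str = "leaf",
    seg_config: SegmentationConfig | None = None,
    evaporation: EvaporationSetting | None = None,
    flow_window_s: float = 60.0,
    flow_trace_uri: str | None = None,
) -> PipelineResult:
    """Run the full EFM chain on one trace and return its report record.

    ``trace`` may carry a raw weight series (the flow stages run first) or
    an already area-normalized flow series (they are skipped).  K_leaf is
    computed only for class-D traces and requires ``leaf.psi_final_MPa``;
    ``leaf.T_leaf_C`` defaults to 25 °C (no viscosity correction) when
    absent.
    """
    cfg = seg_config or SegmentationConfig()
    evap = evaporation or EvaporationSetting()

    if trace.flow is None:
        trace = weight_to_flow(trace, window_s=flow_window_s)
    if trace.flow_units == FLOW_PER_LEAF:
        trace = correct_evaporation(trace, evap)
        trace = area_normalize(trace, leaf.leaf_area_m2)
    if trace.flow_units != FLOW_PER_AREA:
        raise ValidationError(f"unrecognized flow units {trace.flow_units!r}")

    segments = merge_invalid_segments(dp_segment(trace, cfg), trace, cfg)
    steadiness = classify_steadiness(segments, trace, cfg)
    log.info(
        "%s: class %s (last segment %.0f s, slope p = %.3g)",
        leaf_id,
        steadiness.curve_class,
        steadiness.last_segment_duration_s,
        steadiness.slope_p_value,
    )

    kres: KleafResult | None = None
    if steadiness.steady:
        E = extract_E(trace, steadiness)
        if leaf.psi_final_MPa is None:
            raise ValidationError(
                f"{leaf_id}: psi_final_MPa is required to compute K_leaf"
            )
        T_leaf = leaf.T_leaf_C if leaf.T_leaf_C is not None else 25.0
        kres = compute_kleaf(
            E, leaf.psi_final_MPa, T_leaf, steady_window=steadiness.steady_window
        )

    record = ReportRecord(
        leaf_id=leaf_id,
        leaf=leaf,
        curve_class=steadiness.curve_class,
        last_segment_duration_s=steadiness.last_segment_duration_s,
        slope_p_value=steadiness.slope_p_value,
        E_mmol_m2_s=kres.E_mmol_m2_s if kres else None,
        K_leaf_raw=kres.K_raw if kres else None,
        K_leaf_25C=kres.K_25 if kres else None,
        viscosity_factor=kres.viscosity_factor if kres else None,
        flow_trace_uri=flow_trace_uri,
    )
    record.validate()
    return PipelineResult(
        record=record,
        trace=trace,
        segments=segments,
        steadiness=steadiness,
        kleaf=kres,
    )
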