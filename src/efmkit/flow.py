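"""Weight-series → flow conversion, evaporation correction, area normalization.

The balance logs cumulative cylinder weight; the transpirational flow into
the leaf is minus the local slope of weight vs. time divided by the molar
mass of water.  The slope is estimated by ordinary least squares over a
centered sliding window (default 60 s), which suppresses the ±0.01 mg
balance jitter at 3-s sampling while leaving the 15-minute-scale structure
used by steady-state detection untouched.  Windows are truncated, not
dropped, at the trace edges so the flow series keeps the full trace length.

The blank-evaporation correction is applied to per-leaf flow (mmol s⁻¹)
because background evaporation is a property of the cylinder, not the leaf;
area normalization comes after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import ParameterError, StateError, TraceDataError
from .trace import (
    FLOW_PER_AREA,
    FLOW_PER_LEAF,
    WATER_MOLAR_MASS_G_MMOL,
    FlowTrace,
)

log = logging.getLogger(__name__)


class EvaporationPrevention(str, Enum):
    """Physical measures against cylinder evaporation during weighing."""

    NONE = "none"
    WAX = "wax"
    HUMID_CHAMBER = "humid_chamber"
    WAX_PLUS_HUMID = "wax_plus_humid"


@dataclass
class EvaporationSetting:
    """Background cylinder-evaporation handling.

    ``blank_rate_mmol_s`` is the water loss rate of the cylinder with no
    leaf attached.  An uncovered cylinder loses about 0.115 × 10⁻³ mmol s⁻¹;
    wax cover plus a humidified weighing chamber suppresses the loss almost
    entirely, which is why the default numeric correction is zero.
    """

    blank_rate_mmol_s: float = 0.0
    prevention: EvaporationPrevention = EvaporationPrevention.WAX_PLUS_HUMID

    def __post_init__(self) -> None:
        if self.blank_rate_mmol_s < 0:
            raise ParameterError("blank_rate_mmol_s must be >= 0")


def weight_to_flow(
    trace: FlowTrace,
    window_s: float = 60.0,
    molar_mass_g_mmol: float = WATER_MOLAR_MASS_G_MMOL,
) -> FlowTrace:
    """Derive per-leaf molar flow from the weight series.

    At each sample the flow in mmol s⁻¹ is minus the OLS slope (g s⁻¹) of
    weight vs. time over the window centered on that sample, divided by the
    molar mass of water.  Exact on any affine weight series.

    Parameters
    ----------
    trace
        Trace with ``weight_g`` present and strictly increasing time.
    window_s
        Full width of the centered slope window; must cover at least two
        nominal sampling intervals.
    molar_mass_g_mmol
        Molar mass of water, g mmol⁻¹.

    Returns
    -------
    FlowTrace
        Copy of ``trace`` with ``flow`` populated in mmol s⁻¹
        (``flow_units`` = ``"mmol s-1"``).
    """
    if trace.weight_g is None:
        raise StateError("weight_to_flow requires a weight_g series")
    if window_s < 2 * trace.sampling_interval_s:
        raise ParameterError(
            f"window_s={window_s} shorter than 2 sampling intervals "
            f"({2 * trace.sampling_interval_s} s)"
        )
    t = trace.time_s
    w = trace.weight_g
    n = t.size
    half = window_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")  # exclusive
    # guarantee >= 2 points even at pathological spacing
    lo = np.minimum(lo, np.arange(n))
    hi = np.maximum(hi, np.arange(n) + 1)
    one_point = (hi - lo) < 2
    lo[one_point] = np.maximum(lo[one_point] - 1, 0)
    hi[one_point] = np.minimum(hi[one_point] + 1, n)

    # centered prefix sums keep the normal equations well conditioned
    t0 = t - t.mean()
    w0 = w - w.mean()
    ct = np.concatenate(([0.0], np.cumsum(t0)))
    ct2 = np.concatenate(([0.0], np.cumsum(t0 * t0)))
    cw = np.concatenate(([0.0], np.cumsum(w0)))
    ctw = np.concatenate(([0.0], np.cumsum(t0 * w0)))

    m = (hi - lo).astype(float)
    st = ct[hi] - ct[lo]
    st2 = ct2[hi] - ct2[lo]
    sw = cw[hi] - cw[lo]
    stw = ctw[hi] - ctw[lo]
    sxx = st2 - st * st / m
    sxy = stw - st * sw / m
    if np.any(sxx <= 0):
        raise TraceDataError("degenerate time values inside a slope window")
    slope_g_s = sxy / sxx
    flow = -slope_g_s / molar_mass_g_mmol
    return trace.replace(
        flow=flow, flow_units=FLOW_PER_LEAF, smoothing_window_s=float(window_s)
    )


def correct_evaporation(trace: FlowTrace, setting: EvaporationSetting) -> FlowTrace:
    """Subtract the blank cylinder-evaporation rate from per-leaf flow.

    Negative corrected values are retained (not clipped) and flagged via
    ``negative_flow_flagged`` so downstream reports can surface them.
    """
    if trace.flow is None:
        raise StateError("correct_evaporation requires a flow series")
    if trace.flow_units != FLOW_PER_LEAF:
        raise StateError(
            "evaporation correction applies to per-leaf flow (mmol s-1), "
            f"got units {trace.flow_units!r}"
        )
    flow = trace.flow - setting.blank_rate_mmol_s
    flagged = bool(np.any(flow < 0))
    if flagged:
        log.warning(
            "evaporation correction produced %d negative flow samples",
            int(np.sum(flow < 0)),
        )
    return trace.replace(flow=flow, negative_flow_flagged=flagged)


def area_normalize(trace: FlowTrace, leaf_area_m2: float) -> FlowTrace:
    """Convert per-leaf flow (mmol s⁻¹) to flow per unit leaf area (mmol m⁻² s⁻¹)."""
    if trace.flow is None:
        raise StateError("area_normalize requires a flow series")
    if trace.flow_units != FLOW_PER_LEAF:
        raise StateError(
            f"flow already normalized or in unknown units {trace.flow_units!r}"
        )
    if leaf_area_m2 <= 0:
        raise ParameterError("leaf_area_m2 must be > 0")
    return trace.replace(flow=trace.flow / leaf_area_m2, flow_units=FLOW_PER_AREA)
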