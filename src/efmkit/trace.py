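"""Core time-series container for balance-log measurements.

A :class:`FlowTrace` holds the raw cylinder weight series and/or the derived
water-flow series on a shared time axis.  Flow passes through two unit
stages: per-leaf molar flow (mmol s⁻¹) straight from the balance slope, and
area-normalized flow (mmol m⁻² s⁻¹) after division by leaf area.  The
``flow_units`` tag records which stage the ``flow`` array is in so that the
processing operations can refuse to run out of order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import TraceDataError

#: flow straight from the balance slope, not yet divided by leaf area
FLOW_PER_LEAF = "mmol s-1"
#: area-normalized transpirational flow
FLOW_PER_AREA = "mmol m-2 s-1"

#: molar mass of water, g mmol⁻¹
WATER_MOLAR_MASS_G_MMOL = 0.018015


@dataclass
class FlowTrace:
    """Timestamped cylinder-weight and/or flow series.

    Parameters
    ----------
    time_s
        Seconds since recording start; strictly increasing, length ≥ 2.
    weight_g
        Cylinder water weight in grams.  Optional when ``flow`` is supplied
        directly (e.g. when re-reading an exported raw-flow table).
    flow
        Water flow series in the units named by ``flow_units``.
    flow_units
        Either :data:`FLOW_PER_LEAF` or :data:`FLOW_PER_AREA`.
    sampling_interval_s
        Nominal balance logging interval (3 s for the reference setup).
    negative_flow_flagged
        Set when an evaporation correction drove some samples negative;
        the values themselves are retained.
    smoothing_window_s
        Width of the sliding OLS window used to derive ``flow`` from
        ``weight_g``, when that is how the flow was obtained.  Within one
        window width, consecutive flow samples share raw data and are
        therefore strongly correlated; statistics that assume independent
        samples (the steadiness slope t-test) consult this to thin the
        series.  ``None`` for directly measured/simulated flow.
    """

    time_s: np.ndarray
    weight_g: np.ndarray | None = None
    flow: np.ndarray | None = None
    flow_units: str = FLOW_PER_AREA
    sampling_interval_s: float = 3.0
    negative_flow_flagged: bool = field(default=False, compare=False)
    smoothing_window_s: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.size < 2:
            raise TraceDataError("time_s must be 1-D with at least 2 samples")
        if not np.all(np.diff(self.time_s) > 0):
            raise TraceDataError("time_s must be strictly increasing")
        for name in ("weight_g", "flow"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.time_s.shape:
                    raise TraceDataError(
                        f"{name} length {arr.size} != time_s length {self.time_s.size}"
                    )
                setattr(self, name, arr)
        if self.weight_g is None and self.flow is None:
            raise TraceDataError("trace needs a weight_g or flow series")
        if self.sampling_interval_s <= 0:
            raise TraceDataError("sampling_interval_s must be positive")

    @property
    def n(self) -> int:
        """Number of samples."""
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        """Span of the time axis in seconds."""
        return float(self.time_s[-1] - self.time_s[0])

    def replace(self, **changes) -> "FlowTrace":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def trailing_window(self, window_s: float) -> tuple[int, int]:
        """Inclusive index range of the trailing ``window_s`` seconds.

        The window is the set of samples with ``t > t_end - window_s``
        (half-open on the left), so a 15-min window of a 3-s-sampled trace
        contains exactly 300 points.
        """
        if window_s <= 0:
            raise TraceDataError("window_s must be positive")
        cutoff = self.time_s[-1] - window_s
        start = int(np.searchsorted(self.time_s, cutoff, side="right"))
        start = min(start, self.n - 1)
        return start, self.n - 1
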