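"""Synthetic balance-log generator with analytic ground truth.

Real EFM traces fall into four phenomenological families: a rise to a
stable plateau (steady), quasi-periodic stomatal oscillation, a decline
after a short-lived peak (often attributed to disturbed ionic homeostasis
when leaves take up deionized water), and runs that end before the plateau
has lasted long enough.  The generator reproduces these shapes from a small
parametric model so the segmentation, classification and K_leaf-recovery
machinery can be exercised — and its error quantified — without a balance.

The mean flow curve is

    flow(t) = E_plateau · (1 − exp(−t/τ_rise))
                        · (1 + a · sin(2πt/P_osc))
                        · exp(−r_decline · max(0, t − 3τ_rise))

with additive Gaussian noise (optionally AR(1)-correlated, since balance
readings in practice are serially correlated).  The true curve class is
derived from the parameters alone, independently of any detector:

* ``B`` when ``decline_rate > 0`` (the trajectory drifts down after its peak);
* ``A`` when the oscillation amplitude ``a·E_plateau`` is detectable, i.e.
  at least 3× the noise standard deviation;
* ``D`` when the plateau (99 % of E_plateau) is reached with at least one
  steady window (15 min) of recording to spare;
* ``C`` otherwise (the plateau arrives too late to satisfy the duration rule).

``flow_to_weight`` inverts the flow derivation: it integrates area-scaled
flow plus background evaporation into a cumulative weight series, producing
a balance log that the full pipeline can consume end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import ParameterError
from .trace import (
    FLOW_PER_AREA,
    WATER_MOLAR_MASS_G_MMOL,
    FlowTrace,
)

__all__ = ["TraceSpec", "TraceTruth", "simulate_flow", "flow_to_weight", "simulate_blank"]

#: oscillation counts as detectable when its amplitude (in flow units)
#: exceeds this many noise standard deviations
OSC_DETECTABILITY_SD = 3.0


@dataclass
class TraceSpec:
    """Parameters of one simulated measurement.

    Defaults emulate a rice leaf under 1000 µmol m⁻² s⁻¹ PAR: plateau flow
    8.75 mmol m⁻² s⁻¹, a ~2-min rise time constant, 30 min of recording at
    3-s sampling, noise of about 1 % of the plateau, and a 25 cm² leaf.
    """

    duration_s: float = 1800.0
    interval_s: float = 3.0
    E_plateau: float = 8.75
    rise_tau_s: float = 120.0
    osc_amplitude: float = 0.0  # fraction of plateau
    osc_period_s: float = 1800.0
    decline_rate: float = 0.0  # fractional decay per second after the peak
    noise_sd: float = 0.1  # flow units (mmol m-2 s-1)
    ar1: float = 0.0  # lag-1 autocorrelation of the noise
    blank_evap_mmol_s: float = 0.0
    leaf_area_m2: float = 2.5e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ParameterError("interval_s must be > 0")
        if self.duration_s < 2 * self.interval_s:
            raise ParameterError("duration_s must cover at least 2 intervals")
        for name in ("osc_amplitude", "noise_sd", "decline_rate", "blank_evap_mmol_s"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not -1.0 < self.ar1 < 1.0:
            raise ParameterError("ar1 must be in (-1, 1)")
        if self.leaf_area_m2 <= 0:
            raise ParameterError("leaf_area_m2 must be > 0")

    # -- analytic pieces -------------------------------------------------
    def time_axis(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + 0.5 * self.interval_s, self.interval_s)

    def mean_curve(self, t: np.ndarray) -> np.ndarray:
        """Noise-free flow curve, mmol m⁻² s⁻¹."""
        t = np.asarray(t, dtype=float)
        rise = 1.0 - np.exp(-t / self.rise_tau_s) if self.rise_tau_s > 0 else np.ones_like(t)
        osc = 1.0 + self.osc_amplitude * np.sin(2.0 * np.pi * t / self.osc_period_s)
        t_peak = 3.0 * self.rise_tau_s
        decay = np.exp(-self.decline_rate * np.clip(t - t_peak, 0.0, None))
        return self.E_plateau * rise * osc * decay

    def plateau_reached_s(self) -> float:
        """Time at which the rise term passes 99 % of the plateau."""
        if self.rise_tau_s <= 0:
            return 0.0
        return self.rise_tau_s * np.log(100.0)

    def true_class(self, steady_window_s: float = 900.0) -> str:
        """Curve class implied by the parameters (independent of any detector)."""
        if self.decline_rate > 0:
            return "B"
        if (
            self.osc_amplitude > 0
            and self.osc_amplitude * self.E_plateau >= OSC_DETECTABILITY_SD * self.noise_sd
        ):
            return "A"
        if self.duration_s - self.plateau_reached_s() >= steady_window_s:
            return "D"
        return "C"

    def true_E(self, steady_window_s: float = 900.0) -> float:
        """Mean of the noise-free curve over the trailing steady window."""
        t = self.time_axis()
        cutoff = t[-1] - steady_window_s
        tail = t[t > cutoff]
        return float(self.mean_curve(tail).mean())


@dataclass
class TraceTruth:
    """Ground-truth labels attached to a simulated trace."""

    curve_class: str
    steady: bool
    E_true: float
    spec: TraceSpec

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2)


def simulate_flow(spec: TraceSpec) -> tuple[FlowTrace, TraceTruth]:
    """Generate an area-normalized flow trace plus its ground truth.

    Seeded runs are bit-reproducible; with ``ar1`` nonzero the Gaussian
    noise is filtered to the requested lag-1 autocorrelation while keeping
    its marginal standard deviation at ``noise_sd``.
    """
    t = spec.time_axis()
    mean = spec.mean_curve(t)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        innov = rng.normal(0.0, spec.noise_sd, size=t.size)
        if spec.ar1 != 0.0:
            noise = np.empty_like(innov)
            noise[0] = innov[0]
            c = np.sqrt(1.0 - spec.ar1**2)
            for k in range(1, t.size):
                noise[k] = spec.ar1 * noise[k - 1] + c * innov[k]
        else:
            noise = innov
    else:
        noise = np.zeros_like(t)
    trace = FlowTrace(
        time_s=t,
        flow=mean + noise,
        flow_units=FLOW_PER_AREA,
        sampling_interval_s=spec.interval_s,
    )
    truth = TraceTruth(
        curve_class=spec.true_class(),
        steady=spec.true_class() == "D",
        E_true=spec.true_E(),
        spec=spec,
    )
    return trace, truth


def flow_to_weight(trace: FlowTrace, spec: TraceSpec, w0_g: float = 100.0) -> FlowTrace:
    """Integrate a flow trace into the balance's cumulative weight series.

    weight(t) = w0 − M_w × ∫₀ᵗ (leaf_area × flow + blank_evap) dt by the
    trapezoid rule, with M_w the molar mass of water in g mmol⁻¹.  Running
    the flow derivation on the (noiseless) output recovers the input flow
    up to discretization error.
    """
    if trace.flow is None:
        raise ParameterError("flow_to_weight requires a flow series")
    q_mmol_s = spec.leaf_area_m2 * trace.flow + spec.blank_evap_mmol_s
    loss_g = WATER_MOLAR_MASS_G_MMOL * cumulative_trapezoid(
        q_mmol_s, trace.time_s, initial=0.0
    )
    return FlowTrace(
        time_s=trace.time_s.copy(),
        weight_g=w0_g - loss_g,
        sampling_interval_s=trace.sampling_interval_s,
    )


def simulate_blank(
    duration_s: float,
    rate_mmol_s: float = 0.115e-3,
    noise_sd_g: float = 0.0,
    seed: int | None = None,
    interval_s: float = 3.0,
    w0_g: float = 100.0,
) -> FlowTrace:
    """Weight-only trace of a leafless cylinder evaporating at a fixed rate.

    The default rate is the loss of an uncovered cylinder
    (0.115 × 10⁻³ mmol s⁻¹, i.e. ≈ 7.5 mg h⁻¹).
    """
    if rate_mmol_s < 0:
        raise ParameterError("rate_mmol_s must be >= 0")
    t = np.arange(0.0, duration_s + 0.5 * interval_s, interval_s)
    w = w0_g - rate_mmol_s * WATER_MOLAR_MASS_G_MMOL * t
    if noise_sd_g > 0:
        rng = np.random.default_rng(seed)
        w = w + rng.normal(0.0, noise_sd_g, size=t.size)
    return FlowTrace(time_s=t, weight_g=w, sampling_interval_s=interval_s)
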