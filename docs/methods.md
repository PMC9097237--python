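# Methods

`efmkit` processes evaporative-flux-method (EFM) measurements of leaf
hydraulic conductance. In the EFM, an excised leaf transpires under
controlled light, temperature and airflow while drawing water through a
tube from a reservoir standing on a precision balance; the reservoir's
weight-loss rate is the water flow through the leaf. Once that flow is
steady and the final leaf water potential ψ_final has been measured with a
pressure chamber, the conductance is

    K_leaf = E / (0 − ψ_final)      [mmol m⁻² s⁻¹ MPa⁻¹]

with E the steady area-normalized flow (mmol m⁻² s⁻¹) and ψ_final in MPa
(< 0). Everything in the package serves one of three goals: deriving E
defensibly from the raw balance log, deciding *whether a steady state was
ever reached* (the main source of irreproducibility in published K_leaf),
and reporting the result with enough metadata to be reusable.

## Flow derivation

The balance logs cumulative weight, nominally every 3 s. Flow at each
sample is minus the ordinary-least-squares slope of weight vs. time over a
centered sliding window, divided by the molar mass of water
(18.015 g mol⁻¹). The default window is 60 s (user-settable): wide enough
to suppress ±0.01 mg balance jitter, narrow relative to the 15-min
structure that steadiness detection inspects. Windows are truncated (made
asymmetric) at the trace edges instead of dropping edge samples, so the
flow series keeps the trace's length; the estimator is exact on any affine
weight series regardless of window.

Background reservoir evaporation — about 0.115 × 10⁻³ mmol s⁻¹ for an
uncovered cylinder, i.e. ~7.5 mg h⁻¹ — can be subtracted as a constant
blank rate. The correction is applied to per-leaf flow (mmol s⁻¹), before
area normalization, because the blank is a property of the cylinder, not
the leaf. The default blank rate is zero: the recommended physical
prevention (liquid-wax surface cover plus a humidified weighing chamber)
suppresses the loss to near nothing, and subtraction is only appropriate
when a matching blank run exists. Negative corrected flows are retained
and flagged, never clipped.

## Segmentation

The flow–time curve is decomposed into contiguous straight-line pieces by
penalized dynamic programming. A candidate segment over samples [i, j] is
scored by minus its OLS residual variance, score = −rss/n, and each break
point costs a penalty P; the DP maximizes Σ score − P × (breaks) over all
segmentations with ≥ 3 samples per segment. Scores come from centered
prefix sums (O(1) per evaluation after one linear pass; O(n²) total), and
the recursion is exact — a test verifies equality with exhaustive
enumeration on small traces. Ties are broken toward fewer segments, then
toward a longer final segment, making the output deterministic.

P controls how much within-segment variance is tolerated: large P gives
few long segments. Because the score has units of flow variance, the
default penalty auto-scales to 0.02 × var(flow), which makes the
segmentation invariant to rescaling the flow axis. The constant 0.02 was
chosen as the largest (most parsimonious) scale at which the segmentation
still separates rise curvature and stomatal-oscillation half-waves from
genuine plateaus while leaving a pure-noise plateau as one segment; it is
user-overridable, as is an absolute P.

Segments shorter than 60 s are treated as outlier artifacts, not flow-regime
changes: each is dissolved (shortest first) into whichever neighbor gives
the smaller combined residual variance, with refitting, until none remain.

## Steadiness classification

A merged segmentation is assigned one of four curve classes:

* **C** — the last segment spans less than 15 min: the recording ended
  before a steady regime could be demonstrated.
* **D** (steady) — the last segment spans ≥ 15 min *and* the OLS slope of
  the trailing 15-min window (300 points at 3-s sampling) is not
  significantly different from zero: two-sided t-test with n − 2 degrees
  of freedom, p > 0.001. Only class D yields an E (the mean flow over that
  trailing window) and hence a K_leaf.
* **A** (oscillating) — the duration rule passed but the slope test
  failed, and the post-peak segment slopes change sign at least twice.
  The anchor is the first crest (first +→− slope transition) of the fitted
  segments; anchoring at the global flow maximum would never register
  oscillation, because a rising trace's global maximum sits at the *last*
  crest, leaving at most one post-peak segment.
* **B** (drifting) — the slope test failed and the post-peak trajectory is
  monotone (typically a decline after a short-lived peak).

Degenerate slope-test inputs follow fixed conventions: a perfect nonzero
trend gives p = 0, a perfectly flat window gives p = 1.

One numerical subtlety matters when flow was derived from weight by the
sliding window: within one window width, consecutive flow samples share
raw data and are strongly serially correlated. The plain t-test assumes
independent residuals and becomes arbitrarily overpowered on such series —
in testing it flagged residual exponential approach of ~0.05 % of the
plateau as significant drift. For traces that carry smoothing provenance,
the steadiness test therefore thins the trailing window to one sample per
smoothing width (e.g. 15 of the 300 points at the defaults) before
testing; the window span, the E computation and directly measured flow
series are unaffected. The t-test's calibration on independent samples is
verified by Monte Carlo (the rejection fraction at α = 0.001 over 10,000
white-noise windows lies inside the 99 % binomial interval).

## K_leaf, viscosity standardization, desk checks

K_raw = E/(−ψ_final) is computed only from class-D traces; the call fails
explicitly otherwise. Because water's dynamic viscosity falls ~2 % per °C
near room temperature, conductances are standardized to 25 °C:
K_25 = K_raw × η(T_leaf)/η(25 °C), so a leaf warmer than 25 °C is corrected
downward. η(T) uses the CRC Handbook two-branch empirical correlation
(Hardy–Cochrane form below 20 °C, Kestin form 20–100 °C, anchored at
η(20 °C) = 1.002 mPa·s), which reproduces tabulated values within ~0.1 %
over (0, 100) °C — far below EFM measurement error; any published
correlation agrees to < 0.5 % over the 15–40 °C range that matters here.
The correlation is exposed as `water_viscosity_mPa_s` for inspection.

Two desk checks quantify setup tolerances. `hydrostatic_pressure_kPa`
computes ρ·g·h (ρ = 1000 kg m⁻³, g = 9.8 m s⁻²) for a height offset
between leaf and reservoir meniscus: 0.196 kPa for 2 cm, about 0.06 % of a
typical 0.3 MPa driving force. (This figure is sometimes quoted with the
unit "Pa"; dimensionally ρgh for 2 cm of water is 196 Pa = 0.196 kPa, and
the package reports kPa.) `sensitivity_grid` tabulates K_leaf while E and
ψ_final are varied one at a time around a reference: K is linear in E but
hyperbolic in ψ_final, so over the observed ψ_final range of −0.17 to
−0.45 MPa at fixed E = 8.7 mmol m⁻² s⁻¹ the conductance changes 2.65-fold —
small-|ψ_final| measurements amplify ψ error severely.

## Synthetic traces and what passing tests mean

The generator produces flow(t) = E_plateau · (1 − e^(−t/τ)) ·
(1 + a·sin(2πt/P_osc)) · e^(−r·max(0, t − 3τ)) plus Gaussian noise
(optionally AR(1)-filtered to a requested lag-1 autocorrelation at
constant marginal SD), and integrates area-scaled flow plus blank
evaporation into a cumulative weight series (trapezoid rule) to emulate a
balance log. Ground-truth labels come from the parameters alone:
decline ⇒ B; oscillation amplitude ≥ 3 noise SD ⇒ A; plateau (99 %)
reached with ≥ 15 min to spare ⇒ D; else C.

Default conditions emulate a rice leaf under 1000 µmol m⁻² s⁻¹ PAR:
plateau 8.75 mmol m⁻² s⁻¹, τ = 120 s, 30 min at 3-s sampling, noise
0.1 mmol m⁻² s⁻¹ (~1 % of plateau), 25 cm² leaf area. The test conditions
for the other families: decline 6 × 10⁻⁵ s⁻¹ (final-window drift ≈ 4.7
noise SD); short-plateau runs of 1150 s (a ~10-min flat stretch); and
oscillation of 8 % amplitude with a 2000-s period in a 3450-s run, chosen
by phase analysis so the final monotone half-wave itself exceeds 15 min
while the trailing-window slope is clearly nonzero. Test problem sizes —
200 traces for classification accuracy, 50 end-to-end weight-log
recoveries, 10,000 t-test replicates, exhaustive-enumeration checks at
n ≤ 15 — were chosen so the whole suite runs in well under a minute of
the heavy tests' budget while keeping binomial/recovery margins wide.

The generator reproduces the *shapes* that matter to the classifier, not
leaf physiology: noise is (at most AR(1)) Gaussian rather than the
heavier-tailed disturbances real balances produce (vibration spikes,
door-opening steps), oscillation is a fixed-amplitude sinusoid rather than
the drifting quasi-periodic cycles of real stomata, and temperature and
humidity are constant. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated conditions, not
robustness to every field artifact; the 1-min merge rule and the
configurable penalty are the intended levers for messier data.

## Known limitations

* A trace that drifts more slowly than the t-test's detection limit over
  the final window is indistinguishable from steady — by construction of
  the criterion, not by implementation.
* An oscillation whose period divides twice the test window can place a
  phase-symmetric arc in the trailing window and pass the slope test; the
  segment-based duration rule usually, but not always, catches this.
* The A/B distinction (oscillating vs drifting) is heuristic; the steady /
  non-steady boundary, which controls whether a K_leaf is reported, does
  not depend on it.
* Blank-evaporation correction assumes a constant rate; it does not model
  humidity- or temperature-dependent evaporation during a run.
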