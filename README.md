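# efmkit

Processing toolkit for **evaporative-flux-method (EFM)** measurements of
leaf hydraulic conductance (K_leaf), aimed at plant ecophysiologists and
hydraulic-phenotyping labs.

In the EFM an excised, transpiring leaf draws water from a reservoir on a
precision balance; the reservoir's weight-loss rate is the flow through
the leaf. When that flow is steady,

```
K_leaf = E / (0 − ψ_final)        [mmol m⁻² s⁻¹ MPa⁻¹]
```

with E the steady area-normalized flow (mmol m⁻² s⁻¹) and ψ_final the
final leaf water potential (MPa, < 0). The fragile step is deciding that
the flow ever *was* steady: real traces oscillate (stomatal cycling),
decline after a brief peak, or end before a plateau lasted long enough,
and a K_leaf computed from such a trace is meaningless. `efmkit`
implements the whole chain:

* **Flow derivation** — sliding-window OLS slope of the balance's weight
  log (default 60 s window), blank-evaporation correction, area
  normalization.
* **Steady-state identification** — exact penalized piecewise-linear
  segmentation of flow vs. time by dynamic programming (score −rss/n per
  segment, per-breakpoint penalty P, sub-minute segments merged away),
  then the steadiness rules: last segment ≥ 15 min, trailing 15-min slope
  t-test p > 0.001. Traces are classed **A** (oscillating), **B**
  (drifting), **C** (too short) or **D** (steady); only class D yields a
  K_leaf.
* **K_leaf** — E from the trailing steady window; viscosity
  standardization to 25 °C via K_25 = K_raw × η(T_leaf)/η(25 °C);
  hydrostatic and sensitivity desk checks.
* **Synthetic traces** — a generator for all four curve families with
  analytic ground truth, so the pipeline's accuracy is measurable without
  a balance.
* **Standardized reporting** — tidy, unit-annotated CSV rows per leaf
  (metadata + steadiness evidence + K_leaf, NA for non-steady leaves) and
  long-format raw-flow archives.

## Worked example

```python
from efmkit import LeafRecord, TraceSpec, simulate_flow, flow_to_weight, process_trace

spec = TraceSpec(seed=42)                      # 30-min run, plateau 8.75 mmol m-2 s-1
flow_trace, truth = simulate_flow(spec)
weight_log = flow_to_weight(flow_trace, spec)  # what the balance would record

leaf = LeafRecord(species="Oryza sativa", leaf_area_m2=2.5e-3,
                  psi_final_MPa=-0.31, T_leaf_C=27.0, PARa_umol_m2_s=1000.0)
result = process_trace(weight_log, leaf, leaf_id="rice-001")
print(result.record.curve_class, result.record.E_mmol_m2_s,
      result.record.K_leaf_raw, result.record.K_leaf_25C)
```

prints (see `examples/02_weight_log_to_kleaf.py` for the narrated version):

```
curve class          : D (steady)
steady flow E        : 8.748 mmol m-2 s-1 (true 8.749)
K_leaf (raw, 27 C)   : 28.22 mmol m-2 s-1 MPa-1
viscosity factor     : 0.9560
K_leaf (25 C)        : 26.98 mmol m-2 s-1 MPa-1
```

The trace was classified steady (class D), so the mean flow over the
trailing 15-min window is a valid E; dividing by the 0.31 MPa driving
force gives the raw conductance, and the viscosity factor removes the
purely physical flow advantage the 27 °C leaf had over the 25 °C
reference. The non-steady classes never produce a K_leaf — they appear in
reports with their class and diagnostics and `NA` conductance.

More walkthroughs live in `examples/`: curve-family classification,
sensitivity analysis and desk checks, and batch report generation.

## Command line

```bash
efmkit simulate --out run1 --seed 11          # synthetic balance log + truth sidecar
efmkit process --log run1/balance_log.csv --meta meta.csv --out results/
efmkit sensitivity --e-ref 8.7 --psi-ref -0.31 --out grid.csv
efmkit validate-report results/report.csv     # audit: every K re-derivable from its row
```

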