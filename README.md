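# cabuffer

Analysis toolkit for neuronal Ca²⁺-handling and excitability studies that
combine whole-cell patch-clamp recordings with ratiometric fura-2 imaging —
the kind of experiment used to ask how a cell's calcium buffering,
extrusion and mitochondrial Ca²⁺ stores change between cohorts (for
example, hypothalamic POMC neurons in lean versus diet-induced-obese mice).

It is written for electrophysiologists and imaging labs who have ROI-mean
time series (fluorescence at 340/360/380 nm excitation, membrane voltage,
injected current) and want a tested, scriptable implementation of:

- **Equilibrium speciation of calibration solutions** — free Ca²⁺/Mg²⁺ in
  EGTA/fura-2 recipes from a versioned table of critical stability
  constants, with Davies ionic-strength and van't Hoff temperature
  corrections (`chem_equilibrium`).
- **Fura-2 calibration** — the ratio equation
  `[Ca²⁺]ᵢ = K_d,eff · (R − R_min)/(R_max − R)` with
  `K_d,eff = K_d,Fura · F380_min/F380_max`, its inverse, and dye-loading
  tracking from the isosbestic (360 nm) channel (`fura_calibration`).
- **The "added buffer" method** — the dye itself is the titrated exogenous
  buffer with incremental binding ratio
  `κ_B = [B_T]·K_d / ([Ca²⁺]ᵢ + K_d)²`; under the linear single-compartment
  model the transient decay constant is
  `τ_transient = (1 + κ_B + κ_S)/γ`, so an OLS fit of τ against κ_B yields
  the endogenous binding ratio κ_S (negative x-intercept minus 1), the
  extrusion rate γ (inverse slope) and the endogenous decay constant τ_endo
  (y-intercept). Uncertainty comes from a fixed-x residual bootstrap
  (n = 1000) and cohorts are compared by t-tests on the log-transformed
  bootstrap distributions (`added_buffer`).
- **Spike-train metrics** — detection, spontaneous-activity classification
  (< 0.5 Hz ⇒ not spontaneously active, NSAN), spike-frequency adaptation
  via `Y = (Y0 − Plateau)·exp(−K·T) + Plateau` with Y0 fixed to the first
  instantaneous frequency (SFA ratio = Y0/Plateau, > 3 ⇒ strong
  adaptation), ramp threshold currents and F–I curves (`spike_analysis`).
- **FCCP mitochondrial-release quantification** — baseline-normalised
  Δ(F340/F380) amplitudes from AM-loaded slices with per-cohort
  aggregation and testing (`fccp_analysis`).
- **A forward simulator** (`synthetic_data`) that generates every input
  above with known ground truth — loading experiments whose transient
  amplitudes shrink and decays slow as dye accumulates, adapting spike
  trains, ramps/steps, FCCP bumps — plus control-like and DIO-like cohort
  presets, so the entire pipeline is verifiable by parameter recovery.

## Worked example

Speciation of a defined-Ca²⁺ calibration solution (recipe in
`examples/r_def.yaml`: 4 mM EGTA, 2.7 mM CaCl₂, 1 mM MgCl₂, 0.05 mM
fura-2, pH 7.2):

```sh
$ cabuffer calibrate-solution examples/r_def.yaml
free Ca2+ : 0.3377 uM
free Mg2+ : 0.9834 mM
apparent Kd(EGTA) : 0.1659 uM at pH 7.2
apparent Kd(fura-2) : 0.2563 uM at pH 7.2
```

About one third of a micromolar free Ca²⁺: EGTA is roughly two-thirds
Ca-loaded, so the free level sits near twice its pH-conditional K_d.

End-to-end simulate-and-analyse run (8 cells per cohort, seed 1,
1000 bootstrap samples):

```python
from cabuffer.cli_io import run_pipeline

res = run_pipeline({"cohorts": {"control": 8, "DIO": 8}, "seed": 1})
```

prints, via the equivalent `cabuffer run --seed 1`:

```
control: kappa_S = 492 +/- 18, gamma = 149.4 +/- 3.0 1/s, tau_endo = 3.30 s (80 points)
DIO:     kappa_S = 244 +/- 5,  gamma = 112.3 +/- 0.9 1/s, tau_endo = 2.18 s (80 points)
kappa_s_DIO_vs_control: p < 1e-300 (***)
gamma_per_s_DIO_vs_control: p < 1e-300 (***)
```

The pooled fits recover the generating cohort parameters (κ_S = 497 vs
240, γ = 150 vs 111 s⁻¹) within ~1–2 %, the bootstrap spreads match the
dispersion built into the cohorts, and the log-scale comparison separates
the cohorts decisively — the DIO-like preset has weaker buffering *and*
slower extrusion, which is why its resting Ca²⁺ is higher yet its
transients at low dye load decay faster.

Other entry points: `cabuffer simulate` (write a synthetic cohort as
CSV/YAML), `cabuffer added-buffer --cells DIR`, `cabuffer sfa`,
`cabuffer fccp`, and the library API re-exported from `cabuffer`
(see `docs/methods.md` for the model details and assumptions).

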