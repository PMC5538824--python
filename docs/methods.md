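# Methods

This note documents the models implemented in `cabuffer`, their
assumptions, the defaults that matter, and what the synthetic-data tests
do and do not demonstrate about real recordings.

## Calibration-solution chemistry (`chem_equilibrium`)

**Model.** Calibration solutions are treated as closed equilibrium systems
at fixed, buffered pH. Each chelator L (EGTA, fura-2) binds protons
stepwise (H⁺ + Hₙ₋₁L ⇌ HₙL) and Ca²⁺/Mg²⁺ at the fully deprotonated site.
The coupled mass-action + mass-balance system in the unknowns
(free Ca²⁺, free Mg²⁺, free unprotonated L per chelator) is solved with a
Powell-hybrid root finder in log₁₀ space; convergence is enforced at a
relative residual < 1e−9 (typically ~1e−15), and mass conservation per
element is an explicit invariant of the test suite.

**Constants.** The shipped table (version `critical-2024.1`) holds
critical-compilation stability constants on a 20 °C, I = 0.1 M molar
reference: EGTA log K_H = 9.47, 8.85, 2.66, 2.00; log K_CaL = 10.97;
log K_MgL = 5.21; fura-2 log K_H = 6.40, 5.50, log K_CaL = 6.96
(equivalent to the familiar ~0.14–0.24 µM dye K_d once protonation and
ionic strength are folded in), with reaction enthalpies for the
temperature-sensitive EGTA equilibria.

**Corrections.** Three standard conversions are applied:

1. *Ionic strength* — Davies equation, `log γ = −0.51 z² (√I/(1+√I) −
   0.3 I)`, applied per reaction through Δ(z²); association constants
   decrease with I, as they must. Valid to I ≈ 0.5 M; no activity model
   beyond Davies is attempted.
2. *Temperature* — van't Hoff with tabulated ΔH (the 2 °C step from the
   reference to room temperature moves the EGTA apparent K_d by a few
   per cent).
3. *pH scale* — a meter reads proton **activity**; the proton
   concentration entering the mass-action terms is 10^(−pH)/γ_H with γ_H
   from Davies. This is the convention of the widely used Ca-buffer
   calculators and moves the EGTA apparent K_d at pH 7.2 by ~40 %, so it
   is not optional.

If the recipe does not state an ionic strength it is estimated from the
composition (inert salts fully dissociated; chelators at their dominant
protonation-state charge; HEPES treated as ionically silent). Hydroxide
totals contribute their cation only: the pH is set by the buffer, and no
proton balance is solved. Protonated metal complexes (CaHL, MgHL) are
omitted; near pH 7.2 their share is below 10⁻⁴ of the bound pool.

**EGTA purity** is exposed as a multiplicative factor on chelator totals
(default 1.0). Commercial EGTA is typically 92–98 % pure; the defined-Ca²⁺
example recipe solves to 0.34 µM free Ca²⁺ at purity 1.0 and ~0.35–0.38 µM
at realistic purities, which is the scale of uncertainty a user should
expect from this term alone.

## Fura-2 calibration (`fura_calibration`)

The ratio equation and its inverse are exact algebra; the numerical
choices are at the edges. Ratios at or above R_max raise a saturation
error (Ca²⁺ undefined), while ratios slightly below R_min — routine at
rest under photon noise — clip to 0 nM with a warning rather than error,
so resting-level estimates stay robust. The effective dissociation
constant can be taken from a defined-Ca²⁺ solution
(`effective_kd`, independent of dye concentration) or assembled from the
chemical K_d and the 380-nm dynamic range; both live in
`CalibrationResult` because downstream arithmetic needs them separately:
Eq.-style ratio conversion uses K_d,eff, the dye's Ca²⁺-binding ratio κ_B
uses the chemical K_d.

Isosbestic conversion assumes a single scalar (ADU per µM, obtained by
imaging the pipette solution under identical optics); bleaching and
spatial effects are out of scope. The loading curve is fit with
`c(t) = c_∞(1 − e^(−t/τ_fill))` by bounded least squares; constant or
non-converging data are flagged, never silently fitted.

## Added-buffer estimation (`added_buffer`)

**Model.** Linear single-compartment: a brief Ca²⁺ influx distributes
instantly between free Ca²⁺, endogenous buffer (κ_S) and dye (κ_B), and is
cleared by a lumped linear extrusion rate γ, giving
`τ_transient = (1 + κ_B + κ_S)/γ`. The pure linear form is used
throughout; no loading-time correction term is modelled, because every
extraction rule (x-intercept −(1+κ_S), slope 1/γ, y-intercept τ_endo) is
defined on the straight line. Assumptions worth keeping in mind: buffers
fast and unsaturated at transient amplitudes, extrusion linear in Ca²⁺,
dye concentration quasi-static within a single transient.

**Per-transient processing.** Resting Ca²⁺ comes from the mean ratio over
the 5-s pre-stimulus baseline. The dye concentration is extrapolated
linearly from the baseline isosbestic samples to the stimulus onset —
the cell is still filling during the baseline window, and using the
window mean instead biases κ_S upward by ~2 % even without noise. Decay
fits are mono-exponential from the peak; a transient is accepted when the
fit converges, τ ∈ [0.05, 60] s, and the residual RMS is below 20 % of the
amplitude (the acceptance rule is a package choice; it rejects flat or
pathological segments without touching healthy fits).

**Fit and uncertainty.** Unweighted OLS (statsmodels), matching the usual
R `lm` treatment; pointwise confidence bands from the fit covariance.
Points are pooled per cohort by default (a per-cell workflow is available
by calling the fit per cell). A non-positive slope is non-physical and
raises an error carrying the raw coefficients. The bootstrap is fixed-x
(residual) resampling: the κ_B design is kept, residuals are resampled
with replacement onto fitted values, and the line is refit — vectorised
over all replicates via the pseudoinverse of the fixed design, so 1000
replicates cost one matrix product. Replicates with non-positive slope
are counted and excluded. Cohort comparison takes natural logs of the
bootstrap distributions (bringing them close to Gaussian) and applies a
Welch unpaired t-test; identical zero-variance samples are defined to give
p = 1 rather than NaN.

## Spike analysis (`spike_analysis`)

Spikes are upward crossings of −20 mV with a 2-ms refractory period
(deterministic, sampling-rate stable for ≥ 5 kHz waveforms).
Spontaneous-activity classification is strict: mean rate < 0.5 Hz over the
full epoch ⇒ NSAN. Instantaneous frequency is 1/ISI timestamped at the
second spike of each interval.

The adaptation fit holds Y0 fixed at the first instantaneous frequency
and fits (Plateau, K) by least squares. One convention matters: the
exponential's time origin is anchored at the first frequency sample.
Because Y0 is *defined* as the frequency at that sample, anchoring
anywhere else (e.g. literally at stimulus onset) makes the fixed-Y0 model
inconsistent with the decay law it is read from and biases K by a few per
cent; with this anchoring, jitter-free round trips through the simulator
recover (Plateau, K) to machine precision. The SFA ratio is defined as
Y0/Plateau — the ratio is 1 for a non-adapting cell, > 3 is treated as
strong adaptation, and a plateau below 0.1 Hz (cell effectively stops
firing) maps to +∞ with a flag. The ratio is dimensionless. A flat series
leaves K unidentifiable and is flagged as such.

Ramp thresholds report the injected current at the first detected spike
(no spike ⇒ explicit no-threshold flag); because a real membrane charges
with τ_m, steeper ramps read equal-or-higher thresholds, and the
simulator reproduces that lag. F–I curves count spikes per step, sort by
current, and average duplicated currents with a note. The 10-s AP count
uses the full window (no onset exclusion).

## FCCP release (`fccp_analysis`)

AM-loaded data have no defined background, so no background is
subtracted and the primary statistic is the raw-ratio amplitude
ΔR = peak(R) − R₀, with R₀ the pre-application baseline mean.
Baseline-normalised traces R(t)/R₀ (baseline mean exactly 1,
gain-invariant) are produced for visualisation and overlays; note the
deliberate asymmetry that raw ΔR is rig-specific (an F340-only gain
scales it), which is why cohort comparisons should come from one rig.
The peak is searched from application onset to 5 min past application end
(responses outlast the application) after a 5-sample moving average;
non-responders (ΔR ≤ 0) are retained. Cohort aggregation reports
mean ± SEM over cells with slices counted separately, and exposes both an
unpaired Welch t-test (default) and Mann-Whitney U — both appear in the
literature for this endpoint, and they can disagree near the 0.05
boundary, so the choice is explicit.

## Forward simulator (`synthetic_data`)

The generator emulates, with stored ground truth:

- **Loading experiments** — dye fills as `B(t) = B_pip(1 − e^(−t/τ_fill))`
  (defaults 200 µM pipette, τ_fill = 300 s, 20-Hz imaging, 600 s, stimuli
  every 60 s, so κ_B sweeps ~70→600); each stimulus injects a fixed total
  Ca²⁺ load (default 100 µM-total, chosen to give ~200 nM free transients
  at low dye load) that raises free Ca²⁺ by `influx/(1+κ_S+κ_B)` (rapid
  buffering approximation) and decays with `τ = (1+κ_S+κ_B)/γ`; κ_B is
  held at its onset value within a transient (quasi-static dye). Stored
  (κ_B, τ) truths are exactly collinear before noise — the oracle for the
  fit. Fluorescence: F360 ∝ B(t); F380 ∝ B(t) times the free-dye
  fraction; F340 = R·F380; multiplicative Gaussian noise per wavelength
  (shot-noise proxy, default CV 2 %) applied last. Schedules whose
  transients would overlap the next stimulus within 5 τ are rejected.
- **Adapting trains** — from a spike at onset (plus 5 ms latency), each
  ISI solves `ISI = 1/Y(t + ISI)`, so the measured instantaneous
  frequency equals the adaptation law exactly at the spike times; ISI
  jitter is multiplicative lognormal (default CV 3 % in cohorts). The
  spike count over 10 s equals the integral of Y within rounding.
- **Ramps/steps** — passive RC subthreshold behaviour with a stereotyped
  AP template on a −60 mV baseline; adequate to exercise the detector and
  the threshold/F–I logic, with no claim to AP biophysics.
- **FCCP traces** — difference-of-exponentials bump (rise 30 s,
  fall 120 s) normalised so its peak equals the requested ΔR exactly, on
  a stable baseline ratio.

**Cohort presets.** Two parameter sets, "control" and "DIO", carry the
group means this package is designed to resolve: κ_S = 497 vs 240,
γ = 150 vs 111 s⁻¹, resting Ca²⁺ 19.3 vs 45.8 nM, membrane potential
−58.8 vs −64.0 mV, spontaneous rate 3.4 vs 1.7 Hz, silent fractions
8/26 vs 19/37, strong-adaptation fractions 4/19 vs 10/29, FCCP
ΔR 0.020 vs 0.012. Per-cell parameters are drawn lognormally around the
preset mean with the associated standard error as the dispersion — a
deliberately tight, well-posed population; class memberships (silent,
strong adaptation) are deterministic rounded counts so cohorts built at
the reference group sizes reproduce the reference percentages exactly.
Firing-subpopulation rates are rescaled so the cohort mean matches the
preset despite the silent fraction. All randomness flows from one
`numpy` Generator per cohort; identical seeds give byte-identical output.

**What passing tests show — and don't.** Parameter recovery on this
generator demonstrates that the analysis chain is unbiased and correctly
seeded *under the model's own assumptions* (mono-exponential decays,
linear buffering, multiplicative noise, no drift). Real recordings add
bleaching, movement, dye compartmentalisation, saturating extrusion and
non-stationary baselines, none of which the generator emulates; recovery
here is a necessary check, not a validation on real data.

## Problem sizes and reproducibility

Default test and pipeline sizes — 8–20 cells per cohort, 10 transients
per cell, 1000 bootstrap replicates, 50–100 Monte-Carlo seeds per
round-trip check — were chosen so the full suite exercises every claim at
comfortable statistical resolution while staying quick to run on a
laptop. Every stochastic routine takes an explicit seed or Generator;
pipeline outputs are stamped with the seed and a hash of the
configuration.

## Known limitations

- Single-compartment, linear model only: no ER/mitochondrial flux terms,
  no saturating extrusion, no multi-exponential decays.
- The Davies equation caps the chemistry module at I ≈ 0.5 M, and pH is
  taken as buffered (no proton balance).
- Voltage synthesis is a template generator, not a conductance model;
  F–I "gain" is a bookkeeping construct for testing the analysis.
- Trace I/O covers ROI-mean CSV time series; image stacks, segmentation
  and registration are out of scope.
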