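# Methods

## Scope and model overview

`cardiopatch` simulates how spatially heterogeneous, inflammation-driven
electrophysiological remodeling turns a regularly beating cardiac sheet
into an irregular, arrhythmia-prone substrate.  Three remodeling axes are
modeled as multiplicative downregulation factors applied inside circular
tissue patches:

* `s_na` — scales the fast sodium current I_Na (SCN5A / Nav1.5 activity),
* `s_nak` — scales the Na+/K+ ATPase pump current I_NaK (ATP1A1 activity),
* `s_cond` — scales local tissue conductivity (gap-junctional coupling,
  GJA5 / connexin-40 activity).

Tissue outside the patches keeps control properties, so remodeled and
control myocytes coexist in one electrical syncytium.

## Transmembrane voltage model

The monodomain reaction–diffusion equation

    dV/dt = −I_ion(y, V)/C_m + ∇·(D ∇V)

is solved on a regular 2D square grid (default element edge 250 µm).
Space: 5-point Laplacian; the interface diffusivity between neighboring
elements is the harmonic mean of the two element diffusivities, which
preserves flux continuity across conductivity jumps at patch borders.
Boundaries (and inactive elements, e.g. the pseudo-atria septal wall) are
no-flux.  Per-element diffusivity is `base_diffusivity × s_cond`
(cm²/ms); isotropy is assumed throughout.

Time: Godunov operator splitting.  Hodgkin–Huxley gates advance by
Rush–Larsen updates (exact for frozen voltage), concentrations and the
membrane voltage by forward Euler.  When the explicit-diffusion stability
bound dx²/(4 D_max) is larger than the reaction step, several reaction
substeps share one diffusion step (≤ 0.1 ms); when the bound is tighter
(high diffusivity), the cheap diffusion update is sub-cycled inside one
reaction step instead.  Both regimes respect the CFL bound exactly.

### Time steps

Single-cell defaults are 0.02 ms (hiPSC model) and 0.01 ms (atrial
model).  Tissue runs use 0.1 ms and 0.02 ms respectively: measured
convergence shows the spontaneous cycle length changes by 0.12 % and
APD90 by < 0.5 % between the tissue and single-cell steps, far below the
effect sizes of interest.  Gating variables are clamped to [0, 1] after
every update; clamp events are counted and reported in run metadata.

### Performance path and its verification

Production kernels (numba) read voltage-dependent gate targets,
Rush–Larsen factors and current prefactors from tables on a 0.02 mV grid
with linear interpolation.  A plain-NumPy right-hand side, generated from
the same rate formulas, serves as the reference implementation: tests
integrate it with an independent adaptive-step method (LSODA) and require
the production path to match the spontaneous cycle length and APD90
within 1 %.  Single-step equivalence between the two paths is ≤ 2×10⁻⁴
relative (table interpolation error).

## Ionic models

Two published human models are implemented behind one interface, both
exposing `s_na` and `s_nak` as exact multiplicative factors on I_Na and
I_NaK (all other currents untouched):

* **hiPSC-CM (Paci-type, spontaneous).**  A ventricular-like induced
  pluripotent stem-cell cardiomyocyte model in the 2013 Paci formulation:
  I_Na, I_CaL, I_f, I_Kr, I_Ks, I_K1, I_to, I_NaK, I_NaCa, I_pCa,
  background currents, and ten-Tusscher-style SR calcium handling
  (18 states).  The equation set was transcribed from the published model
  description; because transcription fidelity cannot be proven
  equation-by-equation here, the implementation is validated against the
  published *emergent behavior*: spontaneous rate 41.6 bpm (published
  ~0.5 Hz), APD90 ≈ 322 ms, maximum diastolic potential −76.6 mV, peak
  +31 mV, amplitude ≈ 106 mV.  Halving I_NaK depolarizes the maximum
  diastolic potential (−76.6 → −74.9 mV) and slowly raises [Na+]i, both
  in the direction reported for pump inhibition.
* **Adult atrial (Courtemanche–Ramirez–Nattel 1998).**  The standard
  21-state human atrial myocyte model; quiescent without stimulation,
  resting at −81.2 mV, APD90 ≈ 297 ms at 1 Hz.  Halving I_NaK prolongs
  APD90 by ~24 ms (295 → 319 ms), the repolarization-prolongation
  direction that creates the heterogeneous substrate in the atria.

Initialization: the atrial model starts from its published resting state;
the hiPSC model is pre-run for 10 s to settle its limit cycle before any
recorded experiment.  For triggered-wave measurements on the (otherwise
spontaneous) hiPSC model, cables start from a "diastolic" snapshot taken
600 ms after a spontaneous beat, leaving a ≳1 s quiescent window.

## Geometries

* **hiPSC sheet**: uniform square mesh.  The full-scale configuration is
  100×100 elements (6.25 cm²); the desk-scale suite uses 40×40 (1 cm²).
* **Pseudo-atria**: the whole-organ atrial geometry is reduced to a 2D
  two-chamber sheet: rectangular right and left chambers separated by an
  inexcitable septal wall, joined by a conducting bridge
  (Bachmann-bundle analog, default 0.4 of the sheet height ≈ 0.4 cm —
  the anatomical bundle width; a much narrower isthmus depresses AP
  peaks at its exit below the 0 mV registration threshold through
  source-sink expansion load), each chamber with a superior venous
  sub-zone;
  a sinus-node pacing site sits at the superior right-atrial border.
  Default 80×40 elements (2×1 cm).  This preserves the localized-versus-
  spread infiltration logic and the pacing protocol of the whole-organ
  model while remaining tractable on one CPU.

## Remodeling patches

Non-overlapping circles of fixed radius are placed by seeded rejection
sampling inside a placement mask (whole sheet; whole chamber for
"spread"; venous sub-zone for "localized") until the covered element
fraction is within ±2 percentage points of the target (50 % by default,
matching the half-remodeled/half-control design).  Circles may be
clipped by the mask boundary; clipped area counts toward coverage.  When
sampling jams (no admissible candidate without overshooting), placement
restarts with a derived sub-seed (≤ 8 restarts within the global attempt
budget); results are deterministic given the seed.

Scenario grids: control + {I_Na, I_NaK, conductivity} singles and the
three pairs, each at 25 % or 50 % intensity (13 scenarios); for the
atria, {control, localized, spread}² minus all-control = 8 remodeled
configurations plus control, each patch carrying 50 % I_NaK and 50 %
conductivity downregulation at 0.5 cm radius.

## Protocols

* **Spontaneous activity**: stimulus-free run, default 50 s.
* **Stress pacing** (atria): 10 beats at 85 bpm (cycle length 700 ms)
  followed by 5 beats at 190 bpm (310 ms) at the sinus-node site; the
  fast train starts one fast cycle after the last sinus pulse (the
  protocol source states only "subsequently").  Pulses: 2 ms, 60 A/F over
  the pacing site (suprathreshold with margin in tissue).
* **Conductivity calibration**: bisection on log-diffusivity on a 5 cm
  cable (200 elements), bracketed via the cable-theory CV ∝ √D law;
  planar CV is measured between probes at 25 % and 75 % of cable length
  (≥1 cm from each end, avoiding stimulus and boundary artifacts), and
  the returned diffusivity reproduces the target within 2 %.  Control
  targets: 45 cm/s (hiPSC sheet), 0.8 m/s (atrial body).  Calibrated
  values: D ≈ 4.6×10⁻³ cm²/ms (hiPSC), ≈ 2.5×10⁻³ cm²/ms (atrial).

## Readout statistics

* **Activation detection**: upward 0 mV crossings, linearly interpolated
  between samples, with a refractory/debounce window (100 ms hiPSC,
  50 ms atrial).  Tissue runs detect activations on voltage frames
  decimated to 1–2 ms; interpolation keeps timing error ≪ 0.1 ms.
* **Beat irregularity**: per source, instantaneous rates
  r_i = 60000/interval_i; irregularity (%) = SD(r)/mean(r) × 100 (sample
  SD by default; population SD selectable).  Tissue-level aggregation is
  the median across elements (mean and per-element export available);
  elements with fewer than 3 activations are excluded and counted.
* **Conduction mapping**: the per-beat activation-time surface T is
  differentiated by central differences; velocity = ∇T/|∇T|² (cm/s),
  direction = ∇T/|∇T|; gradient magnitudes below 10⁻⁴ ms/cm mark the
  element invalid (quasi-simultaneous activation).
* **Heterogeneity index**: circular variance 1 − |mean unit vector| of
  valid conduction directions (global mode; a local 3×3-neighborhood
  mode is provided).  0 = aligned propagation, 1 = fully disordered.
  For von Mises-distributed directions at concentration κ the index has
  the closed form 1 − I₁(κ)/I₀(κ), used as a test oracle.
* **AP morphology**: per beat, from the preceding diastolic minimum:
  amplitude (peak − diastolic minimum), activation at maximum dV/dt,
  APD90 to 90 % repolarization (interpolated crossing), AUC90 = ∫(V −
  V₉₀) over the APD90 window; across-beat variance statistic SD/mean ×
  100.  An unrepolarized final AP is dropped with a warning.
* **Sustained (AF-like) activity**: after the last stimulus plus a 50 ms
  blanking period, activity is sustained iff ≥ 25 % of elements register
  ≥ 2 activations within a 2 s window.  These thresholds are artifact
  definitions (the source reports AF qualitatively).

## Synthetic readout generators

Deterministic, seeded generators emulate the study's experimental
readouts so that every statistic is testable against ground truth:
beat-event series with gamma-distributed intervals (shape 1/CV²,
positive support without truncation bias); analytic activation-time
surfaces (planar / focal / collision / spiral-like re-activation) with
optional clipped Gaussian jitter preserving per-element monotonicity;
stylized AP trains (2 ms linear upstroke, sagging plateau, exponential
repolarization reaching 90 % at the nominal APD) with optional
alternans; and von Mises-distributed conduction-direction fields.  The
generators emulate event timing and waveform shape, not raw video/MEA
waveforms or optical noise, so passing recovery tests demonstrates
correctness of the statistics, not robustness to instrument noise.

## Desk-scale study design

The mechanism suite runs control + the four 50 % scenarios (I_Na, I_NaK,
conductivity, I_NaK+conductivity) on the 40×40 sheet for 20 s with three
patch seeds, patch radius 0.2 cm (the full-scale 0.5 cm scaled by the
linear mesh ratio), 50 % coverage, diffusivity from the 45 cm/s
calibration.  The pseudo-atria suite keeps the 0.5 cm patch radius
unchanged, because the repolarization substrate survives electrotonic
smoothing only when patches are at least comparable to the atrial space
constant (~0.5 cm; with 0.2 cm patches the APD90 contrast vanishes).

## Numerical and design notes

* Determinism: identical configuration and seed give bit-identical
  activation maps on one platform; solver kernels contain no randomness.
* Voltage tables span −120…+80 mV; states outside are clamped into the
  table (and a blow-up guard aborts runs exceeding ±200 mV with the
  failure time).
* ICaL's GHK-type prefactor has a removable singularity at 0 mV; the
  analytic limit is used on the table grid.
* Remodeling maps are exact: elements outside all patches carry scalers
  (1, 1, 1); coverage is reported from the element recount.
* The CLI (`cardiopatch simulate | simulate-atria | calibrate |
  scenarios | analyze | synth`) is a thin layer over the library; seeds
  are mandatory for stochastic steps.

## Known limitations

* **Electrotonic compactness of the reduced hiPSC sheet.**  On the
  1 cm² desk-scale mesh at the 45 cm/s calibration, the diastolic space
  constant is comparable to the whole sheet, so spontaneous activity is
  fully synchronized: every element shares the global beat sequence.
  In this regime the irregularity statistic responds to the slow
  I_NaK-driven drift of the limit cycle (combined and I_NaK-only
  scenarios roughly double control irregularity) but conductivity
  downregulation has no pathway to add beat-to-beat variability, and
  the combined scenario ties the I_NaK-only scenario instead of
  exceeding it.  Reproducing the full separation of the combined
  scenario appears to require tissue much larger than the space
  constant (the full-scale 6.25 cm² mesh at 50 s, beyond a desk-scale
  test budget) and possibly cell-to-cell parameter variability, which
  the study design does not specify and which this package therefore
  does not invent.  The full-scale configuration is exposed through the
  normal API/CLI for users with the compute budget.
* The hiPSC model is a careful reconstruction of the published
  formulation validated behaviorally, not a certified copy of a
  reference implementation.
* Isotropic conductivity; no fiber architecture, no anisotropy ratios,
  no realistic atrial anatomy; the bidomain formulation, drug-binding
  channel models and temperature effects are out of scope.
* Repolarization times are not registered in the activation map by
  default (APD metrics come from probe/frame traces instead).
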