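# Methods

## Frequency-domain lifetime estimation

Under sinusoidal excitation at frequency f (ω = 2πf, default 550 kHz), a
mono-exponential emitter of lifetime τ responds with phase lag
φ = arctan(ωτ) and demodulation m = 1/√(1+(ωτ)²). Each pixel's K
phase-stepped samples (default K = 8, configurable; K ≥ 3 required) are
reduced to the first-harmonic Fourier coefficients

    c0 = Σ I_k / K,  a = (2/K) Σ I_k cos(2πk/K),  b = (2/K) Σ I_k sin(2πk/K)

giving φ = atan2(b, a) (a pure delay yields positive phase) and
m = √(a²+b²)/c0. Instrument phase offset and modulation gain are removed by
measuring a reference slide of known lifetime (default 3.75 ns) at the same
frequency; calibrations are frequency-specific and applying one at a
mismatched frequency is an error.

Numerical conventions: dark pixels (c0 = 0) carry NaN phasors; a
numerically zero first harmonic on a lit pixel reports phase 0; strictly
negative phases and φ ≥ π/2 are unphysical for a single decay and map to
NaN lifetimes; over-modulated pixels (m > 1, possible under noise) clip to
τ = 0. All such pixels are counted and reported. The phase lifetime is the
default readout (better conditioned than the modulation lifetime near
ωτ ≈ 1.8, the sensor's anoxic operating point); the modulation lifetime is
retained as an independent consistency check — on noise-free
mono-exponential input the two agree to < 1e−6 ns, which the test suite
verifies across 1–1000 ns.

Lifetime images are noisy pixel-wise, so downstream conversion uses the
ROI-mean lifetime per image (arithmetic mean over finite pixels, exclusion
count reported).

## Stern–Volmer oxygen conversion

The RTDP sensor obeys [O₂] = (1/K_q)(τ₀/τ − 1). Oxygen is represented
internally as a fraction of the full calibration scale (1.0 = 100% O₂) and
converted to percent only at I/O boundaries; this choice is forced by the
two-point calibration algebra, K_q = (τ₀/τ_ox − 1)/[O₂]_ox, which yields
the dimensionless constants 2.58 (25 °C anchors 573/160 ns) and 2.65
(30 °C anchors 526/144 ns) only when [O₂] is fractional. Calibrations carry
a temperature label and converting a series labelled with a different
temperature raises an error — quenching is strongly temperature-dependent,
so calibration and measurement must share a temperature rather than be
corrected across one.

Noisy traces may transiently read below 0% or above 100%; they are kept
unclipped in stored traces so that window averages stay unbiased, and are
clipped only in rendered reports.

### Step-test statistics

For a programmed schedule (default 0/2/4/6/8/10/15/21/100% O₂, 4 h initial
hold, 3 h steps, 5-min sampling), the per-step **plateau** is the mean
measured concentration over the final hour of the step (truncated with a
warning on shorter steps), reported against the setpoint.

**Switching times** t_X (X = 85, 90, 95%) measure how fast the chamber
traverses a step's change: with entry value c_i (latest sample at or before
onset) and final value c_f, t_X is the first time the trace crosses
c_i + X·(c_f − c_i), located by linear interpolation between samples, and —
by default — does not fall back across the threshold for the remainder of
the step (robust to noise spikes; pure first-crossing is a flag away).
Thresholds are defined on the *change*, not the absolute level, so a null
step gives t_X = 0 (flagged degenerate) and t₉₀ is independent of step
amplitude for a first-order response. The final value c_f defaults to the
step's last measured sample: the last-hour plateau average deliberately
lags the asymptote of a first-order response (by ≈2% of the step for
T = 37 min and 3 h steps), which would bias t_X low by several minutes if
used as c_f, while the last sample sits within 0.8% of the asymptote.
Plateau-mean and setpoint variants remain available as options. With the
default response time constant, t₉₀ ≈ 83 min for every step, inside one
sample interval of the ideal T·ln 10 ≈ 85 min.

## Single-cell and population quantification

Inputs are paired integer label masks (0 = background) and fluorescence
frames. Cells with any pixel center within 0.5 μm of an image edge are
removed (segmentation artifacts at the field border); I_cell is the mean
fluorescence over the cell's pixels, exact on piecewise-constant input.
Coordinates are 0-based row-major pixels; physical distances use the pixel
size (default 0.065 μm).

Tracking is a greedy frame-to-frame assignment by descending
intersection-over-union with deterministic tie-breaks (IoU descending, then
source and target label ascending). A source cell may claim at most two
targets above the IoU threshold (default 0.2); two claims constitute a
division, unmatched targets found new lineages. Frame-local labels are
never assumed stable — identity lives only in the lineage forest.
Founders carry generation 0 and both daughters gain one generation per
recorded division. This tracker is a deliberately simple stand-in adequate
for well-separated monolayer masks; the simulator's ground-truth lineage
can be used in its place for analyses that must not depend on tracking
quality (on clean rendered masks the tracker recovers ≥95% of true links —
in practice 100% in the shipped tests).

Population metrics per frame: N_population (retained cell count) and
I_population (unweighted mean of I_cell — a per-cell, not per-pixel,
average). Growth rate μ is the OLS slope of ln N vs time in hours over a
stated window, reported with its standard error; replicate chambers are
summarised as mean ± SD. Intensity slopes ΔI_population/Δt are OLS slopes
over their windows (default windows 0–9 h, and 8:10–9:00 h after a switch);
the fold-change of two slopes is their ratio, rounded half-up to an integer
fold. No background subtraction is applied; the renderer can add a known
background so its effect on I_cell is measurable (it shifts I_cell by
exactly the background level).

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
exercised; all randomness flows through one seeded generator and identical
(parameters, seed) reproduce bit-identical datasets.

**Chip oxygen dynamics.** The chamber concentration relaxes toward each
setpoint as a lumped first-order system with time constant T = 37 min by
default. T stands in for PDMS diffusion (t ≈ d²/D with D_O₂ ≈ 1e−9 m²/s;
≈1.5 mm of PDMS gives ≈37 min) and is a free parameter, not a physics
claim; the default places t₉₀ = T·ln 10 ≈ 85 min inside the experimentally
reported 80–90 min band.

**FLIM forward model.** Per frame, τ = τ₀/(1 + K_q·[O₂](t)); each pixel's
K-step series is synthesized with the exact phase and modulation for that
τ, plus optional Gaussian or Poisson noise around a configurable DC level.
The noise-free composition simulate → phasor → lifetime → invert is exact
to 1e−6 over the whole 0–100% range (verified in the tests).

**Monolayer colonies.** Rod cells (width 1 μm, birth length 2.5 μm) grow
exponentially in a 50 × 30 μm chamber whose 1 μm height enforces a
monolayer. Interdivision times are lognormal with CV 0.2 (default); their
mean is set by numerically solving the Euler–Lotka renewal condition
2·E[e^(−μT_d)] = 1 so the *population* growth rate equals the requested μ
(a plain mean of ln 2/μ would overshoot by ~1.4% at CV 0.2). Division is
symmetric: length halves, GFP pools split in proportion to daughter length
(a binomial split was considered and rejected as an extra parameter with no
observable consequence at these copy numbers). Mechanics are simplified and
documented as non-physical: capsule–capsule overlap is relieved by pairwise
push-apart along the centroid axis (no torque), side walls confine, and the
two chamber ends are open — cells pushed past them exit into the supply
channels and are removed from the population but kept in the GFP ledger.
Simulations halt with a flag above 0.9 packing fraction. The internal time
step is 1 min; division times are exact (daughter birth times are not
quantized to the grid), so no growth-rate bias accumulates.

**GFP kinetics.** Each cell carries an immature (dark) and a mature
(fluorescent) pool. Expression fills the immature pool at a per-cell rate
that ramps linearly over 9 h from induction at t = 0 (full rate
850 a.u. h⁻¹) — a phenomenological account of slow induction chosen to
reproduce the near-linear rise of I_population seen in continuously
induced aerobic cultures; with instantaneous full expression, dilution at
rate μ would saturate I_population within ≈2/μ hours instead. Maturation
converts immature to mature at k_mat = 0.5 h⁻¹ (GFP-variant maturation
half-times of 1–2 h at 30 °C) and halts entirely below the o2_min
threshold. The literature bound for chromophore maturation is ≈0.1 ppm O₂;
mapping ppm onto the percent-of-full-scale axis would require a solubility
model the data cannot constrain, so o2_min is an abstract threshold on the
simulator's O₂ variable, default effectively zero (1e−4 of full scale).
Bleaching is available (default 0). The ledger identity
(immature + mature over living and exited cells) = (cumulative expression −
cumulative bleaching) holds to 1e−6 relative and is tested.

This structure yields the qualitative phenomenology the analysis must
detect: aerobic colonies show a near-linear I_population rise (R² > 0.95
over 0–9 h); anaerobic colonies stay exactly dark while immature GFP
accumulates; after a switch the backlog matures and I_population rises
several-fold faster than the aerobic reference; and faster-dividing
lineages dilute their backlog more, producing a negative rank correlation
between generation number and I_cell.

**Rendering.** Masks rasterize each rod's capsule footprint with its
frame-local label (later labels overwrite on the rare residual overlap, so
masks never overlap); fluorescence paints the cell's mature-GFP
concentration (a.u. μm⁻²) over the same footprint, optionally blurred with
a Gaussian PSF and degraded with background and noise. The field of view
extends 2 μm beyond the chamber so that wall-adjacent cells are not
spuriously caught by the border filter. Pixel sizes above 0.5 μm warn
(cells become unresolvable).

**Presets.** `aerobic` (21% O₂, 9 h, μ = 0.55 h⁻¹), `anaerobic_switch`
(0% O₂ for 8 h, then 21% filtered by the chip response; μ = 0.52 h⁻¹), and
`step_test` (the default 9-level schedule; no colonies). Both growth
presets default to five replicate chambers with seeds derived
deterministically from the master seed.

## Problem sizes and what the tests show

Shipped tests and the acceptance script run colonies of 2 seed cells for up
to 9 h at 5-min frames (≈200–280 cells at the end, ≈1 s per chamber), FLIM
stacks at 4×4–32×32 pixels, and renderings at 0.1 μm/px; these sizes make
the suite fast while leaving all statistics well-resolved. Passing tests
demonstrate internal consistency of estimators and simulators under the
stated models — mono-exponential decays, spatially uniform oxygen, ideal
segmentation masks, simplified rod mechanics. They do not validate
performance on real camera data with multi-exponential backgrounds,
segmentation errors, or crowded colony geometries, and the fluorescence
scale is self-consistent arbitrary units, not instrument counts.

## Known limitations

- No multi-exponential decay unmixing; the phasor reduction assumes a
  single lifetime per pixel.
- The O₂ field is spatially uniform per frame; no reaction–diffusion
  within the chamber and no consumption by cells.
- The tracker handles at most two descendants per frame transition;
  heavily under-sampled time-lapses (several divisions between frames)
  break lineage recovery.
- Rod mechanics ignore torque and elasticity; mask geometry, not forces,
  is the fidelity target.
- Growth rate is an input to the simulator, not an emergent property of
  nutrient or oxygen physiology.
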