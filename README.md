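# flimox

Analysis and simulation toolkit for oxygen-controlled microfluidic
single-cell cultivation experiments monitored by frequency-domain
fluorescence lifetime imaging (FD-FLIM).

Microfluidic monolayer chambers (50 × 30 × 1 μm, 1.5 pL) grown through
gas-permeable PDMS let the dissolved oxygen around bacterial micro-colonies
be switched between 0% and 100% of full scale while time-lapse microscopy
follows every cell. `flimox` covers the computational chain of such a
platform, for microbiologists and microfluidics developers who need the
sensing and the single-cell readout without the instrument:

1. **FD-FLIM lifetime estimation** (`flimox.fdflim`) — first-harmonic phasor
   (φ, m) of phase-stepped modulated image stacks, reference-slide
   calibration (τ_ref = 3.75 ns by default), and the two standard lifetime
   estimators τ_φ = tan(φ)/ω and τ_m = √(1/m² − 1)/ω at ω = 2π·550 kHz.
2. **Stern–Volmer oxygen sensing** (`flimox.oxygen`) — the lifetime of the
   ruthenium dye RTDP is quenched by oxygen as

   [O₂] = (1/K_q)(τ₀/τ − 1)

   A two-point calibration at 0% and 100% O₂ fixes (τ₀, K_q) per
   temperature; the module converts lifetime series to O₂ traces and
   characterises programmed step tests (per-step plateau averages,
   switching times t₈₅/t₉₀/t₉₅).
3. **Single-cell quantification** (`flimox.cellquant`) — border filtering of
   label masks, per-cell mean fluorescence I_cell, greedy-overlap lineage
   tracking with generation numbers, and population metrics: growth rate μ
   from log-linear fits of N_population, intensity slopes ΔI_population/Δt,
   fold-changes, and intensity-vs-generation statistics.
4. **Synthetic data with ground truth** (`flimox.synthesis`) — first-order
   chip O₂ dynamics, forward-model FLIM stacks, and an agent-based
   monolayer colony simulator with oxygen-gated GFP maturation (GFP is
   expressed anaerobically but only becomes fluorescent once oxygen allows
   chromophore maturation — a one-way intracellular O₂ indicator).

## Worked example

```python
>>> from flimox import fit_stern_volmer, lifetime_from_o2, o2_from_lifetime
>>> calib = fit_stern_volmer(526, 144, 1.0, temperature_c=30.0)
>>> round(calib.kq, 4)
2.6528
>>> round(lifetime_from_o2(0.21, calib), 1)   # ambient air, ns
337.8
>>> o2_from_lifetime(144.0, calib) * 100      # oxic anchor reads full scale
100.0
```

`fit_stern_volmer(526, 144, ...)` uses the 30 °C anchor lifetimes
(τ₀ = 526 ns anoxic, τ₁₀₀% = 144 ns oxic) and yields K_q ≈ 2.65; the same
call with the 25 °C pair (573, 160) gives 2.58. A lifetime of 337.8 ns
therefore reads as 21% O₂, and the oxic anchor inverts back to exactly
100%.

The full sensing chain on a simulated step test (setpoints
0→2→4→6→8→10→15→21→100% O₂, 4 h hold then 3 h steps, one frame per 5 min),
including FLIM stack synthesis, phasor estimation, reference correction and
Stern–Volmer inversion:

```text
$ flimox run --preset step_test --out out/
flimox run report — preset: step_test

  kq: 2.6528
  max_plateau_error_percent: 1.4260641754126766
  n_steps: 9
  t90_mean_min: 82.79614136017028
```

Each step's last-hour average sits within 1.5% absolute of its setpoint,
and the time to cross 90% of a step's change is ≈83 min for every step —
independent of step amplitude, as expected for diffusion-limited gas
exchange (first-order response, T = 37 min).

The biological presets simulate replicate micro-colonies and analyze them:

```text
$ flimox run --preset anaerobic_switch --seed 1 --out out/
flimox run report — preset: anaerobic_switch

  aerobic_reference_slope_au_per_h: 17.87
  fold_change: 6
  fold_change_ratio: 5.58
  intensity_slope_post_switch_au_per_h: 99.74
  mu_mean_per_h: 0.5209
  mu_sd_per_h: 0.0173
  n_chambers: 5
```

Five anaerobic chambers grow at μ = 0.52 h⁻¹; their fluorescence stays at
zero for 8 h, then surges several-fold faster than the aerobic reference
once the oxygen switch releases the accumulated immature-GFP backlog.

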