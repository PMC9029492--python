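# Methods

## Physical model

`magslp` evaluates the linear-response (Debye) expression for the power a
sinusoidal magnetic field dissipates in an ensemble of monodisperse,
spherical, single-domain superparamagnetic nanoparticles:

P_s = π μ₀ f H² χᵢ · [3 L(ξ)/ξ] · ωτ/(1+(ωτ)²) / ρ, reported per gram of
magnetic material (internal SI W/kg divided by 1000).

The three factors have distinct physical roles:

- **χᵢ = ε π μ₀ M_s² D³ / (18 k_B T)** — equilibrium initial susceptibility
  of the ensemble. Linear in the packing fraction ε, cubic in the core
  diameter.
- **3 L(ξ)/ξ** — saturation correction. The Debye result assumes a linear
  M(H); at finite amplitude the magnetization bends toward saturation along
  the Langevin curve, and the chord slope at ξ = π μ₀ M_s D³ H/(6 k_B T)
  replaces the initial slope. The factor is 1 at ξ → 0 and decays
  monotonically, which is what pushes the optimal diameter down as the field
  amplitude grows.
- **ωτ/(1+(ωτ)²)** — out-of-phase Lorentzian, bounded by 1/2 with equality
  exactly at ωτ = 1. The relaxation time τ is the Néel time alone when the
  particle is immobilized, or the harmonic combination 1/τ = 1/τ_N + 1/τ_B
  when it can rotate in the carrier.

The Brown time uses the hydrodynamic diameter D_h = D + 2d (core plus twice
the organic shell); the susceptibility, Langevin argument and Néel barrier
use the magnetic core D. This split is the entire effect of the coating in
the model: a thicker shell slows rotation, moves the Brown Lorentzian peak,
and (for high-anisotropy materials) leaves the Néel channel untouched.

### Assumptions

Monodisperse spherical particles; uniaxial anisotropy; no dipolar or van der
Waals interactions (the shell is assumed to keep particles apart, so ε enters
only through χᵢ, linearly, even at ε = 0.15); no polydispersity averaging; no
heat-transfer modelling — the output is the source term, not a temperature
rise. The carrier mass is excluded from the per-gram normalization: ρ is the
core material density.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| M_s | spontaneous magnetization | 425 (preset) | kA/m |
| K | anisotropy constant | 200 (preset) | kJ/m³ |
| ρ | core material density | 5.29 (preset) | g/cm³ |
| τ₀ | Néel attempt time | 10⁻⁹ | s |
| ε | packing fraction | 0.024 / 0.15 (presets) | — |
| η | carrier viscosity | 7×10⁻⁴ | Pa·s |
| d | shell thickness | 1.6 | nm |
| T | temperature | 300 | K |

The packaged presets describe cobalt-ferrite cores with a
cyclodextrin/polyacrylic-acid shell in saline: `table1` is the dilute
baseline (ε = 0.024, D swept 1–25 nm, H 10–50 kA/m, f 100–500 kHz),
`table5` the high-packing scenario (ε = 0.15, D 1–30 nm, H 5–100 kA/m,
f 50–1000 kHz). "Room temperature" is fixed at T = 300 K and exposed as a
config parameter; all user-facing units follow hyperthermia convention
(kA/m, kHz, nm, W/g) and convert to SI exactly once at the config/CLI
boundary.

## Numerical choices

- **Langevin evaluation.** coth ξ − 1/ξ cancels catastrophically at small
  argument; below ξ = 0.05 the Taylor series through ξ⁷ is used (relative
  error < 10⁻¹⁴ at the switch point, and the coth branch's cancellation
  error stays below ~3×10⁻¹³ there).
- **Néel overflow guard.** The exponent π K D³/(6 k_B T) is clamped at 700:
  exp(700) ≈ 10³⁰⁴ sits just under the double-precision ceiling, and a
  relaxation time beyond 10²⁹⁴ s is physically indistinguishable from
  infinite. Beyond the clamp τ_N is an "effectively infinite" sentinel
  (`inf`) whose reciprocal is zero in the harmonic combination, so the
  dispersed model degrades smoothly to Brown-only.
- **Diameter grid.** Sweeps default to a 0.01 nm step (2401 points over
  1–25 nm); each strict interior grid maximum is refined by golden-section
  search (`scipy.optimize.golden`) within its bracketing cells, which agrees
  with a brute-force 0.001 nm grid argmax to better than 0.005 nm. Peaks
  closer than 0.2 nm merge (float-noise twins), boundary maxima raise a
  warning rather than being reported — a maximum on the window edge means
  the sweep range clipped a peak.
- **Regime labels.** A peak (or diameter) is labelled `neel` when
  τ_N < τ_B/10, `brown` when τ_B < τ_N/10, else `mixed`. The factor-10
  threshold reflects the finite band (roughly 5.7–6.4 nm for the baseline
  preset) where both channels contribute comparably; the exact crossover
  (τ_N = τ_B, found by bisection on log τ_N/τ_B to ~10⁻⁹ relative precision
  in D, overflow-proof because the log of the Néel time is assembled from
  the exponent directly) sits at ≈5.95 nm for the baseline preset.
- **Determinism.** There is no randomness anywhere; identical inputs yield
  byte-identical CSV/JSON. Files carry full repr precision; only
  human-readable tables round (0.1 nm, 0.01 W/g).

## Design notes

- The dominant peak of a sweep is the global interior maximum; secondary
  maxima are reported separately. They appear only above ≈1.5 MHz for the
  baseline preset, where the fast Néel channel of sub-7 nm cores produces a
  narrow second maximum (near 6.0 nm at 2 MHz) alongside the broad Brown one
  (near 9.4 nm).
- Reference peak values for the baseline preset carry a 3% regression
  tolerance on P_sM and ±0.25 nm on D_M in the tests: two of the published
  500 kHz rows sit ~1.5% below the model's true maxima, consistent with a
  coarse diameter grid in the original tabulation, and the crossover is
  only quoted to ≈0.1 nm precision. The 30 kA/m, 500 kHz condition is
  printed inconsistently in the reference tables (25.66 vs 25.96 W/g); the
  tests target 25.96, which direct evaluation supports.
- Config files are flat key-value JSON/TOML with unknown keys rejected
  (fail-fast) so a misspelled parameter cannot silently fall back to a
  default.

## What the tests show — and don't

The test oracle is an independently written one-pass evaluation of the same
closed-form chain; agreement to 10⁻¹² relative error on random parameter
draws verifies the implementation, not the model. Reproduction of the
reference operating tables shows the package evaluates the published
equations faithfully. None of this validates the model against calorimetry:
real suspensions are polydisperse, particles may agglomerate or interact
dipolarly at high packing, shells can be incomplete, and the linear-response
form itself degrades at large ξ (hysteresis-type losses are outside its
scope). Measured SLP values routinely differ from this model's predictions
for those reasons.

## Limitations

Single diameter per run (no size-distribution averaging); no shape
anisotropy; no dipolar-interaction corrections at high ε; no bioheat or
temperature-rise modelling; no fitting of parameters to measured heating
curves; no clinical H·f safety-product constraints.
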