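# Methods

## Scope and model

`pykrm` computes the acoustic backscatter of swimbladdered pelagic fish with
the Kirchhoff Ray Mode (KRM) approximation and carries the downstream
analyses used in fisheries acoustics: swimbladder morphometry, orientation
(tilt) averaging of the backscattering cross-section, TS–length regression
(free slope and slope fixed to 20), and the relative frequency response used
as a multifrequency species fingerprint.

A specimen is a pair of station tables digitized from dorsal and lateral
projections: axial position `u` (mm, snout → tail), sagittal boundaries
`z_upper`/`z_lower` (mm, ventral → dorsal), and dorsal width `w` (mm), one
table for the fish body and one for the swimbladder. Profiles are resampled
by linear interpolation to a uniform working slice thickness (default 1 mm)
and the model sums, coherently over finite cylinders formed at station
midpoints:

* a **soft (gas-filled swimbladder) term** — per-cylinder amplitude
  proportional to the body→gas reflection coefficient and the water→body
  transmission product `(1 − R_wb²)`, with the published empirical low-`ka`
  corrections `A = ka/(ka + 0.083)` (amplitude) and
  `ψ_p = ka/(40 + ka) − 1.05` (phase), and phase set by twice the acoustic
  path (water, then body) to the cylinder's upper surface;
* a **fluid (fish body) term** — the front-interface echo minus the
  internally transmitted back-interface echo, the latter phase-advanced by
  `2 k_fb h` over the local body thickness `h` plus the empirical phase term
  `ψ_b = −(π/2)·k_fb(h/2)/(k_fb(h/2) + 0.4)`.

`σ_bs = |L|²` and `TS = 10 log10(σ_bs)` (dB re 1 m², equivalently
`10 log10(σ/4π)` with `σ = 4π σ_bs`). Off-broadside incidence rotates the
geometry by `θ − 90°` about its centroid before acoustic depths are taken,
with the projection factor `sin θ` in the per-cylinder amplitudes; incidence
is restricted to `θ ∈ [65°, 115°]`, outside which the ray approximation is
known to degrade. Tapered ends are represented by the shrinking
midpoint-radius cylinders of the digitized outline; no separate end factor
is applied, and the slice-convergence tests bound the residual
discretization effect.

Material defaults (sound speed m/s, density kg/m³): water 1509 / 1026, fish
flesh 1570 / 1070, swimbladder gas 345 / 1.24. These are the survey CTD
value and standard literature fish-tissue/gas properties; all are
constructor arguments of `MaterialSet`.

## Oracles

Two independent references validate the engine; neither shares code with it.

* **Fluid sphere, exact** (`oracles.sphere_modal_ts`): the classical
  partial-wave series with pressure/velocity continuity at the interface,
  truncated adaptively (at least `ka + 10` modes, relative tolerance 1e−6).
  Its rigid high-`ka` limit reproduces `σ_bs → a²/4` and its weak-contrast
  low-`ka` limit the Rayleigh closed form within 1%.
* **Sound-soft prolate spheroid, exact** (`spheroidal`): the
  spheroidal-wave-function series at broadside. `scipy.special`'s radial
  function of the second kind is numerically unusable for slender spheroids
  (`ξ0 → 1`) at moderate `c = k·(semifocal)` — Wronskian residuals reach
  10²–10³ exactly on the 15 × 2 mm benchmark — so the package computes
  eigenvalues and Legendre coefficients from the classical three-term
  recursion, `R1` from the spherical-Bessel expansion, and the outgoing
  radial function by inward ODE integration from Hankel asymptotics with
  Wronskian renormalization (which cancels the start-point truncation
  error). The series matches the soft-sphere modal series to < 0.01 dB in
  the near-sphere limit and the physical-optics integral to ~0.25 dB on an
  aspect-2 spheroid at high `ka`.

A physical-optics Kirchhoff–Helmholtz surface integral
(`oracles.kirchhoff_spheroid_spectrum`) is also provided; it is a
high-frequency approximation only and is labelled a synthetic stand-in.

**Known limitation.** Against the exact spheroidal series, the KRM spectrum
of the 15 × 2 mm gas spheroid reads 0.8–2.0 dB high across 38–200 kHz. The
excess traces to the published empirical soft-cylinder amplitude
`A·sqrt(ka + 1)`, which exceeds the exact two-dimensional soft-cylinder
equivalent by up to +1.7 dB for transverse `ka` between 0.2 and 5 — this
benchmark's regime. The corresponding benchmark test asserts tighter
published agreement bounds and fails; the failure is a property of the
model formulation, not of the discretization (slice-convergence tests pass
at the 0.05 dB level).

## Statistical post-processing

* **Tilt averaging**: Gaussian density in `θ` evaluated at the grid nodes
  (1° default), truncated to [65°, 115°] and renormalized; averaging is
  strictly linear in `σ_bs`, with the log transform applied afterwards. A
  vanishing standard deviation collapses onto the node nearest the mean.
  The default distribution set is 90±5, 90±10, 90±20, 101±12 and 88±13
  degrees (broadside = 90°; fish tilt t = 90° − θ, so 101° is a −11° mean
  tilt).
* **TS–length**: OLS of TS on `log10(TL cm)` via statsmodels; with the
  slope fixed to 20, `b20` is the mean offset `mean(TS − 20 log10 TL)` with
  its standard error from the offset sample. The intercept's standard error
  is reported (the residual standard error is also carried) and `r²` of the
  fixed-slope model is `1 − SSres/SStot`, which may fall below the free
  fit's.
* **Relative frequency response**: per fish `r(f) = σ(f)/σ(38 kHz)` at 38,
  70, 120, 200 kHz, computed for a tilt-averaged case and at broadside;
  cohort band is the mean ± 1.96 standard errors across fish.
* **Allometry**: OLS of `log10(area)` on `log10(TL)` with a two-sided
  t-test of the slope against 2 (isometry for an area). On numerically
  noiseless power-law data the test degenerates and is reported exactly.
* **Species comparison**: each measure is regressed on TL over the *pooled*
  cohorts and the residuals are compared with a Welch t-test. A pooled fit
  is essential — per-species residuals are zero-mean by construction and
  could carry no between-species signal.

## Synthetic specimens

Digitized radiographs of the two study species are not publicly deposited,
so `synthetic` generates stand-ins anchored to the published cohort means:
at the reference total length (15.4 cm / 14.4 cm) a zero-noise specimen
reproduces the mean bladder dimensions exactly (50 × 4 × 4.8 mm for the
horse mackerel, 30 × 5 × 7.1 mm for the chub mackerel); dimensions scale
linearly with TL. The horse-mackerel bladder uses a front-heavy Beta-shaped
taper ("pear"), the chub mackerel an unskewed spheroid; the bladder midline
is inclined by a draw from the `sbθ` distribution (means 10.9°/11.4°, sd
2.5°). Per-dimension multiplicative noise defaults to 4%, chosen from the
variance identity so that cohort regressions on TL land in the observed
r² ≥ 0.95 regime under uniform TL over the observed ranges (11.2–23.1 cm
and 11.1–33.7 cm); the true per-fish dispersion is unpublished and this
noise model is a stand-in. The generator reproduces cohort-level
regularities only: smooth outlines, no haemal-spine surface ripples, no
individual-specimen realism — so passing tests demonstrate pipeline
correctness and statistical recovery, not shape fidelity to real fish.

Exact prolate-spheroid geometries for benchmarking come from
`spheroid_fish`, including the 15 × 2 mm gas spheroid and the
equivalent-spheroid rule (semi-minor = `sqrt(sbh·sbw)/2`).

## Numerical choices

* Default grids: slice thickness 1 mm ("λ/10" refinement is one tenth of
  the water wavelength at 200 kHz, ≈ 0.75 mm); discrete survey frequencies
  38/70/120/200 kHz; tilt grid 65°–115° at 1°. Step sizes are package
  choices; the physical limits are part of the model.
* Resampling preserves both endpoints, so the realized spacing is
  `extent/(n−1)` with `n` minimizing the distance to the requested spacing;
  resampling is idempotent at fixed spacing.
* Deflated specimens (no inflated bladder) are representable, excluded from
  acoustics, and logged with a reason by the pipeline.
* Degenerate inputs raise typed errors (`DomainError`,
  `ValidityRangeError`, `DeflatedSpecimenError`, `InsufficientDataError`)
  rather than returning sentinels; zero acoustic contrast yields
  `σ_bs = 0` and `TS = −inf`.
* All randomness flows through `numpy.random.default_rng(seed)`; cohort
  generation draws independent child seeds so specimens are reproducible
  individually and jointly.

## Problem sizes

Test and acceptance runs use cohorts of 6–57 synthetic fish, 1 kHz
frequency steps over 38–200 kHz, 1° tilt steps, and 200-replicate recovery
studies; the exact spheroidal oracle is evaluated on a ~9 kHz grid and
compared to the 1 kHz KRM spectrum by linear interpolation in TS. These
sizes were chosen so every result recomputes from scratch in seconds to a
few minutes on one CPU.
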