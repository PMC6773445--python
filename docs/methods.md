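# Methods

This note records the model, the calibration choices, the numerical methods
and the known limitations of the package. Units are micrometres, hours,
Pascals and picolitres (1 pl = 10³ µm³) internally; viscosities are reported
in Pa·s (1 Pa·hr = 3600 Pa·s).

## 1. The shell model and its conservation laws

The otic vesicle is idealised as a thin spherical shell: a fluid lumen of
sphere-equivalent radius `R` wrapped by an epithelium of thickness `h ≪ R`.
Two bookkeeping identities anchor everything:

* **Fluid**: the lumen volume changes only by transepithelial flux,
  `dVl/dt = Sl·Ω`; for a sphere this collapses to `dR/dt = Ω`, so the flux
  (µm³ of water per µm² of epithelium per hour, i.e. µm/hr) is directly the
  radial growth rate.
* **Tissue**: the wall volume `Vt = 4πR²h` changes only by growth,
  `4π·d(R²h)/dt = j`, with `j` the tissue growth rate supplied as data
  (proliferation is measured input, not modelled). Both identities are
  verified to 1% along every simulated trajectory.

Stress in the wall follows the thin-shell Laplace law `σ = PR/(2h)`. On
long timescales the epithelium flows; the spherical Stokes relation is
`σ = 4µ·(1/R)(dR/dt)`. Equating the two gives the effective-viscosity
estimator

    µ = P·R² / (8·h·dR/dt),

which converts interval-averaged morphometry plus pressure into a material
property. With the measured interval means (116 Pa, 36 µm, 13 µm,
2.31×10⁻⁴ µm/s) it returns 6.26×10⁶ Pa·s, and 22.2×10⁶ Pa·s for the later
interval — the epithelium stiffens several-fold over half a day.

### Error propagation: two modes

`propagate_viscosity_error` defaults to the propagation formula that
reproduces the reported uncertainty table,

    δµ/µ = (1/8)·√[(δP/P)² + 2(δR/R)² + (δh/h)² + (δR′/R′)²],

whose 1/8 prefactor and coefficient 2 on the radius term are *not* the
textbook first-order result for µ ∝ PR²/(hR′) (that would carry no
prefactor and a coefficient 4, and gives uncertainties roughly eight times
larger). Both conventions are implemented (`mode="published"`,
`mode="standard"`); neither is silently "corrected", because which one the
original analysis intended cannot be determined from the published text,
and only the first reproduces the published table.

## 2. The feedback growth simulator

State: `(R, h, σ)` on a fixed time grid. The flux law is

    Ω = gate·(Ω₀(t) + κ·Δ) − K·min(P, P₀(t)),  floored at 0,

and the Maxwell wall evolves as `σ̇ = 4k·ε̇ − σ/τ` with `ε̇ = Ω/R`,
`τ = µ/k`, and `P = 2hσ/R` (clamped at zero: a slack or compressed wall
supports no lumenal pressure). The factor 4 is the spherical-shell (Stokes)
geometric factor, so the quasi-steady stress is `σ = 4µε̇` and the
quasi-static pressure closure is `P* = Ω₀/(K + R²/(8µh))` — the balance of
osmotic influx against viscous wall creep, exposed as
`quasi_static_pressure`.

Three deliberately non-obvious design choices:

* **The catch-up term κ·Δ.** Δ is the fractional lumen-volume deficit
  against the unperturbed (shadow) solution of the same parameters, which
  the simulator integrates internally when a puncture event is present.
  This term exists because pure Laplace/Maxwell wall mechanics carries no
  size reference: at equal wall stress a smaller vesicle with conserved
  tissue (hence a thicker wall) holds *more* pressure
  (P = 2hσ/R ∝ σ/R³ at fixed Vt), so after the brief elastic transient a
  punctured vesicle would grow *slower* than its control and bilateral
  symmetry would never be restored — we verified this across a wide range
  of elastic/viscous splits. The κ·Δ term is the linearized
  osmo-regulatory response of transport to a size deficit (the same law the
  data-analysis regression estimates), and it is gated by the same factor
  as Ω₀ so that ion-pump inhibition abolishes regeneration along with
  baseline growth.
* **The pressure-relief cap min(P, P₀).** During fast regeneration the
  rebuilding wall tension would otherwise overshoot the homeostatic
  pressure and choke the influx; physiologically the inner ear possesses a
  relief path (the endolymphatic duct) that bounds lumenal pressure near
  its stage-appropriate set point. The cap never binds on the wild-type
  trajectory, which tracks P₀ by construction.
* **Reseal restores tension.** Resealing re-establishes junctional
  integrity within ~5 minutes; the wall stress restarts on the homeostatic
  branch (σ = P₀R/2h) rather than re-accumulating from the recoiled state.
  Regeneration is then driven by κ·Δ, and the measured excess-flux-vs-
  deficit slope equals κ essentially exactly.

**Puncture events** release the stored elastic strain `σ/(4k)` (the wall
recoils, cells become columnar, `h` rises at conserved `R²h`) and then leak
lumen fluid until the requested total loss fraction (default 0.35) is
reached; leak beyond the recoil drives σ negative — compressed,
super-columnar cells — matching the observed squamous→columnar shape change.
While open, P = 0 and Ω = 0; the barrier closes after the reseal delay
(default 5 min, from the dye-exclusion observation).

### Wild-type calibration (`calibrate_wildtype`)

The defaults are chosen once, from the measured phenomenology, and define
the study conditions:

* `P₀(t)`: linear 100 → 300 Pa over the 18 h measurement window (the
  measured pressure range), starting at the 30 hpf-equivalent state
  R = 30.2 µm, h = 13.1 µm (sphere-equivalent values of the measured
  volumes at 30 hpf).
* `Ω̄ = 1 µm/hr`: the measured near-constant wild-type flux.
  `Ω₀(t) = Ω̄ + K·P₀(t)` — the osmotic pumping capacity rises with stage,
  which is the only way a constant flux can coexist with a tripling
  pressure under a linear flux law.
* `K = 0.015 µm/(hr·Pa)`: chosen so the implied catch-up gain
  `K·P₀(30)/0.35 ≈ 4.3` sits inside the measured κ ≈ 3–5 band and the
  post-reseal flux ratio `Ω₀/Ω̄ ≈ 2.5` sits inside the measured 2–5×.
* `κ = 4` µm/hr per unit fractional deficit: centre of the measured range.
* `k(t) = 5·σ_wt(t)` (stiffness_ratio = 5): ties elasticity to the working
  stress so the elastic recoil at puncture is the fixed strain 1/20 (≈14%
  of lumen volume — the visible cell-shape recoil), the balance of the
  30–40% loss being leak.
* `µ(t)` solves the stress-tracking condition
  `σ̇_wt = 4kΩ̄/R − σ_wt·k/µ` on the nominal trajectory, so the simulated
  pressure follows P₀ exactly; the resulting µ(30) ≈ 4×10⁶ Pa·s and its
  rise with stage mirror the effective-viscosity table. τ = µ/k comes out
  at ~2–3 h: elastic on the puncture timescale, fluid on the developmental
  one.

With these defaults the simulator reproduces: flux 1.00 ± 0.01 µm/hr,
pressure 100 → 300 Pa, 35% volume loss with tissue conserved at puncture,
peak regeneration flux ratio 2.4, monotone deficit decay to < 1%, and an
excess-flux/deficit slope of 4.0.

## 3. The synthetic-data generator

The generator emulates the published wild-type growth curves; its defaults
are the published values and are not tuning knobs.

* **Backbones.** Monotone cubic (PCHIP) interpolation through anchor
  points, so no overshoot between anchors. Cell number is anchored on
  `N(t) = 415·exp(g(t−16))` with `g = ln(1106/415)/29` (415 ± 26 cells at
  16 hpf to 1106 ± 52 at 45 hpf). Mean cell volume falls 0.55 → 0.34 pl by
  28 hpf and is constant after. The lumen sphere-equivalent radius rises
  rapidly over 16–21 hpf and then linearly at 1.134 µm/hr — the slope that
  puts `Vl(45) = 440 pl` and the surface-area break-even
  (`Rl′/Rl = N′/N`) at 33 hpf given the exponential N. Wall thickness
  thins 20 → 4 µm medially/laterally while the poles stay columnar;
  pressure is anchored 100 Pa @30, 166 @36, 300 @48 and reported as
  missing before 30 hpf (unmeasurable through a slack epithelium).
* **Derived fields are exact identities**: `Sl = 4πRl²`, `ψ = Sl/N`,
  `Vt = N·s`, `Vo = Vl + Vt` — so the bookkeeping invariants hold by
  construction in every noisy realisation.
* **Noise.** Additive Gaussian per primary quantity with SD linearly
  interpolated between the published per-stage SDs (the publication reports
  SDs only at selected stages); half the variance is a shared per-embryo
  random effect. Left/right sides of one (punctured) embryo share 80% of
  their noise variance — bilateral measurements of the same animal through
  the same segmentation pipeline are strongly correlated, and this is what
  makes recovery-of-symmetry detectable above measurement noise.
* **Puncture pairs.** The punctured side drops 35% of its lumen volume at
  the event (tissue conserved, wall thickens as 1/R²), stalls for the 5 min
  reseal window, then regenerates with excess radial flux `κ·Δ` (κ = 4
  µm/hr by default) until the deficit closes; asymmetry falls below 5% by
  45 hpf.
* **Drugs.** Ouabain/morpholino scale the lumen influx toward zero with
  dose (full dose arrests growth); cytochalasin softens the wall so the
  realized flux rises by `1 + 3·dose` (2–5× at meaningful doses).
* `Vt(45) = N·s = 376 pl` whereas the printed tissue-volume increment gives
  362.6 pl — the source quantities are themselves inconsistent at the 4%
  level; N and s are kept primary and Vt derives from them.

What the generator does *not* emulate: non-spherical geometry, regional
flux differences, left-right developmental asymmetry beyond the puncture,
per-cell heterogeneity, or autocorrelated segmentation errors. Tests passing
on these cohorts therefore validate the estimators' correctness and their
behaviour under realistic noise magnitudes, not robustness to systematic
imaging artefacts.

## 4. Kinetics estimators

* **Derivatives** come from local least-squares quadratics in a ±3 h window
  (7 points at hourly sampling; the window shrinks one-sidedly at the series
  ends, where estimates are correspondingly less reliable). On noise-free
  quadratic data the result is window-independent; noise-free product-rule
  decompositions close to 1% wherever the curves are smooth (windows that
  straddle an anchor-point curvature break can deviate by a few percent).
* **Flux** is `(dVl/dt)/Sl` with both pieces window-fitted; where a fitted
  surface area would be non-positive (possible at the strongly convex early
  samples) the raw datum replaces it.
* **Break-even time**: the first *sustained* crossing where the division
  term `ψ·dN/dt` exceeds the stretching term `N·dψ/dt`, refined by the root
  of the locally linearised difference over ±4 h — the two-point
  interpolated crossing alone has needlessly high variance under cohort
  noise.
* **Catch-up regression**: excess flux `Ω̃ − Ω` against fractional deficit
  `ΔVl/Vl`, with per-time points averaged across pairs *before* the OLS
  (statsmodels). Averaging first suppresses the errors-in-variables
  attenuation that noisy per-embryo deficits would cause (regressing
  per-embryo points attenuates κ̂ by ~40%); the published per-timepoint
  values are cohort means as well. The pool starts one full window after
  the puncture so no derivative window straddles the volume discontinuity.
  The fractional-deficit form is the default (rather than absolute volume
  difference) because only it makes κ ≈ 3–5 dimensionally consistent with
  a flux in µm/hr.

## 5. Probe physics

* **Plate.** The sensing membrane is a clamped square silicon plate
  (L = 850 µm, t = 5–50 µm, E = 163 GPa, ν = 0.27) under uniform load:
  `∇⁴w = P/D`, solved by sparse finite differences with the 13-point
  biharmonic stencil; w = 0 on the boundary and the zero-normal-slope
  condition enters by ghost-node reflection. The dimensionless centre
  coefficient `w_c·D/(PL⁴)` converges to the classical 1.26×10⁻³ (0.5% off
  at 129²). Bending stiffness uses the classical `D = Et³/(12(1−ν²))`;
  the half-thickness convention `2Ea³/(3(1−ν²))` with `a = t/2` is
  algebraically identical, so one implementation serves both. The displaced
  volume `∬w dx dy` at the worst case (5 µm membrane, 400 Pa) sits 2.1
  orders of magnitude below the 4.19×10⁶ µm³ volume of a 200 µm vesicle:
  the act of measuring does not meaningfully deflate the organ.
* **Dilution.** Endolymph (200 mM) diffuses out of the vesicle through the
  water-filled conical capillary (10.5° full angle, 1.8 mm, tip 5–15 µm,
  D = 1.61×10⁻⁹ m²/s). The vesicle is treated as a well-mixed compartment
  coupled to a quasi-1D variable-area diffusion domain along the cone, with
  C = 0 held at the tube's back end. The reduction is justified by
  timescales: internal mixing of a 100 µm sphere takes `a²/(π²D) ≈ 0.16 s`
  (the radial solver `solve_sphere_dirichlet`, validated against the
  classical eigenfunction series, bounds this), versus minutes for
  tube-limited efflux. Discretisation is conservative finite-volume with
  backward-Euler time stepping (unconditionally stable; solute balance
  closes to ~10⁻¹³). At the 0.5 min probe rise time the vesicle retains
  93/85/76% of its solute for 5/10/15 µm tips; the 15 µm tip reaches 10%
  at 5.8 min — the probe reads pressure long before the osmotic drive is
  perturbed, but readings beyond several minutes are suspect.
* **Plateau extraction.** Traces are segmented on the derivative of a
  box-smoothed trace with noise-adaptive thresholds (4× a robust MAD noise
  floor, at least 5% of the peak rate): baseline, rise, plateau (sustained
  quiet ≥ 10 s), withdrawal. Boundaries are refined on a minimally smoothed
  derivative when its SNR permits — for noise-free traces this recovers
  stage boundaries to within one sample. The vesicle pressure is the
  trimmed plateau mean minus the pre-insertion baseline mean.

## 6. Numerics, determinism, problem sizes

* The growth ODE uses an explicit fixed step (default dt = 0.02 h) with the
  stress relaxation handled semi-implicitly; a guard enforces
  `dt ≤ τ/20`. Halving dt moves the final radius by ~10⁻⁴ relative. The
  core ODE is deterministic; seeds govern only generator noise and
  bootstrap resampling.
* Default problem sizes: cohorts of 10 embryos at hourly sampling (the
  published design), 10 puncture pairs per regression, 100 replicates for
  parameter-recovery checks, 129² plate grids, 360-cell dilution grids at
  0.25 s steps. The full test suite runs in well under a minute.
* Identical seeds give byte-identical generator output and pipeline
  summaries.

## 7. Known limitations

* Spherical symmetry throughout: no regional stress variation from shape,
  no ellipsoidal corrections; regional mechanics enter only through the
  relative (ranked) stiffness/viscosity indicators.
* The κ·Δ catch-up term is a linearization with an explicit set point; the
  honest finding documented above is that the minimal closed-loop wall
  model cannot produce full size recovery without one.
* Parameter fitting treats schedules as scalars (or scalar multipliers);
  K is only identifiable with pressure data or a perturbation, and the
  code refuses to fit it otherwise rather than returning an unconstrained
  number.
* Osmotic chemistry is bookkeeping only (`M = Ω·c`); no explicit ion
  species, no concentration dynamics in the lumen.
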