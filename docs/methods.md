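# Methods

## Unit system

All internal quantities use μm, s, pN and K.  This system is chosen so
that stress needs no conversion: 1 pN/μm² = 1 Pa exactly, so moduli come
out in Pa, viscosities in Pa·s, and trap/spring stiffnesses are pN/μm.
Energy is pN·μm = 10⁻¹⁸ J; `constants.KB_PNUM` is the Boltzmann constant
in these units.  The single authoritative definitions of k_B
(1.380649 × 10⁻²³ J/K) and R (8.314462618 J mol⁻¹ K⁻¹) live in
`microrheo.constants`; file inputs may carry temperatures in °C and are
converted to kelvin on read.

## Trapped-bead microrheology (pmot)

**Model.**  A bead of radius *a* in a harmonic trap of stiffness κ inside
a *Jeffreys fluid*: a Maxwell element (plateau modulus G₀, relaxation
time τ_M) in parallel with a Newtonian solvent η_s.  The medium is
realised as one auxiliary overdamped degree of freedom *y* coupled to the
bead *x*:

    γ_s dx = [−κx − k_m(x − y)] dt + √(2 k_B T γ_s) dW₁
    γ_m dy = [ k_m(x − y)      ] dt + √(2 k_B T γ_m) dW₂

with k_m = 6πa G₀, γ_m = 6πa G₀ τ_M, γ_s = 6πa η_s.  Eliminating *y*
gives a generalized Langevin equation whose complex viscosity is exactly
η_s + G₀τ_M/(1 + iωτ_M), i.e. the bath's complex modulus is Maxwell +
solvent and its zero-shear viscosity is η₀ = η_s + G₀τ_M by construction.
Equipartition ⟨x²⟩ = k_B T/κ holds independently of the medium.

**Exact sampling.**  The pair (x, y) is a two-dimensional linear SDE, so
the generator uses the exact one-step Gaussian propagator — transition
matrix e^(−A·dt) with the noise covariance Σ − e^(−A·dt) Σ e^(−Aᵀ·dt),
where Σ solves the continuous Lyapunov equation — rather than an Euler
step.  The sampled chain then carries the continuous-time statistics
(equipartition, two-exponential position ACF) exactly at any step size.
This matters in practice: at the step sizes used here the fast solvent
eigenmode sits only a few steps wide, where an explicit Euler scheme
measurably distorts the fast relaxation and hence the apparent crossover
frequency.  Step-size guards (dt ≤ τ_M/50 and dt ≤ (6πη_s a/κ)/50)
are still enforced so that generated trajectories resolve the medium's
timescales.

**Inversion.**  The normalized position autocorrelation A(τ) (NPAF;
unbiased per-lag normalization, A(0) = 1 exactly) is fitted with a sum of
1–3 exponentials, Σᵢ aᵢ e^(−τ/θᵢ) with aᵢ > 0 and Σaᵢ = 1 (softmax/log
parameterisation).  The analytic one-sided Fourier transform
Â(ω) = Σᵢ aᵢθᵢ/(1 + iωθᵢ) then yields the moduli through the
trapped-bead generalized Stokes–Einstein relation

    G*(ω) = (κ / 6πa) · iωÂ(ω) / (1 − iωÂ(ω)).

Going through a fitted analytic form instead of a discrete Fourier
transform of the noisy ACF keeps the band edges free of truncation
artifacts.  The relation is validated by its closed-form limits: a purely
Newtonian bath (single-exponential NPAF with θ = 6πηa/κ) maps to
G* = iωη identically, and the Jeffreys bath maps back to Maxwell +
solvent.

**Fitting the NPAF is a correlated-noise problem.**  Empirical
autocorrelations of a correlated signal have errors that are both
heteroscedastic (Bartlett: var[Â(τ)] ≈ (τ_int/T)(1 − e^(−2τ/τ_int)),
τ_int = Σaᵢθᵢ, T the trajectory duration) and strongly correlated across
neighbouring lags.  Ordinary least squares with a naive information
criterion therefore overfits — spurious exponential components absorb
slow noise excursions and leak into the moduli as artificial elasticity.
The package fits each model order twice: an unweighted pass to estimate
τ_int, then a generalized-least-squares pass that standardises residuals
by the Bartlett profile and prewhitens them with an AR(1) factor of
correlation range τ_int.  Model order (1–3) is selected by BIC on the
whitened chi-square.  Fits use ~400 log-spaced lags up to `max_lag`
(≤ duration/10); moduli are reported on a log-spaced grid of 10
points/decade between 2π/(10·max_lag) and 2π/(10·dt), never outside it,
and modulus extraction requires at least 10⁴ trajectory samples.

**Derived quantities.**  The terminal relaxation time is 1/ω_c at the
lowest-frequency sign change of log G′ − log G″ (log-log interpolated);
absence of a crossing in band is a valid outcome, not an error, and when
multiple crossings exist the lowest-frequency one is terminal.  The
zero-shear viscosity is the mean of G″/ω over the lowest frequency decade
(equivalent to a 1/ω²-weighted fit of G″ = ηω, which equalises relative
errors), and requires that decade to be viscous-dominated.  `MaxwellModel`
fits both moduli jointly in log space with an optional η_s·ω solvent term
(bounded non-negative); an RMS log-residual above 0.15 flags the
single-mode Maxwell form as a poor description (e.g. power-law spectra).

**Statistical limits.**  With κ = 10 pN/μm, a = 0.1 μm and η₀ ≈ 3 Pa·s
the slowest system timescale is the trap relaxation 6πaη₀/κ ≈ 0.6 s, so a
120-s trajectory holds only ~190 independent correlation times.  The
Cramér–Rao bound for η₀ under these conditions is ≈15% relative (the GLS
estimator reaches ≈11–12%), while the crossover time is much better
conditioned (bound ≈2%, achieved ≈5%).  Recovery tests and tolerances in
the suite reflect these limits; single-trajectory η₀ values should be
read with that uncertainty in mind.

## Particle-tracking thermorheology (vpt)

Per temperature: the time-averaged MSD of each bead over all overlapping
pairs (FFT algorithm), ensemble-averaged with per-lag pair-count weights;
then a diffusivity fit; then Stokes–Einstein η = k_B T/(6πaD); finally an
Arrhenius fit of η(T).

* **Diffusivity fit.**  The default model is `msd = 4·D·lag + offset`,
  where the intercept absorbs the static localization-noise floor
  4σ_loc² (white camera noise adds a constant to the 2D MSD).  The
  diffusivity exponent α is measured on the offset-corrected curve over
  signal-dominated lags as a diagnostic.  The default fit window is the
  first 20 lag times: short lags carry nearly independent displacement
  statistics, whereas long-lag ensemble-MSD values are few-pair averages
  with strongly correlated errors that inflate the slope variance several
  fold without adding information.
* **Errors by track-level bootstrap** (50 resamples of particles with
  replacement, seeded): per-lag least-squares errors are meaningless here
  because MSD residuals are correlated across lags, while bead-to-bead
  scatter is the real uncertainty.
* **Diffusive gate.**  A temperature whose α ± σ_α interval lies entirely
  outside [0.9, 1.1] is flagged non-diffusive and excluded from Arrhenius
  fitting — sub-diffusive beads do not report a Newtonian viscosity.  The
  band is applied at one bootstrap standard error because at realistic
  ensemble sizes (10 beads × 600 frames) σ_α ≈ 0.06–0.13 and a hard cut
  would discard genuinely diffusive points.
* **Arrhenius forms.**  "linear": OLS of ln η on 1/T, E_A = slope·R.
  "exp+const": nonlinear least squares of η = η₀e^(E_A/RT) + c,
  initialised from the linear fit with c = 0; a negative fitted c is
  pinned to zero and flagged.  Both report E_A in RT units at the fixed
  reference 298.15 K (25 °C convention — never at the measurement
  temperature), with seeded 200-resample bootstrap errors over the
  (T, η) points.  Fits require ≥ 4 temperatures spanning ≥ 20 K.

## FRAP (frap)

Recovery is modelled as a single exponential with an immobile fraction on
the full-scale normalized trace (pre-bleach mean → 1, first post-bleach
point → 0):

    I(t) = I_∞ − (I_∞ − I₀) e^(−ln2 · t/τ_half),
    mobile fraction = (I_∞ − I₀)/(1 − I₀),
    τ_D = τ_half / R_bleach²   [s/μm²].

The half-time is defined through the fitted exponential (noise-robust);
the raw half-crossing is reported as a secondary diagnostic.  No
diffusion-equation (Soumpasis) profile fitting: the timescale of interest
is explicitly a bleach-radius-normalized half-time.  An optional
reference trace divides out acquisition photofading; the bleach radius is
user metadata, never estimated.

## Polymer observables (polymer)

* **Rouse modes** of the discrete free-end chain use the exactly
  orthogonal cosine basis X_p = (1/N) Σₙ rₙ cos(pπ(n+½)/N); the p = 0
  centre-of-mass mode is available separately.  For the ideal chain the
  mode relaxation times obey τ_p = ζ/(4k sin²(pπ/2N)).  Mode ACFs discard
  a fixed 10% burn-in and are fitted with a single exponential over
  C_p ∈ [0.05, 1]; non-decaying ACFs are flagged unresolved rather than
  mis-fitted.
* **Normalized relaxation modulus** G_norm(t) = (1/p_max) Σ_p C_p(t)² —
  Rouse stress relaxation is carried by squared mode correlators — with
  G_norm(0) = 1 exactly; absolute prefactors (c·k_BT/N) are deliberately
  dropped since only the normalized quantity is analysed, and p_max is a
  reported parameter.
* **Sticky chains.**  Stickers are beads attracted by Gaussian wells
  U = −ε k_B T exp(−|r − site|²/2r_well²).  Besides explicit fixed sites,
  the generator offers a cubic *lattice* of sites (`site_lattice`
  spacing, nearest-image evaluation) emulating binding partners
  distributed throughout a dense phase.  The lattice is the protocol used
  for retardation studies: binding then is a stationary, hop-limited
  process, whereas a single isolated well in 3D is escaped once and never
  revisited, which produces no steady retardation.  Retardation of the
  slowest mode is strongest for stickers on the chain ends, where mode 1
  has its largest amplitude (cosine weight 0.99 versus −0.16 for a
  mid-chain bead); the packaged sticky protocol (ε = 6 k_BT, r_well
  = 0.08 μm, lattice 0.4 μm, stickers on both ends of an N = 10 chain)
  slows mode 1 by a factor 1.5–2.3 across seeds.
* **Green–Kubo viscosity** η = (V/k_B T) ∫₀^∞ ⟨σ_xy(0)σ_xy(t)⟩ dt, with
  the ACF computed on the mean-removed series via overlapping pairs
  (burn-in 10%).  Default method fits A·e^(−t/τc) to the ACF over the
  first ~5 correlation times and uses the analytic integral A·τc; the
  alternative reads the first plateau of the cumulative trapezoid
  integral (running change < 1% per decade of time).  Both are reported.
  Series shorter than 100 correlation times are rejected as unconverged.
  For the synthetic OU stress, (V/k_BT)·A·τc is the exact answer and
  serves as the oracle.
* **Coexistence and critical point.**  Slab profiles are fitted with
  ρ(z) = ½(ρd+ρl) − ½(ρd−ρl)·tanh((|z−z_c|−z₀)/w); a density gap not
  significant at 2σ is flagged "no coexistence" (an exactly-fitted
  profile with undefined covariance is treated as zero-error).  The
  critical temperature comes from regressing (ρd−ρl)^(1/β) on T with the
  3D-Ising exponent β = 0.325 held fixed — the standard choice for
  coarse-grained condensate models — and ρ_c from the rectilinear
  diameter (ρd+ρl)/2 evaluated at T_c.  At least 4 subcritical
  temperatures with a monotonically closing gap are required.

## Synthetic-data generators: what they emulate and what they do not

Every generator is a pure function of its parameter object including the
seed (bit-reproducible); multi-particle and multi-temperature runs derive
independent sub-streams from the root seed via `SeedSequence` spawning.
Defaults encode the reference study conditions: trap stiffness 10 pN/μm
and bead radius 0.1 μm (a 200-nm tracer in a soft trap); tracer sweeps of
10 beads × 600 frames at 10 Hz across six temperatures spanning
11–55 °C with 0.02 μm localization noise; FRAP traces with a 9-s
half-time and 0.5-μm bleach radius at 2% intensity noise; viscosity and
Maxwell-time combinations of (3.3 Pa·s, 20 ms) and (23 Pa·s, 200 ms) for
the reference and long-chain baths and 37 Pa·s at 27 °C with a 26 RT
barrier for the strong-sticker variant.

The generators deliberately idealise: Brownian tracers are free (no
droplet confinement, no drift, no interactions); localization noise is
white and Gaussian (no motion blur or frame correlation); the FRAP model
has a single recovery timescale and no photofading; chains have no
excluded volume or hydrodynamic interactions; stress fluctuations are
Gaussian with a single correlation time; density profiles are symmetric
tanh shoulders with i.i.d. bin noise.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise models,
not robustness to instrument systematics (drift, aging, photobleaching
during acquisition, anisotropic traps) that real data may carry.

## Problem sizes and numerical choices

Recovery tests and the reproduction script use desk-scale inputs chosen
to sit well inside each estimator's resolvable regime: 120-s trapped-bead
trajectories at dt = 10⁻⁴ s (1.2 × 10⁶ samples; 600 s at 2 × 10⁻⁴ s for
the 200-ms bath), 3.6 × 10⁴ tracer positions per temperature sweep,
130-frame FRAP traces, 1.2 × 10⁵ saved chain frames, 4 × 10⁵-step stress
series, and 301-bin density profiles at five temperatures.  Tie-breaks
and degenerate inputs are handled explicitly: zero-variance trapped-bead
series, uniform density profiles, non-decaying mode ACFs and
elastic-dominated low-frequency bands raise or flag rather than return
numbers; exponential fits use multi-start log-parameterised least
squares; BIC falls back to the most parsimonious order when a model
represents the data exactly.

## Known limitations

* The pMOT inversion assumes the NPAF is a completely monotone (sum of
  decaying exponentials) function — appropriate for Maxwell-like media;
  power-law (critical-gel) rheology is detected as a poor Maxwell fit but
  not modelled.
* Zero-shear viscosity from a single trapped-bead trace is
  information-limited (see above); averaging over beads/droplets is the
  practical remedy and is how the ensemble generators are intended to be
  used.
* The sticky-chain model is a minimal single-chain caricature of sticker
  dynamics: wells are external and static, so it reproduces the
  qualitative retardation ordering, not transferable binding kinetics.
* No trap calibration, particle detection/linking, drift correction
  beyond per-track mean subtraction, or image-based FRAP.
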