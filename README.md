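# microrheo

Rheology and thermorheology of biomolecular condensates — trapped-bead
passive microrheology, temperature-resolved particle tracking, FRAP, and
coarse-grained polymer-simulation observables, with seeded synthetic-data
generators so that every analysis stage is verifiable by parameter
recovery.

Biomolecular condensates (phase-separated droplets of proteins and nucleic
acids, e.g. Arg/Gly-rich peptides with single-stranded DNA) behave as
viscoelastic network fluids.  Two quantities characterise their dynamics:

* the **terminal relaxation time** of the condensate-spanning network,
  measured as the inverse of the crossover frequency where the elastic
  modulus G′(ω) overtakes the viscous modulus G″(ω); and
* the **flow activation energy** E_A, the energy barrier for network
  reconfiguration, measured from the temperature dependence of viscosity,

  η(T) = η₀ · exp(E_A / RT),  so  ln η = ln η₀ + (E_A/R)(1/T),

  and conventionally reported in RT units at 25 °C.

The package is aimed at experimentalists analysing optical-tweezer and
video-tracking data from condensates, and at simulators computing the
matching observables from coarse-grained models.

## What is implemented

| module | contents |
| --- | --- |
| `microrheo.synthgen` | seeded generators: trapped bead in a Jeffreys fluid, Brownian tracers with Arrhenius η(T) and localization noise, single-exponential FRAP traces with an immobile fraction, ideal and sticky bead-spring chains, exponentially correlated (OU) shear stress, tanh-shaped slab density profiles with a 3D-Ising density gap |
| `microrheo.pmot` | position autocorrelation → complex modulus G*(ω) through the trapped-bead generalized Stokes–Einstein relation; crossover / terminal time; zero-shear viscosity (G″/ω limit); `MaxwellModel` fit |
| `microrheo.vpt` | ensemble MSD, `DiffusivityModel` (power-law and linear+offset), Stokes–Einstein viscosity, `ArrheniusModel` (linear and exp+constant forms), activation-energy unit conversion |
| `microrheo.frap` | full-scale normalization, `FRAPRecoveryModel` (half-time, mobile fraction), diffusion timescale τ_D = τ_half/R_bleach² |
| `microrheo.polymer` | Rouse-mode decomposition and relaxation times, normalized relaxation modulus, Green–Kubo viscosity from stress autocorrelation, `TanhProfileModel` coexistence fits, `CriticalPointModel` (T_c, ρ_c) |
| `microrheo.io`, `microrheo.cli` | CSV/XYZ readers and writers with JSON metadata sidecars; a `microrheo` executable with `simulate\|pmot\|vpt\|arrhenius\|frap\|polymer` subcommands |

All fitting operations are scikit-learn-style estimators (`fit`,
fitted `*_` attributes, `get_params`/`set_params`) and compose with
sklearn tooling; the module-level functions are thin wrappers over them.

## Worked example

```python
import microrheo as mr

# trapped-bead microrheology of a condensate-like Maxwell fluid
bath = mr.JeffreysBathParams(kappa=10.0, a=0.1, T=300.15,
                             eta_s=0.05, G0=162.5, tau_M=0.02,
                             dt=1e-4, n_steps=1_200_000, seed=0)
traj = mr.gen_trapped_bead(bath)
npaf = mr.compute_npaf(traj, max_lag=5.0)
spec = mr.npaf_to_modulus(npaf, traj.kappa, traj.a)

eta0 = mr.zero_shear_viscosity(spec)
cross = mr.find_crossover(spec)
maxwell = mr.fit_maxwell(spec)
print(f"zero-shear viscosity: {eta0.eta:.2f} Pa s")
print(f"terminal relaxation time: {cross.tau_terminal*1e3:.1f} ms")
print(f"Maxwell fit: G0 = {maxwell.G0_:.0f} Pa, tau = {maxwell.tau_*1e3:.1f} ms")

# thermorheology: flow activation energy from particle tracking
sweep = mr.VPTSimParams(E_A=17 * mr.R_GAS * 298.15, eta_ref=3.3,
                        T_ref=300.15, seed=0)
points, _ = mr.viscosity_vs_temperature(mr.gen_vpt_tracks(sweep))
arr = mr.arrhenius_fit(points)
print(f"flow activation energy: {arr.E_A_RT_:.1f} +/- {arr.E_A_RT_err_:.1f} RT"
      f"  ({arr.E_A_kJmol_:.1f} kJ/mol)")
```

prints

```
zero-shear viscosity: 3.49 Pa s
terminal relaxation time: 19.6 ms
Maxwell fit: G0 = 170 Pa, tau = 20.3 ms
flow activation energy: 17.1 +/- 0.5 RT  (42.3 kJ/mol)
```

The simulated bath has zero-shear viscosity η₀ = η_s + G₀τ_M = 3.30 Pa·s
and Maxwell time 20 ms; the pipeline recovers both from the 120-second
bead trajectory alone (the ~5% deviations are the finite-trajectory
sampling noise).  The track sweep was generated with a 17 RT barrier and
3.3 Pa·s at 27 °C; the MSD → Stokes–Einstein → Arrhenius chain returns
17.1 ± 0.5 RT ≈ 42 kJ/mol.

The same analyses run from the command line on delimited-text inputs:

```sh
microrheo simulate  --config sim.json --out data/ --seed 1
microrheo pmot      --config pmot.json --out results/
```

Each run writes its result tables plus a `report.json` with the package
version, seeds and SHA-256 checksums of all inputs.

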