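"""Seeded generators for every input class the analysis modules consume.

Each generator is a pure function of its parameter object (including the
seed), so output is bit-reproducible.  Sub-streams for independent particles
or temperatures are derived from the root seed with
:class:`numpy.random.SeedSequence` spawning, which keeps runs reproducible
while avoiding stream overlap.

Physics implemented here:

* A bead held in a harmonic optical trap inside a *Jeffreys fluid* — a
  Maxwell element (spring ``G0`` + dashpot, relaxation time ``tau_M``) in
  parallel with a Newtonian solvent ``eta_s``.  The medium is realised as an
  auxiliary overdamped degree of freedom coupled to the bead, which is the
  exact Markovian embedding of the single-exponential memory kernel; the
  zero-shear viscosity is ``eta_s + G0*tau_M`` by construction.
* Brownian tracer beads in a Newtonian fluid whose viscosity follows an
  Arrhenius law across a temperature grid, with additive white localization
  noise (camera model).
* Single-exponential FRAP recovery with an immobile fraction.
* Ideal (Rouse) and "sticky" bead-spring chains, the stickers being fixed
  Gaussian potential wells acting on chosen beads.
* A stationary Ornstein–Uhlenbeck shear-stress series whose autocorrelation
  integral is known analytically (the Green–Kubo oracle).
* tanh-shaped slab density profiles whose coexistence densities close at a
  prescribed critical temperature with a 3D-Ising exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from .constants import KB_PNUM
from .datatypes import (
    ChainTrajectory,
    DensityProfile,
    FRAPTrace,
    ParticleTrackSet,
    StressSeries,
    TrapTrajectory,
)

__all__ = [
    "JeffreysBathParams",
    "VPTSimParams",
    "FRAPSimParams",
    "ChainSimParams",
    "OUStressParams",
    "SlabProfileParams",
    "gen_trapped_bead",
    "gen_vpt_tracks",
    "gen_frap_trace",
    "gen_chain_trajectory",
    "gen_ou_stress",
    "gen_slab_profiles",
    "arrhenius_viscosity",
]


def _require_positive(obj, names) -> None:
    for name in names:
        value = getattr(obj, name)
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{type(obj).__name__}: {name} must be > 0")


# --------------------------------------------------------------------------
# trapped bead in a Jeffreys bath
# --------------------------------------------------------------------------

@dataclass
class JeffreysBathParams:
    """Parameters of the trapped-bead (pMOT) generator.

    Defaults for ``kappa`` and ``a`` correspond to a soft trap holding a
    200-nm tracer bead; the Maxwell parameters are free.
    """

    kappa: float = 10.0  # trap stiffness, pN/μm
    a: float = 0.1  # bead radius, μm
    T: float = 300.15  # K
    eta_s: float = 0.05  # solvent viscosity, Pa·s
    G0: float = 165.0  # Maxwell-arm modulus, Pa
    tau_M: float = 0.02  # Maxwell relaxation time, s
    dt: float = 1e-4  # integration step, s
    n_steps: int = 1_000_000
    seed: int = 0

    @property
    def eta0(self) -> float:
        """Zero-shear viscosity of the medium, Pa·s."""
        return self.eta_s + self.G0 * self.tau_M


def gen_trapped_bead(params: JeffreysBathParams) -> TrapTrajectory:
    """Simulate a trapped bead in a Jeffreys fluid.

    The coupled overdamped pair is

    .. code-block:: text

        γ_s dx = [-κ x - k_m (x - y)] dt + sqrt(2 k_B T γ_s) dW1
        γ_m dy = [ k_m (x - y)      ] dt + sqrt(2 k_B T γ_m) dW2

    with ``k_m = 6π a G0`` (pN/μm), ``γ_m = 6π a G0 τ_M`` and
    ``γ_s = 6π a η_s`` (pN·s/μm).  Eliminating ``y`` gives a generalized
    Langevin equation whose complex modulus is exactly Maxwell + solvent,
    so the bead statistics embody the target medium.

    Because the pair is a linear (2D Ornstein–Uhlenbeck) SDE it is
    integrated by its *exact* one-step Gaussian propagator — transition
    matrix ``expm(−A dt)`` with the matching noise covariance — rather
    than an Euler approximation: the sampled chain then carries the
    continuous-time statistics (equipartition, two-exponential position
    ACF) exactly at any step size, where explicit Euler distorts the fast
    solvent mode already at the permitted ``dt``.  The step-size guards
    below still reject grids too coarse to resolve the medium's
    timescales.
    """
    _require_positive(
        params, ("kappa", "a", "T", "eta_s", "G0", "tau_M", "dt", "n_steps")
    )
    six_pi_a = 6.0 * math.pi * params.a
    k_m = six_pi_a * params.G0  # pN/μm
    gamma_m = six_pi_a * params.G0 * params.tau_M  # pN·s/μm
    gamma_s = six_pi_a * params.eta_s  # pN·s/μm

    tau_solvent = gamma_s / params.kappa
    if params.dt > params.tau_M / 50.0:
        raise ValueError(
            f"dt={params.dt} too coarse: must be <= tau_M/50 = {params.tau_M / 50.0:g}"
        )
    if params.dt > tau_solvent / 50.0:
        raise ValueError(
            f"dt={params.dt} too coarse: must be <= (6π η_s a / κ)/50 = "
            f"{tau_solvent / 50.0:g}"
        )

    kBT = KB_PNUM * params.T  # pN·μm
    # drift matrix A of dz = -A z dt + noise, z = (x, y)
    A = np.array(
        [
            [(params.kappa + k_m) / gamma_s, -k_m / gamma_s],
            [-k_m / gamma_m, k_m / gamma_m],
        ]
    )
    B = np.diag([2.0 * kBT / gamma_s, 2.0 * kBT / gamma_m])
    dt = params.dt
    # exact discretisation: z_{n+1} = M z_n + η, M = expm(-A dt),
    # cov(η) = Σ − M Σ Mᵀ with Σ the stationary covariance (Lyapunov)
    Sigma = linalg.solve_continuous_lyapunov(A, B)  # A Σ + Σ Aᵀ = B
    M = linalg.expm(-A * dt)
    Q = Sigma - M @ Sigma @ M.T
    L = linalg.cholesky((Q + Q.T) / 2.0, lower=True)

    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    s = rng.standard_normal((params.n_steps, 2)) @ L.T  # step noise
    z0 = linalg.cholesky((Sigma + Sigma.T) / 2.0, lower=True) @ rng.standard_normal(2)

    # diagonalize M; γ-similarity makes the eigenvalues real for any
    # positive parameter set
    lam, P = linalg.eig(M)
    lam = lam.real
    P = P.real
    Pinv = linalg.inv(P)
    u = s @ Pinv.T  # eigen-channel noise (correlated across channels)
    w0 = Pinv @ z0
    # w_n = λ w_{n-1} + u_{n-1}; run each channel as an AR(1) filter
    w = np.empty((params.n_steps, 2))
    for i in range(2):
        zi = signal.lfiltic([1.0], [1.0, -lam[i]], [w0[i]])
        w[:, i], _ = signal.lfilter([1.0], [1.0, -lam[i]], u[:, i], zi=zi)
    x = w @ P[0, :]  # bead coordinate only

    t = np.arange(params.n_steps, dtype=float) * dt
    return TrapTrajectory(t=t, x=x, kappa=params.kappa, a=params.a, T=params.T)


def jeffreys_position_acf(params: JeffreysBathParams, lags: np.ndarray) -> np.ndarray:
    """Closed-form stationary position ACF of the Jeffreys trapped bead.

    Computed from the continuous-time 2×2 Ornstein–Uhlenbeck system via the
    Lyapunov equation and matrix exponentials — independent of the
    simulation path, usable as an oracle.
    """
    six_pi_a = 6.0 * math.pi * params.a
    k_m = six_pi_a * params.G0
    gamma_m = six_pi_a * params.G0 * params.tau_M
    gamma_s = six_pi_a * params.eta_s
    kBT = KB_PNUM * params.T
    A = np.array(
        [
            [(params.kappa + k_m) / gamma_s, -k_m / gamma_s],
            [-k_m / gamma_m, k_m / gamma_m],
        ]
    )
    B = np.diag([2.0 * kBT / gamma_s, 2.0 * kBT / gamma_m])
    Sigma = linalg.solve_continuous_lyapunov(A, B)  # A Σ + Σ Aᵀ = B
    out = np.empty(len(lags))
    for i, tau in enumerate(np.asarray(lags, dtype=float)):
        C = linalg.expm(-A * tau) @ Sigma
        out[i] = C[0, 0] / Sigma[0, 0]
    return out


# --------------------------------------------------------------------------
# video particle tracking across temperature
# --------------------------------------------------------------------------

@dataclass
class VPTSimParams:
    """Parameters of the temperature-resolved particle-tracking generator."""

    E_A: float = 42.14e3  # activation energy, J/mol
    eta_ref: float = 3.3  # viscosity at T_ref, Pa·s
    T_ref: float = 300.15  # K
    offset_c: float = 0.0  # additive viscosity constant, Pa·s
    temperatures: tuple = (284.15, 293.15, 300.15, 311.15, 320.15, 328.15)
    a: float = 0.1  # bead radius, μm
    dt_frame: float = 0.1  # s
    n_frames: int = 600
    n_particles: int = 10
    sigma_loc: float = 0.02  # localization noise std, μm
    seed: int = 0


def arrhenius_viscosity(
    T, E_A: float, eta_ref: float, T_ref: float, offset_c: float = 0.0
):
    """η(T) = η_ref · exp[(E_A/R)(1/T − 1/T_ref)] + c."""
    from .constants import R_GAS

    T = np.asarray(T, dtype=float)
    return eta_ref * np.exp((E_A / R_GAS) * (1.0 / T - 1.0 / T_ref)) + offset_c


def gen_vpt_tracks(params: VPTSimParams) -> list[ParticleTrackSet]:
    """Generate Brownian tracer tracks, one :class:`ParticleTrackSet` per
    temperature.

    Per-axis step std is ``sqrt(2 D(T) dt)`` with the Stokes–Einstein
    ``D(T) = k_B T / (6π a η(T))``; i.i.d. Gaussian localization noise of
    std ``sigma_loc`` is added to every stored coordinate.
    """
    import pandas as pd

    _require_positive(
        params, ("eta_ref", "T_ref", "a", "dt_frame", "n_frames", "n_particles")
    )
    if params.sigma_loc < 0:
        raise ValueError("VPTSimParams: sigma_loc must be >= 0")
    if len(params.temperatures) == 0:
        raise ValueError("VPTSimParams: temperatures must be non-empty")
    etas = arrhenius_viscosity(
        params.temperatures, params.E_A, params.eta_ref, params.T_ref, params.offset_c
    )
    if np.any(etas <= 0):
        bad = np.asarray(params.temperatures)[etas <= 0]
        raise ValueError(f"viscosity non-positive at T = {bad} K")

    root = np.random.SeedSequence(params.seed)
    children = root.spawn(len(params.temperatures))
    out = []
    t_grid = np.arange(params.n_frames, dtype=float) * params.dt_frame
    for Ti, eta, child in zip(params.temperatures, etas, children):
        # D in μm²/s: k_B T [pN μm] / (6π a[μm] η[Pa·s]) — pN/(μm·Pa·s) = μm²/s
        D = KB_PNUM * Ti / (6.0 * math.pi * params.a * eta)
        step_std = math.sqrt(2.0 * D * params.dt_frame)
        rng = np.random.default_rng(child)
        frames = []
        for pid in range(params.n_particles):
            steps = rng.standard_normal((params.n_frames - 1, 2)) * step_std
            pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
            pos = pos + rng.standard_normal(pos.shape) * params.sigma_loc
            frames.append(
                pd.DataFrame(
                    {
                        "particle_id": pid,
                        "t": t_grid,
                        "x": pos[:, 0],
                        "y": pos[:, 1],
                    }
                )
            )
        tracks = pd.concat(frames, ignore_index=True)
        out.append(
            ParticleTrackSet(
                tracks=tracks, T=float(Ti), a=params.a, dt_frame=params.dt_frame
            )
        )
    return out


# --------------------------------------------------------------------------
# FRAP
# --------------------------------------------------------------------------

@dataclass
class FRAPSimParams:
    """Parameters of the FRAP-trace generator (single-exponential recovery
    with an immobile fraction)."""

    tau_half: float = 9.0  # recovery half-time, s
    mobile_frac: float = 1.0  # in [0, 1]
    bleach_depth: float = 0.6  # in (0, 1]
    R_bleach: float = 0.5  # μm
    dt: float = 0.5  # s
    n_pre: int = 10
    n_post: int = 120
    noise_sd: float = 0.0
    seed: int = 0


def gen_frap_trace(params: FRAPSimParams) -> FRAPTrace:
    """Generate a FRAP trace: pre-bleach plateau at 1, instantaneous bleach
    to ``1 − bleach_depth``, exponential recovery toward the mobile plateau
    ``1 − bleach_depth (1 − mobile_frac)``, additive Gaussian noise."""
    _require_positive(params, ("tau_half", "R_bleach", "dt", "n_pre", "n_post"))
    if not 0.0 <= params.mobile_frac <= 1.0:
        raise ValueError("FRAPSimParams: mobile_frac must lie in [0, 1]")
    if not 0.0 < params.bleach_depth <= 1.0:
        raise ValueError("FRAPSimParams: bleach_depth must lie in (0, 1]")
    if params.n_pre < 3:
        raise ValueError("FRAPSimParams: n_pre must be >= 3")
    if params.noise_sd < 0:
        raise ValueError("FRAPSimParams: noise_sd must be >= 0")

    I0 = 1.0 - params.bleach_depth
    I_inf = 1.0 - params.bleach_depth * (1.0 - params.mobile_frac)
    t = np.arange(params.n_pre + params.n_post, dtype=float) * params.dt
    t_bleach = t[params.n_pre]
    I = np.ones_like(t)
    post = t[params.n_pre:] - t_bleach
    I[params.n_pre:] = I_inf - (I_inf - I0) * np.exp(
        -math.log(2.0) * post / params.tau_half
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
        I = I + rng.standard_normal(I.shape) * params.noise_sd
    return FRAPTrace(t=t, I=I, i_bleach=params.n_pre, R_bleach=params.R_bleach)


# --------------------------------------------------------------------------
# bead-spring chains
# --------------------------------------------------------------------------

@dataclass
class ChainSimParams:
    """Parameters of the overdamped bead-spring chain generator.

    ``epsilon = 0`` gives an ideal (phantom) Rouse chain; positive
    ``epsilon`` adds Gaussian sticker wells of depth ``epsilon·k_B·T`` and
    width ``r_well`` acting on the listed beads — a minimal realisation of
    sticker-retarded ("sticky Rouse") dynamics.

    Sites are either explicit fixed coordinates (``sticker_sites``, one
    per sticker bead) or, when ``site_lattice > 0``, a cubic lattice of
    binding sites with that spacing felt by every sticker bead (evaluated
    through the nearest lattice image).  The lattice emulates binding
    partners distributed throughout a dense phase: a bead that escapes
    one well finds another nearby, so binding is a stationary
    hop-limited process rather than a one-off transient — a single
    isolated well in 3D is escaped once and never revisited, which
    produces no steady retardation.
    """

    N: int = 10
    b: float = 0.0  # bond rest length, μm (0 = ideal Gaussian springs)
    k_spring: float = 1.0  # pN/μm
    zeta: float = 1.0  # per-bead friction, pN·s/μm
    T: float = 300.0  # K
    dt: float = 0.02  # s
    n_steps: int = 200_000
    save_stride: int = 1
    sticker_indices: tuple = ()
    sticker_sites: tuple = ()  # one 3-vector (μm) per sticker index
    site_lattice: float = 0.0  # cubic site spacing, μm (0 = explicit sites)
    epsilon: float = 0.0  # well depth, units of k_B T
    r_well: float = 0.1  # well width, μm
    seed: int = 0


def gen_chain_trajectory(params: ChainSimParams) -> ChainTrajectory:
    """Integrate an overdamped Langevin bead-spring chain.

    Forces: harmonic nearest-neighbour springs (rest length ``b``, zero for
    ideal Gaussian springs) and optional attractive Gaussian wells
    ``U = −ε k_B T exp(−|r − site|²/(2 r_well²))`` pinned at fixed sites.
    """
    _require_positive(params, ("N", "k_spring", "zeta", "T", "dt", "n_steps"))
    if params.dt > params.zeta / (10.0 * params.k_spring):
        raise ValueError(
            f"dt={params.dt} unstable: must be <= zeta/(10 k_spring) = "
            f"{params.zeta / (10.0 * params.k_spring):g}"
        )
    use_lattice = params.site_lattice > 0
    if not use_lattice and len(params.sticker_indices) != len(params.sticker_sites):
        raise ValueError("sticker_indices and sticker_sites must pair up")

    N = int(params.N)
    kBT = KB_PNUM * params.T  # pN·μm
    dt = params.dt
    mobility = dt / params.zeta
    noise_std = math.sqrt(2.0 * kBT * dt / params.zeta)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))

    # start from a Gaussian coil: bond vectors with equilibrium variance
    if N > 1:
        bond_var = kBT / params.k_spring
        bonds = rng.standard_normal((N - 1, 3)) * math.sqrt(bond_var)
        if params.b > 0:
            bonds += params.b / math.sqrt(3.0)
        r = np.vstack([np.zeros(3), np.cumsum(bonds, axis=0)])
    else:
        r = np.zeros((1, 3))

    sticker_idx = np.asarray(params.sticker_indices, dtype=int)
    if sticker_idx.size and (np.any(sticker_idx < 0) or np.any(sticker_idx >= N)):
        raise ValueError("sticker_indices out of range")
    if sticker_idx.size and not use_lattice:
        sites = np.asarray(params.sticker_sites, dtype=float).reshape(-1, 3)
        r[sticker_idx] = sites  # start bound so the slow mode is sampled
    else:
        sites = np.zeros((0, 3))

    n_saved = params.n_steps // params.save_stride
    coords = np.empty((n_saved, N, 3))
    two_rw2 = 2.0 * params.r_well**2
    eps_kBT = params.epsilon * kBT
    k = params.k_spring
    b0 = params.b
    saved = 0
    for step in range(params.n_steps):
        f = np.zeros_like(r)
        if N > 1:
            d = r[1:] - r[:-1]
            if b0 > 0:
                dist = np.linalg.norm(d, axis=1, keepdims=True)
                fb = k * (dist - b0) * d / np.maximum(dist, 1e-12)
            else:
                fb = k * d
            f[:-1] += fb
            f[1:] -= fb
        if sticker_idx.size and eps_kBT > 0:
            rs = r[sticker_idx]
            if use_lattice:
                L = params.site_lattice
                dr = rs - L * np.round(rs / L)  # nearest lattice site
            else:
                dr = rs - sites
            w = np.exp(-np.sum(dr**2, axis=1, keepdims=True) / two_rw2)
            f[sticker_idx] += -eps_kBT * dr / (params.r_well**2) * w
        r = r + mobility * f + noise_std * rng.standard_normal(r.shape)
        if (step + 1) % params.save_stride == 0:
            coords[saved] = r
            saved += 1
    return ChainTrajectory(
        coords=coords[:saved],
        dt=dt * params.save_stride,
        zeta=params.zeta,
        k_spring=params.k_spring,
        T=params.T,
    )


# --------------------------------------------------------------------------
# OU stress series
# --------------------------------------------------------------------------

@dataclass
class OUStressParams:
    """Parameters of the exponentially correlated (OU) shear-stress
    generator; its Green–Kubo integral is ``(V / k_B T) · A · tau_c``
    analytically."""

    amplitude_A: float = 100.0  # stress ACF amplitude ⟨σ²⟩, Pa²
    tau_c: float = 0.01  # correlation time, s
    V: float = 1e-22  # box volume, m³
    T: float = 300.0  # K
    dt: float = 1e-3  # s
    n_steps: int = 100_000
    seed: int = 0


def gen_ou_stress(params: OUStressParams) -> StressSeries:
    """Exact-discretisation stationary OU series:
    ``σ_{t+dt} = σ_t e^(−dt/τc) + sqrt(A (1 − e^(−2dt/τc))) ξ``."""
    _require_positive(params, ("amplitude_A", "tau_c", "V", "T", "dt", "n_steps"))
    if params.dt >= params.tau_c:
        raise ValueError(
            f"dt={params.dt} must be < tau_c={params.tau_c} to resolve the "
            "stress correlation"
        )
    rho = math.exp(-params.dt / params.tau_c)
    innov_std = math.sqrt(params.amplitude_A * (1.0 - rho * rho))
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    xi = rng.standard_normal(params.n_steps) * innov_std
    xi[0] = rng.standard_normal() * math.sqrt(params.amplitude_A)  # stationary start
    sigma, _ = signal.lfilter([1.0], [1.0, -rho], xi, zi=np.zeros(1))
    t = np.arange(params.n_steps, dtype=float) * params.dt
    return StressSeries(t=t, sigma_xy=sigma, V=params.V, T=params.T)


# --------------------------------------------------------------------------
# slab density profiles
# --------------------------------------------------------------------------

@dataclass
class SlabProfileParams:
    """Parameters of the coexistence density-profile generator.

    The density gap closes as ``gap_amp (1 − T/Tc)^beta`` (3D-Ising
    ``beta = 0.325`` by default) and the rectilinear diameter drifts
    linearly toward ``rho_c``.
    """

    temperatures: tuple = (300.0, 330.0, 360.0, 390.0, 420.0)
    Tc_true: float = 450.0  # K
    beta_exp: float = 0.325
    rho_c: float = 300.0  # mg/ml
    gap_amp: float = 1000.0  # mg/ml
    diam_slope: float = 0.5  # mg/(ml·K)
    z_grid: tuple = tuple(np.linspace(-15.0, 15.0, 301))
    interface_width: float = 0.8  # μm
    noise_sd: float = 0.0  # mg/ml
    seed: int = 0


def coexistence_densities(params: SlabProfileParams, T: float) -> tuple[float, float]:
    """Ground-truth (ρ_dilute, ρ_dense) at temperature ``T``."""
    gap = params.gap_amp * (1.0 - T / params.Tc_true) ** params.beta_exp
    mean = params.rho_c + params.diam_slope * (params.Tc_true - T)
    return mean - gap / 2.0, mean + gap / 2.0


def gen_slab_profiles(params: SlabProfileParams) -> list[DensityProfile]:
    """Generate one tanh-shouldered slab profile per temperature."""
    if len(params.temperatures) == 0:
        raise ValueError("SlabProfileParams: temperatures must be non-empty")
    if any(T >= params.Tc_true for T in params.temperatures):
        raise ValueError("all temperatures must be below Tc_true")
    _require_positive(params, ("Tc_true", "beta_exp", "rho_c", "interface_width"))

    z = np.asarray(params.z_grid, dtype=float)
    z_center = 0.5 * (z[0] + z[-1])
    z0 = 0.25 * (z[-1] - z[0])  # slab half-width
    root = np.random.SeedSequence(params.seed)
    out = []
    for T, child in zip(params.temperatures, root.spawn(len(params.temperatures))):
        rho_l, rho_d = coexistence_densities(params, T)
        rho = 0.5 * (rho_d + rho_l) - 0.5 * (rho_d - rho_l) * np.tanh(
            (np.abs(z - z_center) - z0) / params.interface_width
        )
        if params.noise_sd > 0:
            rng = np.random.default_rng(child)
            rho = rho + rng.standard_normal(rho.shape) * params.noise_sd
        out.append(DensityProfile(z=z, rho=np.clip(rho, 0.0, None), T=float(T)))
    return out
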