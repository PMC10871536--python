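"""Core data containers shared across the analysis modules.

These are plain dataclasses around numpy arrays / pandas frames with the
minimal validation the downstream fitters rely on (uniform sampling, units,
positive metadata).  Units follow :mod:`microrheo.constants`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrapTrajectory",
    "NPAF",
    "ModulusSpectrum",
    "CrossoverResult",
    "ParticleTrackSet",
    "MSDCurve",
    "ViscosityPoint",
    "FRAPTrace",
    "ChainTrajectory",
    "RouseModeSeries",
    "RelaxationModulus",
    "StressSeries",
    "DensityProfile",
]

_MAX_GRID_JITTER = 1e-9  # s


def _check_uniform(t: np.ndarray, what: str) -> float:
    """Return the grid spacing of ``t``, raising if sampling is non-uniform."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError(f"{what}: need a 1D time grid with >= 2 samples")
    dt = np.diff(t)
    if np.ptp(dt) > _MAX_GRID_JITTER:
        raise ValueError(f"{what}: time grid is not uniform (jitter > 1e-9 s)")
    return float(dt.mean())


@dataclass
class TrapTrajectory:
    """Position of a bead in a calibrated harmonic optical trap.

    Parameters
    ----------
    t : array, s
        Uniform time grid.
    x : array, μm
        Bead position relative to the trap centre.
    kappa : float, pN/μm
        Trap stiffness (instrument calibration, never estimated here).
    a : float, μm
        Bead radius.
    T : float, K
        Temperature.
    """

    t: np.ndarray
    x: np.ndarray
    kappa: float
    a: float
    T: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.shape != self.x.shape:
            raise ValueError("t and x must have the same shape")
        self.dt = _check_uniform(self.t, "TrapTrajectory")
        for name in ("kappa", "a", "T"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TrapTrajectory: {name} must be > 0")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return self.x.size


@dataclass
class NPAF:
    """Normalized position autocorrelation function of a trapped bead.

    ``A(0) = 1`` exactly; ``n_pairs`` holds the number of sample pairs
    entering each lag (used as fit weights downstream).
    """

    lag: np.ndarray
    A: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (self.lag.shape == self.A.shape == self.n_pairs.shape):
            raise ValueError("lag, A and n_pairs must have the same shape")
        if self.lag[0] != 0.0 or abs(self.A[0] - 1.0) > 1e-12:
            raise ValueError("NPAF must start at lag 0 with A(0) = 1")
        self.dlag = _check_uniform(self.lag, "NPAF")

    @property
    def max_lag(self) -> float:
        return float(self.lag[-1])


@dataclass
class ModulusSpectrum:
    """Frequency-dependent viscoelastic moduli G'(ω), G''(ω)."""

    omega: np.ndarray  # rad/s, strictly increasing
    G_prime: np.ndarray  # Pa
    G_dprime: np.ndarray  # Pa

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.G_prime = np.asarray(self.G_prime, dtype=float)
        self.G_dprime = np.asarray(self.G_dprime, dtype=float)
        if not (self.omega.shape == self.G_prime.shape == self.G_dprime.shape):
            raise ValueError("omega, G_prime, G_dprime must share a shape")
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega must be strictly increasing")

    @property
    def n_decades(self) -> float:
        return float(np.log10(self.omega[-1] / self.omega[0]))


@dataclass
class CrossoverResult:
    """Lowest-frequency G'–G'' crossover and the terminal relaxation time."""

    omega_c: float  # rad/s; nan when not found
    tau_terminal: float  # s = 1/omega_c; nan when not found
    found: bool


@dataclass
class ParticleTrackSet:
    """2D bead tracks at one temperature, for video particle tracking.

    ``tracks`` is a tidy frame with columns ``particle_id, t, x, y``
    (t in s, positions in μm).
    """

    tracks: pd.DataFrame
    T: float  # K
    a: float  # bead radius, μm
    dt_frame: float  # s

    REQUIRED_COLUMNS = ("particle_id", "t", "x", "y")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.tracks.columns]
        if missing:
            raise ValueError(f"ParticleTrackSet: missing columns {missing}")
        for name in ("T", "a", "dt_frame"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ParticleTrackSet: {name} must be > 0")

    @property
    def particle_ids(self) -> np.ndarray:
        return self.tracks["particle_id"].unique()

    def __len__(self) -> int:
        return len(self.particle_ids)


@dataclass
class MSDCurve:
    """Ensemble-averaged mean squared displacement versus lag time."""

    lag: np.ndarray  # s
    msd: np.ndarray  # μm²
    n_pairs: np.ndarray
    dim: int = 2

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=float)
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("MSD lags must be increasing")
        if np.any(self.msd < 0):
            raise ValueError("MSD must be non-negative")


@dataclass
class ViscosityPoint:
    """A single (temperature, viscosity) measurement."""

    T: float  # K
    eta: float  # Pa·s
    eta_err: float = 0.0  # Pa·s

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError("ViscosityPoint: T must be > 0")
        if not self.eta > 0:
            raise ValueError("ViscosityPoint: eta must be > 0")


@dataclass
class FRAPTrace:
    """A FRAP intensity time trace with bleach bookkeeping.

    ``i_bleach`` indexes the first post-bleach frame; ``R_bleach`` is the
    bleach-spot radius in μm used to normalise the recovery half-time.
    """

    t: np.ndarray  # s
    I: np.ndarray  # intensity, arbitrary units (or normalized)
    i_bleach: int
    R_bleach: float  # μm
    normalized: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.shape != self.I.shape:
            raise ValueError("t and I must have the same shape")
        if self.i_bleach < 3:
            raise ValueError("FRAPTrace: need >= 3 pre-bleach frames")
        if self.i_bleach >= self.t.size:
            raise ValueError("FRAPTrace: i_bleach out of range")
        if not self.R_bleach > 0:
            raise ValueError("FRAPTrace: R_bleach must be > 0")
        if self.I[self.i_bleach] >= self.I[: self.i_bleach].mean():
            raise ValueError("FRAPTrace: first post-bleach intensity is not "
                             "below the pre-bleach mean")


@dataclass
class ChainTrajectory:
    """Bead coordinates of a single polymer chain over time.

    ``coords`` has shape (n_frames, N, 3) in μm; ``dt`` is the frame
    spacing in s; ``zeta`` (pN·s/μm) and ``k_spring`` (pN/μm) are the
    Langevin friction and bond spring constant used to generate it.
    """

    coords: np.ndarray
    dt: float
    zeta: float
    k_spring: float
    T: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, N, 3)")
        for name in ("dt", "zeta", "k_spring", "T"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ChainTrajectory: {name} must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]


@dataclass
class RouseModeSeries:
    """Time series of one Rouse mode amplitude X_p(t) (μm, 3-vector)."""

    p: int
    X: np.ndarray  # (frames, 3)
    dt: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 3:
            raise ValueError("X must have shape (frames, 3)")
        if self.p < 0:
            raise ValueError("mode index must be >= 0")


@dataclass
class RelaxationModulus:
    """Normalized stress-relaxation modulus G(t)/G(0) from Rouse modes."""

    t: np.ndarray
    G_norm: np.ndarray
    p_max: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.G_norm = np.asarray(self.G_norm, dtype=float)
        if abs(self.G_norm[0] - 1.0) > 1e-12:
            raise ValueError("G_norm(0) must equal 1")


@dataclass
class StressSeries:
    """Off-diagonal stress time series from a simulation box."""

    t: np.ndarray  # s
    sigma_xy: np.ndarray  # Pa
    V: float  # box volume, m³
    T: float  # K

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.sigma_xy = np.asarray(self.sigma_xy, dtype=float)
        if self.t.shape != self.sigma_xy.shape:
            raise ValueError("t and sigma_xy must have the same shape")
        self.dt = _check_uniform(self.t, "StressSeries")
        if not (self.V > 0 and self.T > 0):
            raise ValueError("StressSeries: V and T must be > 0")


@dataclass
class DensityProfile:
    """Slab density profile ρ(z) at one temperature."""

    z: np.ndarray  # μm
    rho: np.ndarray  # mg/ml
    T: float  # K

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.z.shape != self.rho.shape:
            raise ValueError("z and rho must have the same shape")
        _check_uniform(self.z, "DensityProfile")
        if not self.T > 0:
            raise ValueError("DensityProfile: T must be > 0")
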