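"""Simulation-side observables: Rouse modes, Green–Kubo viscosity, and
slab-coexistence phase-diagram analysis.

* Rouse modes of a free-end discrete chain use the cosine basis with the
  (n+1/2) phase offset, which is exactly orthogonal:
  ``X_p(t) = (1/N) Σ_n r_n(t) cos(pπ(n+1/2)/N)``.  For an ideal chain the
  mode autocorrelations decay as single exponentials with
  ``τ_p = ζ / (4k sin²(pπ/2N))``; sticker interactions retard the slow
  modes ("sticky Rouse").
* The normalized relaxation modulus averages the *squared* normalized mode
  autocorrelations, ``G_norm(t) = (1/p_max) Σ_p C_p(t)²`` — Rouse stress
  relaxation is carried by squared mode correlators; absolute prefactors
  (c k_B T / N) are deliberately dropped since only the normalized quantity
  is analysed.
* Green–Kubo: ``η = (V / k_B T) ∫₀^∞ ⟨σ_xy(0) σ_xy(t)⟩ dt``, evaluated
  either from an exponential fit of the stress ACF (analytic integral
  A·τ_c) or from the first plateau of the cumulative integral.
* Coexistence: tanh profile fits give per-temperature dilute/dense
  densities; the critical point comes from the density gap closing as
  ``(ρ_d − ρ_l) ∝ (1 − T/T_c)^β`` with the 3D-Ising β = 0.325 fixed, plus
  a rectilinear-diameter regression for ρ_c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .constants import K_B
from .datatypes import (
    ChainTrajectory,
    DensityProfile,
    RelaxationModulus,
    RouseModeSeries,
    StressSeries,
)

__all__ = [
    "rouse_modes",
    "rouse_tau_theory",
    "mode_autocorrelation",
    "mode_relaxation_times",
    "relaxation_modulus",
    "GreenKuboResult",
    "green_kubo_viscosity",
    "TanhProfileModel",
    "fit_density_profile",
    "CoexistencePoint",
    "CriticalPointModel",
    "estimate_tc",
]

BURN_IN_FRAC = 0.1  # leading fraction of every series discarded as burn-in


def rouse_basis(N: int, p: int) -> np.ndarray:
    """Cosine basis vector of mode ``p`` for an N-bead free-end chain."""
    n = np.arange(N)
    return np.cos(p * math.pi * (n + 0.5) / N)


def rouse_modes(
    traj: ChainTrajectory, p_max: int, include_com: bool = False
) -> list[RouseModeSeries]:
    """Cosine-transform a chain trajectory into Rouse modes 1..p_max.

    ``include_com`` prepends the p = 0 centre-of-mass mode.
    """
    N = traj.n_beads
    if not 1 <= p_max <= N - 1:
        raise ValueError(f"p_max must lie in [1, N-1] = [1, {N - 1}]")
    ps = ([0] if include_com else []) + list(range(1, p_max + 1))
    basis = np.stack([rouse_basis(N, p) for p in ps])  # (n_modes, N)
    X = np.einsum("fnd,pn->fpd", traj.coords, basis) / N
    return [
        RouseModeSeries(p=p, X=X[:, i, :], dt=traj.dt) for i, p in enumerate(ps)
    ]


def rouse_tau_theory(N: int, p: int, zeta: float, k_spring: float) -> float:
    """Ideal-chain relaxation time τ_p = ζ / (4 k sin²(pπ/2N))."""
    return zeta / (4.0 * k_spring * math.sin(p * math.pi / (2.0 * N)) ** 2)


def _acf_vec(X: np.ndarray, n_lags: int) -> np.ndarray:
    """Unbiased autocorrelation of a (frames, d) vector series, summed over
    components and normalized to 1 at lag 0."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    acov = np.zeros(n_lags)
    for d in range(X.shape[1]):
        f = np.fft.rfft(Xc[:, d], nfft)
        acov += np.fft.irfft(f * np.conj(f), nfft)[:n_lags]
    acov /= n - np.arange(n_lags)
    return acov / acov[0]


def mode_autocorrelation(
    mode: RouseModeSeries, max_lag_frac: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized autocorrelation C_p(t) of a mode series (burn-in
    discarded).  Returns (lag, C)."""
    burn = int(mode.X.shape[0] * BURN_IN_FRAC)
    X = mode.X[burn:]
    n_lags = max(int(X.shape[0] * max_lag_frac), 2)
    C = _acf_vec(X, n_lags)
    lag = np.arange(n_lags, dtype=float) * mode.dt
    return lag, C


@dataclass
class ModeRelaxation:
    p: int
    tau: float  # s; nan when unresolved
    resolved: bool


def _fit_single_exp(lag: np.ndarray, C: np.ndarray) -> float:
    """Fit C = exp(-t/τ) over the window C ∈ [0.05, 1]; nan when the ACF
    does not decay into that window."""
    below = np.where(C < 0.05)[0]
    end = below[0] if below.size else C.size
    if end < 3 or C[min(end, C.size - 1) - 1] > 0.8:
        return math.nan  # not decaying within the window
    w_lag, w_C = lag[:end], C[:end]
    pos = w_C > 0
    slope = stats.linregress(w_lag[pos], np.log(w_C[pos])).slope
    if not slope < 0:
        return math.nan
    tau0 = -1.0 / slope
    sol = least_squares(
        lambda x: np.exp(-w_lag / math.exp(x[0])) - w_C,
        [math.log(tau0)],
        method="lm",
    )
    return float(math.exp(sol.x[0]))


def mode_relaxation_times(
    modes: list[RouseModeSeries], dt: float | None = None
) -> list[ModeRelaxation]:
    """Single-exponential relaxation time of each mode autocorrelation.

    Modes whose ACF does not decay inside the accessible window are
    flagged unresolved (``tau = nan``) rather than silently mis-fitted.
    """
    out = []
    for mode in modes:
        if mode.p == 0:
            continue  # the COM mode does not relax
        lag, C = mode_autocorrelation(mode)
        tau = _fit_single_exp(lag, C)
        out.append(ModeRelaxation(p=mode.p, tau=tau, resolved=not math.isnan(tau)))
    return out


def relaxation_modulus(
    modes: list[RouseModeSeries],
    dt: float | None = None,
    p_max: int | None = None,
    max_lag_frac: float = 0.25,
) -> RelaxationModulus:
    """Normalized relaxation modulus G_norm(t) = (1/p_max) Σ_p C_p(t)²."""
    internal = [m for m in modes if m.p >= 1]
    if p_max is not None:
        internal = [m for m in internal if m.p <= p_max]
    if not internal:
        raise ValueError("no internal modes supplied")
    lags, Cs = zip(*(mode_autocorrelation(m, max_lag_frac) for m in internal))
    n = min(C.size for C in Cs)
    G = np.mean([C[:n] ** 2 for C in Cs], axis=0)
    return RelaxationModulus(t=lags[0][:n], G_norm=G, p_max=len(internal))


# --------------------------------------------------------------------------
# Green–Kubo viscosity
# --------------------------------------------------------------------------

@dataclass
class GreenKuboResult:
    """Viscosity from the stress-ACF integral; both estimators reported."""

    eta: float  # Pa·s, the selected method
    eta_fit: float  # exponential-ACF analytic integral
    eta_plateau: float  # plateau of the cumulative integral (nan if none)
    acf_amplitude: float  # Pa²
    acf_tau: float  # s
    method: str

    def __float__(self) -> float:
        return self.eta


def green_kubo_viscosity(stress: StressSeries, method: str = "fit") -> GreenKuboResult:
    """Shear viscosity from the Green–Kubo stress-autocorrelation integral.

    ``method="fit"`` (default) fits the ACF with A·exp(−t/τc) and uses the
    analytic integral A·τc; ``method="plateau"`` integrates the ACF
    cumulatively (trapezoid) and reads the first plateau, defined as the
    point where the running integral changes by less than 1% per decade of
    time.
    """
    if method not in ("fit", "plateau"):
        raise ValueError(f"unknown method {method!r}")
    burn = int(stress.sigma_xy.size * BURN_IN_FRAC)
    s = stress.sigma_xy[burn:] - stress.sigma_xy[burn:].mean()
    n = s.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(s, nfft)
    n_lags = min(n // 4, n - 1)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n_lags] / (n - np.arange(n_lags))
    lag = np.arange(n_lags, dtype=float) * stress.dt
    prefac = stress.V / (K_B * stress.T)  # m³/J

    # correlation-time estimate from the 1/e crossing
    below = np.where(acov < acov[0] / math.e)[0]
    tau0 = lag[below[0]] if below.size and below[0] > 0 else lag[-1] / 10.0
    if n * stress.dt < 100.0 * tau0:
        raise ValueError(
            "stress series shorter than 100 correlation times: Green-Kubo "
            "integral not converged"
        )

    # exponential fit over the first ~5 correlation times
    end = min(int(5.0 * tau0 / stress.dt) + 2, n_lags)
    sol = least_squares(
        lambda x: math.exp(x[0]) * np.exp(-lag[:end] / math.exp(x[1])) - acov[:end],
        [math.log(max(acov[0], 1e-300)), math.log(tau0)],
        method="lm",
    )
    A_fit, tau_fit = math.exp(sol.x[0]), math.exp(sol.x[1])
    eta_fit = prefac * A_fit * tau_fit

    # cumulative-integral plateau
    running = prefac * np.concatenate(
        [[0.0], np.cumsum((acov[1:] + acov[:-1]) / 2.0) * stress.dt]
    )
    eta_plateau = math.nan
    start = max(int(tau0 / stress.dt), 1)
    for i in range(start, n_lags - 1):
        t_i = lag[i]
        j = min(int(i * 10 ** 0.1) + 1, n_lags - 1)  # one tenth of a decade on
        if running[i] != 0 and abs(running[j] - running[i]) < 0.001 * abs(running[i]):
            eta_plateau = float(running[i])
            break
    if math.isnan(eta_plateau):
        # fall back to the integral at ~10 correlation times
        k = min(int(10.0 * tau_fit / stress.dt), n_lags - 1)
        eta_plateau = float(running[k])

    if method == "fit":
        if not sol.success or eta_fit <= 0:
            raise RuntimeError(
                f"stress-ACF exponential fit failed (A={A_fit:.3g}, "
                f"tau={tau_fit:.3g}); plateau estimate was {eta_plateau:.3g}"
            )
        eta = eta_fit
    else:
        eta = eta_plateau
    return GreenKuboResult(
        eta=eta,
        eta_fit=eta_fit,
        eta_plateau=eta_plateau,
        acf_amplitude=A_fit,
        acf_tau=tau_fit,
        method=method,
    )


# --------------------------------------------------------------------------
# slab density profiles → phase diagram
# --------------------------------------------------------------------------

@dataclass
class CoexistencePoint:
    """Dilute/dense coexisting densities at one temperature."""

    T: float  # K
    rho_dilute: float  # mg/ml
    rho_dense: float  # mg/ml
    rho_dilute_err: float = 0.0
    rho_dense_err: float = 0.0
    coexisting: bool = True


def _tanh_profile(z, rho_d, rho_l, z_c, z0, w):
    return 0.5 * (rho_d + rho_l) - 0.5 * (rho_d - rho_l) * np.tanh(
        (np.abs(z - z_c) - z0) / w
    )


class TanhProfileModel(RegressorMixin, BaseEstimator):
    """tanh-shoulder fit of a slab density profile, sklearn-style.

    ``fit(z, rho)`` fits ``ρ(z) = (ρd+ρl)/2 − (ρd−ρl)/2 ·
    tanh((|z − z_c| − z0)/w)``.  Fitted attributes: ``rho_dense_``,
    ``rho_dilute_`` (mg/ml) with ``*_err_``, slab centre ``z_c_``,
    half-width ``z0_``, interface width ``w_``, and ``coexisting_`` —
    False when the density gap is not significant at 2σ.
    """

    def fit(self, z, rho):
        z = np.asarray(z, dtype=float).reshape(-1)
        rho = np.asarray(rho, dtype=float).reshape(-1)
        if z.size != rho.size or z.size < 10:
            raise ValueError("need matching z and rho with >= 10 bins")
        span = z[-1] - z[0]
        p0 = [
            float(rho.max()),
            float(rho.min()),
            float(np.average(z, weights=np.maximum(rho - rho.min(), 1e-12))),
            span / 4.0,
            span / 20.0,
        ]
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            popt, pcov = curve_fit(_tanh_profile, z, rho, p0=p0, maxfev=20000)
        if popt[0] < popt[1]:  # enforce dense >= dilute labelling
            popt[0], popt[1] = popt[1], popt[0]
            pcov[[0, 1]] = pcov[[1, 0]]
            pcov[:, [0, 1]] = pcov[:, [1, 0]]
        perr = np.sqrt(np.abs(np.diag(pcov)))
        # an (numerically) exact fit leaves the covariance undefined; treat
        # it as zero-error rather than as an unidentifiable profile
        resid_rms = float(np.sqrt(np.mean((rho - _tanh_profile(z, *popt)) ** 2)))
        scale = max(float(np.ptp(rho)), 1e-12)
        if not np.all(np.isfinite(perr)) and resid_rms < 1e-8 * scale:
            perr = np.zeros_like(perr)
        self.rho_dense_ = float(popt[0])
        self.rho_dilute_ = float(popt[1])
        self.rho_dense_err_ = float(perr[0])
        self.rho_dilute_err_ = float(perr[1])
        self.z_c_ = float(popt[2])
        self.z0_ = float(abs(popt[3]))
        self.w_ = float(abs(popt[4]))
        gap = self.rho_dense_ - self.rho_dilute_
        gap_err = math.hypot(perr[0], perr[1])
        self.coexisting_ = bool(gap > 2.0 * gap_err)
        self.n_features_in_ = 1
        return self

    def predict(self, z):
        check_is_fitted(self, "rho_dense_")
        return _tanh_profile(
            np.asarray(z, dtype=float),
            self.rho_dense_,
            self.rho_dilute_,
            self.z_c_,
            self.z0_,
            self.w_,
        )


def fit_density_profile(profile: DensityProfile) -> CoexistencePoint:
    """Fit a tanh slab profile; flag "no coexistence" when the density gap
    is not significant at 2σ.

    At least 5 bins of each plateau must lie inside the profile (checked
    through the fitted half-width).
    """
    model = TanhProfileModel().fit(profile.z, profile.rho)
    dz = profile.z[1] - profile.z[0]
    span = profile.z[-1] - profile.z[0]
    n_dense = 2.0 * model.z0_ / dz
    n_dilute = (span - 2.0 * model.z0_) / dz
    if model.coexisting_ and (n_dense < 5 or n_dilute < 5):
        raise ValueError("profile does not span both plateaus (>= 5 bins each)")
    return CoexistencePoint(
        T=profile.T,
        rho_dilute=model.rho_dilute_,
        rho_dense=model.rho_dense_,
        rho_dilute_err=model.rho_dilute_err_,
        rho_dense_err=model.rho_dense_err_,
        coexisting=model.coexisting_,
    )


class CriticalPointModel(RegressorMixin, BaseEstimator):
    """Critical-temperature fit from coexisting densities, sklearn-style.

    ``fit(T, rho)`` with ``rho`` a (n, 2) array of [ρ_dilute, ρ_dense].
    The density gap is regressed as ``(ρd − ρl)^{1/β}`` linear in T with
    the exponent β fixed (3D Ising 0.325 by default); T_c is the root of
    that line.  ρ_c comes from the rectilinear-diameter regression of
    (ρd + ρl)/2 on T, evaluated at T_c.  Fitted attributes: ``Tc_`` (K),
    ``rho_c_`` (mg/ml), ``Tc_err_``.
    """

    def __init__(self, beta: float = 0.325):
        self.beta = beta

    def fit(self, T, rho):
        T = np.asarray(T, dtype=float).reshape(-1)
        rho = np.asarray(rho, dtype=float)
        if rho.ndim != 2 or rho.shape[1] != 2 or rho.shape[0] != T.size:
            raise ValueError("rho must be a (n, 2) array of [rho_dilute, rho_dense]")
        if T.size < 4:
            raise ValueError("need >= 4 subcritical temperatures")
        order = np.argsort(T)
        T, rho = T[order], rho[order]
        gap = rho[:, 1] - rho[:, 0]
        if np.any(gap <= 0):
            raise ValueError("density gap must be positive at every temperature")
        if np.any(np.diff(gap) >= 0):
            raise ValueError("density gap must shrink monotonically toward Tc")
        y = gap ** (1.0 / self.beta)
        res = stats.linregress(T, y)
        if not res.slope < 0:
            raise ValueError("density-gap regression does not close at high T")
        self.Tc_ = float(-res.intercept / res.slope)
        # first-order error propagation of the root
        self.Tc_err_ = float(
            abs(self.Tc_)
            * math.hypot(
                res.intercept_stderr / abs(res.intercept),
                res.stderr / abs(res.slope),
            )
        ) if res.intercept != 0 else math.nan
        diam = stats.linregress(T, rho.mean(axis=1))
        self.rho_c_ = float(diam.intercept + diam.slope * self.Tc_)
        self.gap_slope_ = float(res.slope)
        self.n_features_in_ = 1
        return self

    def predict(self, T):
        """Predicted density gap (ρd − ρl) at temperatures ``T``."""
        check_is_fitted(self, "Tc_")
        T = np.asarray(T, dtype=float).reshape(-1)
        y = self.gap_slope_ * (T - self.Tc_)
        return np.where(y > 0, y, 0.0) ** self.beta


def estimate_tc(points: list[CoexistencePoint], beta: float = 0.325) -> CriticalPointModel:
    """Critical point from a list of coexistence points.

    Thin wrapper over :class:`CriticalPointModel`; points flagged
    non-coexisting are rejected.
    """
    usable = [p for p in points if p.coexisting]
    if len(usable) < 4:
        raise ValueError("need >= 4 coexisting temperatures to estimate Tc")
    T = np.array([p.T for p in usable])
    rho = np.array([[p.rho_dilute, p.rho_dense] for p in usable])
    return CriticalPointModel(beta=beta).fit(T, rho)
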