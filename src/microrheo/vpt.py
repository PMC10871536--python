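"""Video-particle-tracking rheology and thermorheology.

Tracer-bead tracks recorded inside condensate droplets are reduced to an
ensemble-averaged mean squared displacement, a diffusion coefficient, a
Stokes–Einstein viscosity per temperature, and finally an Arrhenius fit of
viscosity against temperature,

.. math::

    \\eta = \\eta_0 \\exp\\!\\left(\\frac{E_A}{RT}\\right) + c, \\qquad
    \\ln \\eta = \\ln \\eta_0 + \\frac{E_A}{R}\\frac{1}{T},

whose slope yields the flow activation energy E_A — the energy barrier for
reconfiguration of the condensate fluid network.  E_A is reported both in
kJ/mol and in RT units at the fixed reference temperature 298.15 K (25 °C).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .constants import KB_PNUM, R_GAS, T_REF_RT
from .datatypes import MSDCurve, ParticleTrackSet, ViscosityPoint

__all__ = [
    "compute_msd",
    "DiffusivityModel",
    "fit_diffusivity",
    "viscosity_from_D",
    "ArrheniusModel",
    "arrhenius_fit",
    "convert_activation_energy",
]


def _msd_1d(r: np.ndarray) -> np.ndarray:
    """Time-averaged MSD of a 1D signal over all overlapping pairs, O(n log n).

    Uses the standard FFT decomposition MSD(k) = S1(k) − 2·S2(k) with S2 the
    autocorrelation.
    """
    n = r.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(r, nfft)
    s2 = np.fft.irfft(f * np.conj(f), nfft)[:n]
    r2 = r * r
    # S1 recursion: S1(0) = 2 Σ r², S1(k) = S1(k−1) − r²_{k−1} − r²_{n−k}
    s1 = np.empty(n)
    s1[0] = 2.0 * r2.sum()
    s1[1:] = s1[0] - np.cumsum(r2[:-1]) - np.cumsum(r2[::-1][:-1])
    counts = n - np.arange(n)
    # roundoff in the FFT path can leave tiny negatives at lag 0
    return np.maximum((s1 - 2.0 * s2) / counts, 0.0)


def _particle_msds(tracks: ParticleTrackSet, max_lag_frac: float):
    """Per-particle time-averaged MSDs on a common lag grid.

    Returns ``(lag, msd_matrix, count_matrix)`` with one row per particle;
    counts are the per-lag pair numbers (zero where a track is too short).
    Tracks shorter than 4 frames are excluded with a warning.
    """
    if not 0 < max_lag_frac <= 0.25:
        raise ValueError("max_lag_frac must lie in (0, 0.25]")
    per_particle = []
    for pid, grp in tracks.tracks.groupby("particle_id", sort=True):
        if len(grp) < 4:
            warnings.warn(f"track {pid!r} shorter than 4 frames: excluded", stacklevel=2)
            continue
        g = grp.sort_values("t")
        msd = _msd_1d(g["x"].to_numpy()) + _msd_1d(g["y"].to_numpy())
        n = len(g)
        per_particle.append((msd, n - np.arange(n)))
    if not per_particle:
        raise ValueError("all tracks excluded: nothing to average")
    n_lags_full = max(m.size for m, _ in per_particle)
    n_lags = max(int(math.floor((n_lags_full - 1) * max_lag_frac)), 1) + 1
    M = np.zeros((len(per_particle), n_lags))
    W = np.zeros((len(per_particle), n_lags))
    for i, (msd, counts) in enumerate(per_particle):
        k = min(n_lags, msd.size)
        M[i, :k] = msd[:k]
        W[i, :k] = counts[:k]
    lag = np.arange(n_lags, dtype=float) * tracks.dt_frame
    return lag, M, W


def compute_msd(tracks: ParticleTrackSet, max_lag_frac: float = 0.25) -> MSDCurve:
    """Ensemble-averaged 2D MSD of a track set.

    Per particle the time-averaged MSD ⟨Δx² + Δy²⟩ over all ordered pairs
    is computed; the ensemble average weights each particle by its per-lag
    pair count.  Tracks shorter than 4 frames are excluded with a warning.
    """
    lag, M, W = _particle_msds(tracks, max_lag_frac)
    den = W.sum(axis=0)
    return MSDCurve(lag=lag, msd=(M * W).sum(axis=0) / den, n_pairs=den, dim=2)


class DiffusivityModel(RegressorMixin, BaseEstimator):
    """Diffusion-coefficient fit of an MSD curve, sklearn-style.

    ``fit(lag, msd)`` supports two models:

    * ``"powerlaw"`` — OLS of log msd on log lag:
      ``log msd = log(2·dim·D) + α·log lag``;
    * ``"linear+offset"`` — weighted least squares of
      ``msd = 2·dim·D·lag + offset``; the intercept absorbs the static
      localization-noise floor 2·dim·σ_loc², and α is then measured on the
      offset-corrected curve as a diagnostic.

    Fitted attributes: ``D_`` (μm²/s), ``alpha_``, ``offset_`` (μm²),
    ``D_err_``, ``alpha_err_``.

    Parameters
    ----------
    model : str
        "linear+offset" (default) or "powerlaw".
    dim : int
        Spatial dimensionality of the MSD (2 for video tracking).
    """

    def __init__(self, model: str = "linear+offset", dim: int = 2):
        self.model = model
        self.dim = dim

    def fit(self, lag, msd, sample_weight=None):
        lag = np.asarray(lag, dtype=float).reshape(-1)
        msd = np.asarray(msd, dtype=float).reshape(-1)
        mask = lag > 0
        lag, msd = lag[mask], msd[mask]
        w = (
            np.asarray(sample_weight, dtype=float).reshape(-1)[mask]
            if sample_weight is not None
            else np.ones_like(lag)
        )
        if lag.size < 5:
            raise ValueError("need >= 5 positive-lag points to fit")
        two_d = 2.0 * self.dim
        if self.model == "powerlaw":
            if np.any(msd <= 0):
                raise ValueError("non-positive MSD in fit window")
            res = stats.linregress(np.log(lag), np.log(msd))
            self.alpha_ = float(res.slope)
            self.alpha_err_ = float(res.stderr)
            self.D_ = float(np.exp(res.intercept) / two_d)
            self.D_err_ = float(self.D_ * res.intercept_stderr)
            self.offset_ = 0.0
        elif self.model == "linear+offset":
            X = np.column_stack([np.ones_like(lag), lag])
            W = np.diag(w)
            XtW = X.T @ W
            beta, *_ = np.linalg.lstsq(XtW @ X, XtW @ msd, rcond=None)
            resid = msd - X @ beta
            dof = max(lag.size - 2, 1)
            s2 = float(resid @ (w * resid)) / dof
            cov = s2 * np.linalg.inv(XtW @ X)
            self.offset_ = float(beta[0])
            self.D_ = float(beta[1] / two_d)
            self.D_err_ = float(math.sqrt(cov[1, 1]) / two_d)
            # diffusivity exponent measured on the offset-corrected curve,
            # restricted to signal-dominated lags (above the noise floor)
            corrected = msd - self.offset_
            ok = corrected > max(self.offset_, 0.0)
            if ok.sum() < 3:
                ok = corrected > 0
            if ok.sum() >= 3:
                res = stats.linregress(np.log(lag[ok]), np.log(corrected[ok]))
                self.alpha_ = float(res.slope)
                self.alpha_err_ = float(res.stderr)
            else:  # offset eats the whole curve; slope undiagnosable
                self.alpha_ = math.nan
                self.alpha_err_ = math.nan
        else:
            raise ValueError(f"unknown model {self.model!r}")
        if not self.D_ > 0:
            raise ValueError("fitted diffusivity is non-positive")
        self.fit_window_ = (float(lag[0]), float(lag[-1]))
        self.n_features_in_ = 1
        return self

    def predict(self, lag):
        check_is_fitted(self, "D_")
        lag = np.asarray(lag, dtype=float).reshape(-1)
        two_d = 2.0 * self.dim
        if self.model == "powerlaw":
            return two_d * self.D_ * lag**self.alpha_
        return two_d * self.D_ * lag + self.offset_


def fit_diffusivity(
    msd: MSDCurve,
    model: str = "linear+offset",
    fit_window: tuple[float, float] | None = None,
) -> DiffusivityModel:
    """Fit D (and α) from an MSD curve over an optional lag window.

    Thin wrapper over :class:`DiffusivityModel`; pair counts weight the
    linear fit.
    """
    lag, curve, w = msd.lag, msd.msd, msd.n_pairs
    if fit_window is not None:
        lo, hi = fit_window
        m = (lag >= lo) & (lag <= hi)
        lag, curve, w = lag[m], curve[m], w[m]
    return DiffusivityModel(model=model, dim=msd.dim).fit(lag, curve, sample_weight=w)


def viscosity_from_D(
    D: float, a: float, T: float, D_err: float = 0.0
) -> ViscosityPoint:
    """Stokes–Einstein viscosity η = k_B T / (6π a D).

    ``D`` in μm²/s, ``a`` in μm, ``T`` in K; relative error propagated
    from D.
    """
    if not (D > 0 and a > 0 and T > 0):
        raise ValueError("D, a and T must all be > 0")
    eta = KB_PNUM * T / (6.0 * math.pi * a * D)  # pN/μm·(s) → Pa·s
    return ViscosityPoint(T=T, eta=eta, eta_err=eta * D_err / D)


class ArrheniusModel(RegressorMixin, BaseEstimator):
    """Arrhenius fit of viscosity against temperature, sklearn-style.

    ``fit(T, eta)`` with temperatures in K and viscosities in Pa·s.  Two
    forms:

    * ``"linear"`` — OLS of ln η on 1/T; ``E_A_ = slope · R``.
    * ``"exp+const"`` — nonlinear least squares of
      ``η = η0 exp(E_A/(R T)) + c``, initialised from the linear fit with
      c = 0.  A negative fitted c triggers a refit with c pinned to zero
      (``offset_pinned_ = True``).

    Fitted attributes: ``E_A_`` (J/mol), ``ln_eta0_``, ``offset_c_``
    (Pa·s), ``E_A_RT_`` (dimensionless, at 298.15 K), ``E_A_err_``
    (bootstrap), ``r_squared_``.

    Parameters
    ----------
    form : str
        "linear" (default) or "exp+const".
    min_span : float
        Minimum temperature span in K (default 20).
    n_boot : int
        Bootstrap resamples over (T, η) points for the E_A standard error.
    random_state : int
        Seed of the bootstrap resampler.
    """

    def __init__(
        self,
        form: str = "linear",
        min_span: float = 20.0,
        n_boot: int = 200,
        random_state: int = 0,
    ):
        self.form = form
        self.min_span = min_span
        self.n_boot = n_boot
        self.random_state = random_state

    @staticmethod
    def _linear(T, eta):
        res = stats.linregress(1.0 / T, np.log(eta))
        return res

    def _fit_once(self, T, eta):
        if self.form == "linear":
            res = self._linear(T, eta)
            return res.slope * R_GAS, res.intercept, 0.0, False
        if self.form == "exp+const":
            from scipy.optimize import least_squares

            lin = self._linear(T, eta)
            x0 = np.array([lin.intercept, lin.slope * R_GAS, 0.0])

            def resid(x, fit_c=True):
                ln_eta0, E_A, c = x[0], x[1], (x[2] if fit_c else 0.0)
                return np.exp(ln_eta0 + E_A / (R_GAS * T)) + c - eta

            sol = least_squares(resid, x0, method="lm", max_nfev=10000)
            pinned = False
            if sol.x[2] < 0:  # unphysical negative background; pin it
                sol = least_squares(
                    lambda x: resid(np.append(x, 0.0)), x0[:2], method="lm",
                    max_nfev=10000,
                )
                pinned = True
                return sol.x[1], sol.x[0], 0.0, pinned
            return sol.x[1], sol.x[0], float(sol.x[2]), pinned
        raise ValueError(f"unknown form {self.form!r}")

    def fit(self, T, eta, eta_err=None):
        T = np.asarray(T, dtype=float).reshape(-1)
        eta = np.asarray(eta, dtype=float).reshape(-1)
        if T.size != eta.size:
            raise ValueError("T and eta must have the same length")
        if T.size < 4:
            raise ValueError("need >= 4 temperatures for an Arrhenius fit")
        if np.ptp(T) < self.min_span:
            raise ValueError(
                f"temperature span {np.ptp(T):.1f} K below the minimum "
                f"{self.min_span:.0f} K"
            )
        if np.any(eta <= 0):
            raise ValueError("viscosities must be positive")

        E_A, ln_eta0, c, pinned = self._fit_once(T, eta)
        self.E_A_ = float(E_A)
        self.ln_eta0_ = float(ln_eta0)
        self.offset_c_ = float(c)
        self.offset_pinned_ = pinned
        self.E_A_RT_ = float(E_A / (R_GAS * T_REF_RT))
        self.E_A_kJmol_ = float(E_A / 1000.0)

        lin = self._linear(T, eta)
        self.r_squared_ = float(lin.rvalue**2)

        # seeded point-level bootstrap for the E_A standard error
        rng = np.random.default_rng(self.random_state)
        boots = []
        for _ in range(self.n_boot):
            idx = rng.integers(0, T.size, T.size)
            if np.ptp(T[idx]) < 1e-9 or np.unique(T[idx]).size < 3:
                continue
            try:
                boots.append(self._fit_once(T[idx], eta[idx])[0])
            except Exception:
                continue
        self.E_A_err_ = float(np.std(boots, ddof=1)) if len(boots) > 2 else math.nan
        self.E_A_RT_err_ = self.E_A_err_ / (R_GAS * T_REF_RT)
        self.n_features_in_ = 1
        return self

    def predict(self, T):
        check_is_fitted(self, "E_A_")
        T = np.asarray(T, dtype=float).reshape(-1)
        return np.exp(self.ln_eta0_ + self.E_A_ / (R_GAS * T)) + self.offset_c_


@dataclass
class _PointArrays:
    T: np.ndarray
    eta: np.ndarray
    eta_err: np.ndarray


def _points_to_arrays(points) -> _PointArrays:
    T = np.array([p.T for p in points], dtype=float)
    eta = np.array([p.eta for p in points], dtype=float)
    err = np.array([getattr(p, "eta_err", 0.0) for p in points], dtype=float)
    return _PointArrays(T=T, eta=eta, eta_err=err)


def arrhenius_fit(
    points: list[ViscosityPoint], form: str = "linear", **kwargs
) -> ArrheniusModel:
    """Arrhenius fit of a list of :class:`ViscosityPoint` measurements.

    Thin wrapper over :class:`ArrheniusModel`; returns the fitted
    estimator.
    """
    arr = _points_to_arrays(points)
    return ArrheniusModel(form=form, **kwargs).fit(arr.T, arr.eta, eta_err=arr.eta_err)


def viscosity_vs_temperature(
    tracksets: list[ParticleTrackSet],
    model: str = "linear+offset",
    fit_window: tuple[float, float] | None = None,
    max_lag_frac: float = 0.25,
    alpha_band: tuple[float, float] = (0.9, 1.1),
    n_boot: int = 50,
    random_state: int = 0,
) -> tuple[list[ViscosityPoint], list[dict]]:
    """MSD → D → Stokes–Einstein viscosity for each temperature's tracks.

    The default fit window covers the first 20 lag times: short lags
    carry nearly independent displacement statistics, while long-lag MSD
    values are few-pair averages with strongly correlated errors that
    inflate the variance of the fitted slope without adding information.

    Standard errors of D and of the diffusivity exponent α come from a
    seeded track-level bootstrap (particles resampled with replacement,
    ensemble MSD refitted), which honestly reflects bead-to-bead scatter
    where per-lag least-squares errors would not (MSD residuals are
    strongly correlated across lags).

    Points whose diffusivity exponent lies *significantly* outside
    ``alpha_band`` are flagged non-diffusive and excluded from the
    returned viscosity list (sub-diffusive beads do not report a
    Newtonian viscosity); the band is applied at one bootstrap standard
    error — only points whose α ± σ_α interval misses the band entirely
    are dropped.  Every temperature still appears in the returned
    per-point diagnostics.
    """
    points: list[ViscosityPoint] = []
    diagnostics: list[dict] = []
    rng = np.random.default_rng(random_state)
    for ts in tracksets:
        lag, M, W = _particle_msds(ts, max_lag_frac)
        window = fit_window if fit_window is not None else (0.0, 20.5 * ts.dt_frame)

        def ensemble_fit(rows):
            den = W[rows].sum(axis=0)
            ok = den > 0
            curve = MSDCurve(
                lag=lag[ok], msd=(M[rows] * W[rows]).sum(axis=0)[ok] / den[ok],
                n_pairs=den[ok], dim=2,
            )
            return fit_diffusivity(curve, model=model, fit_window=window)

        fit = ensemble_fit(np.arange(M.shape[0]))
        boot_D, boot_alpha = [], []
        for _ in range(n_boot):
            rows = rng.integers(0, M.shape[0], M.shape[0])
            try:
                bf = ensemble_fit(rows)
            except (ValueError, RuntimeError):
                continue
            boot_D.append(bf.D_)
            boot_alpha.append(bf.alpha_)
        D_err = float(np.std(boot_D, ddof=1)) if len(boot_D) > 2 else fit.D_err_
        alpha_err = (
            float(np.nanstd(boot_alpha, ddof=1)) if len(boot_alpha) > 2 else 0.0
        )
        diffusive = not (
            math.isfinite(fit.alpha_)
            and (
                fit.alpha_ + alpha_err < alpha_band[0]
                or fit.alpha_ - alpha_err > alpha_band[1]
            )
        )
        point = viscosity_from_D(fit.D_, ts.a, ts.T, D_err=D_err)
        diagnostics.append(
            {
                "T_K": ts.T,
                "D_um2_s": fit.D_,
                "D_err_um2_s": D_err,
                "alpha": fit.alpha_,
                "alpha_err": alpha_err,
                "offset_um2": fit.offset_,
                "eta_Pa_s": point.eta,
                "eta_err_Pa_s": point.eta_err,
                "diffusive": diffusive,
            }
        )
        if diffusive:
            points.append(point)
    return points, diagnostics


def convert_activation_energy(E_A: float, T_ref: float = T_REF_RT) -> dict:
    """Convert an activation energy in J/mol to RT units (at ``T_ref``)
    and kJ/mol."""
    if not T_ref > 0:
        raise ValueError("T_ref must be > 0")
    return {"E_A_RT": E_A / (R_GAS * T_ref), "E_A_kJmol": E_A / 1000.0}
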