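"""FRAP trace normalization, recovery fitting and diffusion timescale.

Recovery after photobleaching is modelled as a single exponential with an
immobile fraction,

.. math::

    I(t) = I_\\infty - (I_\\infty - I_0)\\,e^{-\\ln 2\\,(t - t_b)/\\tau_{1/2}},

on the full-scale normalized trace (pre-bleach = 1, bleach point = 0); the
mobile fraction is ``(I_inf − I0)/(1 − I0)`` and the diffusion timescale is
the recovery half-time normalized by the bleach-spot radius squared,
``τ_D = τ_half / R_bleach²`` (s/μm²).  The half-time is defined through the
fitted exponential — noise-robust — with the raw half-crossing reported as
a secondary diagnostic.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import FRAPTrace

__all__ = [
    "normalize_frap",
    "FRAPRecoveryModel",
    "fit_recovery",
    "diffusion_timescale",
]


def normalize_frap(trace: FRAPTrace, reference: np.ndarray | None = None) -> FRAPTrace:
    """Full-scale normalization: pre-bleach mean → 1, first post-bleach
    point → 0.

    ``reference`` optionally supplies an unbleached-region trace used to
    correct acquisition photofading (divided out before normalization);
    synthetic traces don't fade, so it defaults to None.
    """
    I = trace.I.astype(float).copy()
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != I.shape:
            raise ValueError("reference trace must match the FRAP trace length")
        I = I / (ref / ref[: trace.i_bleach].mean())
    I_pre = I[: trace.i_bleach].mean()
    I0 = I[trace.i_bleach]
    if I_pre <= I0:
        raise ValueError("no bleach detected: pre-bleach mean <= first post-bleach value")
    return FRAPTrace(
        t=trace.t.copy(),
        I=(I - I0) / (I_pre - I0),
        i_bleach=trace.i_bleach,
        R_bleach=trace.R_bleach,
        normalized=True,
    )


class FRAPRecoveryModel(RegressorMixin, BaseEstimator):
    """Single-exponential FRAP recovery fit, sklearn-style.

    ``fit(t, I)`` takes post-bleach times (s, measured from the bleach
    event) and full-scale normalized intensities.  Fitted attributes:
    ``tau_half_`` (s), ``I0_``, ``I_inf_``, ``mobile_frac_``,
    ``tau_half_err_``, ``mobile_frac_err_`` and — when ``R_bleach`` is set —
    ``tau_D_`` (s/μm²).

    Parameters
    ----------
    R_bleach : float or None
        Bleach-spot radius in μm (user metadata, never estimated).
    """

    def __init__(self, R_bleach: float | None = None):
        self.R_bleach = R_bleach

    def fit(self, t, I):
        t = np.asarray(t, dtype=float).reshape(-1)
        I = np.asarray(I, dtype=float).reshape(-1)
        if t.size != I.size:
            raise ValueError("t and I must have the same length")
        if t.size < 20:
            raise ValueError("need >= 20 post-bleach frames to fit recovery")

        ln2 = math.log(2.0)

        def model(x, tt):
            I0, I_inf, log_tau = x
            return I_inf - (I_inf - I0) * np.exp(-ln2 * tt / math.exp(log_tau))

        # half-rise time of the raw trace seeds tau
        I0g, Iinfg = float(I[0]), float(np.median(I[-max(t.size // 10, 3):]))
        half = 0.5 * (I0g + Iinfg)
        above = np.where(I >= half)[0]
        tau_g = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(
            t[-1] / 10.0
        )
        sol = least_squares(
            lambda x: model(x, t) - I,
            [I0g, Iinfg, math.log(tau_g)],
            method="lm",
            max_nfev=10000,
        )
        if not sol.success:
            raise RuntimeError(
                f"FRAP recovery fit did not converge (status={sol.status}, "
                f"cost={sol.cost:.3g})"
            )
        I0, I_inf, log_tau = sol.x
        tau_half = math.exp(log_tau)
        if not tau_half > 0:
            raise RuntimeError("fitted recovery half-time is non-positive")
        self.I0_ = float(I0)
        self.I_inf_ = float(I_inf)
        self.tau_half_ = float(tau_half)
        self.mobile_frac_ = float((I_inf - I0) / (1.0 - I0))

        # covariance from the Jacobian at the solution
        dof = max(t.size - 3, 1)
        s2 = 2.0 * sol.cost / dof
        try:
            cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
            self.tau_half_err_ = float(tau_half * math.sqrt(cov[2, 2]))
            dI0 = (I_inf - 1.0) / (1.0 - I0) ** 2
            dIinf = 1.0 / (1.0 - I0)
            self.mobile_frac_err_ = float(
                math.sqrt(
                    dI0**2 * cov[0, 0]
                    + dIinf**2 * cov[1, 1]
                    + 2 * dI0 * dIinf * cov[0, 1]
                )
            )
        except np.linalg.LinAlgError:
            self.tau_half_err_ = math.nan
            self.mobile_frac_err_ = math.nan

        # raw half-crossing, reported as a diagnostic only
        target = 0.5 * (self.I0_ + self.I_inf_)
        above = np.where(I >= target)[0]
        self.tau_half_raw_ = float(t[above[0]]) if above.size else math.nan

        if self.R_bleach is not None:
            self.tau_D_ = diffusion_timescale(self.tau_half_, self.R_bleach)
        self.n_features_in_ = 1
        return self

    def predict(self, t):
        check_is_fitted(self, "tau_half_")
        t = np.asarray(t, dtype=float).reshape(-1)
        return self.I_inf_ - (self.I_inf_ - self.I0_) * np.exp(
            -math.log(2.0) * t / self.tau_half_
        )


def fit_recovery(trace: FRAPTrace) -> FRAPRecoveryModel:
    """Fit the recovery of a full-scale normalized FRAP trace.

    Thin wrapper over :class:`FRAPRecoveryModel`: slices the trace at its
    bleach index, rebases time at the bleach event, and passes the bleach
    radius through so ``tau_D_`` is populated.
    """
    if not trace.normalized:
        raise ValueError("fit_recovery expects a normalized trace; "
                         "call normalize_frap first")
    t = trace.t[trace.i_bleach:] - trace.t[trace.i_bleach]
    I = trace.I[trace.i_bleach:]
    return FRAPRecoveryModel(R_bleach=trace.R_bleach).fit(t, I)


def diffusion_timescale(tau_half: float, R_bleach: float) -> float:
    """Apparent diffusion timescale τ_D = τ_half / R_bleach² (s/μm²)."""
    if not (tau_half > 0 and R_bleach > 0):
        raise ValueError("tau_half and R_bleach must be > 0")
    return tau_half / R_bleach**2
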