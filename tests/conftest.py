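import math

import numpy as np
import pytest

from microrheo.datatypes import NPAF, ModulusSpectrum
from microrheo.pmot import maxwell_moduli


@pytest.fixture
def make_npaf():
    """Build an NPAF container from a closed-form A(τ) on a uniform grid."""

    def _make(func, dt=1e-4, max_lag=5.0, n_total=1_200_000):
        lag = np.arange(int(round(max_lag / dt)) + 1, dtype=float) * dt
        A = np.asarray(func(lag), dtype=float)
        A[0] = 1.0
        return NPAF(lag=lag, A=A, n_pairs=(n_total - np.arange(lag.size)))

    return _make


@pytest.fixture
def make_maxwell_spectrum():
    """Exact Maxwell(+solvent) modulus spectrum on a log frequency grid."""

    def _make(G0, tau, eta_s=0.0, w_lo=1e-2, w_hi=1e4, n=120):
        omega = np.geomspace(w_lo, w_hi, n)
        Gp, Gpp = maxwell_moduli(omega, G0, tau, eta_s)
        return ModulusSpectrum(omega=omega, G_prime=Gp, G_dprime=Gpp)

    return _make


def jeffreys_acf_oracle(kappa, a, T, eta_s, G0, tau_M, lags):
    """Closed-form position ACF of the trapped bead in a Jeffreys bath,
    computed from the continuous 2x2 Ornstein-Uhlenbeck system via the
    Lyapunov equation and matrix exponentials (independent of the
    generator's sampling path)."""
    from scipy import linalg

    from microrheo.constants import KB_PNUM

    sa = 6.0 * math.pi * a
    k_m = sa * G0
    gamma_m = k_m * tau_M
    gamma_s = sa * eta_s
    kBT = KB_PNUM * T
    A = np.array(
        [
            [(kappa + k_m) / gamma_s, -k_m / gamma_s],
            [-k_m / gamma_m, k_m / gamma_m],
        ]
    )
    B = np.diag([2.0 * kBT / gamma_s, 2.0 * kBT / gamma_m])
    Sigma = linalg.solve_continuous_lyapunov(A, B)
    out = np.empty(len(lags))
    for i, tau in enumerate(lags):
        out[i] = (linalg.expm(-A * tau) @ Sigma)[0, 0]
    return out / Sigma[0, 0]
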