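"""Rouse modes, relaxation modulus, Green–Kubo viscosity, phase diagram."""

import math

import numpy as np
import pytest

import microrheo as m
from microrheo import polymer
from microrheo.constants import K_B, R_GAS
from microrheo.datatypes import ChainTrajectory, DensityProfile, StressSeries
from microrheo.polymer import (
    mode_autocorrelation,
    rouse_basis,
    rouse_tau_theory,
)


def _static_chain(coords_one_frame, n_frames=50, dt=0.1):
    coords = np.repeat(coords_one_frame[None, :, :], n_frames, axis=0)
    return ChainTrajectory(coords=coords, dt=dt, zeta=1.0, k_spring=1.0, T=300.0)


@pytest.fixture(scope="module")
def ideal_chain():
    p = m.ChainSimParams(N=10, k_spring=1.0, zeta=1.0, T=300.0, dt=0.05,
                         n_steps=240_000, save_stride=2, seed=0)
    return m.gen_chain_trajectory(p)


@pytest.fixture(scope="module")
def sticky_chain():
    # end-bead stickers binding to a lattice of sites: stationary,
    # hop-limited binding that retards the slow modes
    p = m.ChainSimParams(N=10, k_spring=1.0, zeta=1.0, T=300.0, dt=0.05,
                         n_steps=240_000, save_stride=2, seed=0,
                         sticker_indices=(0, 9), site_lattice=0.4,
                         epsilon=6.0, r_well=0.08)
    return m.gen_chain_trajectory(p)


class TestRouseModes:
    def test_static_chain_gives_constant_modes(self):
        rng = np.random.default_rng(0)
        traj = _static_chain(rng.standard_normal((8, 3)))
        for mode in m.rouse_modes(traj, p_max=7):
            assert np.ptp(mode.X, axis=0).max() < 1e-14

    def test_inverse_transform_reconstructs_coordinates(self):
        rng = np.random.default_rng(1)
        traj = _static_chain(rng.standard_normal((6, 3)), n_frames=3)
        N = 6
        modes = m.rouse_modes(traj, p_max=N - 1, include_com=True)
        rec = np.zeros_like(traj.coords)
        for mode in modes:
            basis = rouse_basis(N, mode.p)
            factor = 1.0 if mode.p == 0 else 2.0
            rec += factor * np.einsum("fd,n->fnd", mode.X, basis)
        np.testing.assert_allclose(rec, traj.coords, atol=1e-12)

    def test_two_bead_closed_form(self):
        r = np.array([[[0.0, 0, 0], [1.0, 2.0, 3.0]]])
        traj = ChainTrajectory(coords=r, dt=0.1, zeta=1.0, k_spring=1.0, T=300.0)
        (mode,) = m.rouse_modes(traj, p_max=1)
        expected = 0.5 * (r[0, 0] * math.cos(math.pi / 4)
                          + r[0, 1] * math.cos(3 * math.pi / 4))
        np.testing.assert_allclose(mode.X[0], expected, atol=1e-14)

    def test_mode_orthogonality_for_ideal_chain(self, ideal_chain):
        modes = m.rouse_modes(ideal_chain, p_max=3)
        burn = modes[0].X.shape[0] // 10
        X = np.stack([mo.X[burn:] for mo in modes])  # (p, frames, 3)
        X = X - X.mean(axis=1, keepdims=True)
        var = np.einsum("pfd,pfd->p", X, X)
        for i in range(3):
            for j in range(i + 1, 3):
                cross = abs(np.einsum("fd,fd->", X[i], X[j]))
                assert cross < 0.1 * math.sqrt(var[i] * var[j])

    def test_out_of_range_p_rejected(self, ideal_chain):
        with pytest.raises(ValueError, match="p_max"):
            m.rouse_modes(ideal_chain, p_max=10)


class TestModeRelaxation:
    def test_ideal_chain_matches_rouse_spectrum(self, ideal_chain):
        modes = m.rouse_modes(ideal_chain, p_max=3)
        taus = m.mode_relaxation_times(modes)
        for mr in taus:
            theory = rouse_tau_theory(10, mr.p, 1.0, 1.0)
            assert mr.resolved
            assert mr.tau == pytest.approx(theory, rel=0.15)
        # tau_p sin^2(p pi / 2N) constant across p
        scaled = [mr.tau * math.sin(mr.p * math.pi / 20) ** 2 for mr in taus]
        assert max(scaled) / min(scaled) < 1.3

    def test_mode_ratio_closed_form(self, ideal_chain):
        taus = m.mode_relaxation_times(m.rouse_modes(ideal_chain, p_max=2))
        expected = math.sin(2 * math.pi / 20) ** 2 / math.sin(math.pi / 20) ** 2
        assert expected == pytest.approx(3.9, abs=0.05)
        assert taus[0].tau / taus[1].tau == pytest.approx(expected, rel=0.2)

    def test_sticker_wells_retard_slowest_mode(self, ideal_chain, sticky_chain):
        # 6 kBT sticker wells on the end beads (where the slowest mode has
        # its largest amplitude) slow mode-1 relaxation well beyond noise
        tau_plain = m.mode_relaxation_times(m.rouse_modes(ideal_chain, 1))[0]
        tau_sticky = m.mode_relaxation_times(m.rouse_modes(sticky_chain, 1))[0]
        assert tau_plain.resolved and tau_sticky.resolved
        assert tau_sticky.tau > 1.5 * tau_plain.tau


class TestRelaxationModulus:
    def test_single_mode_squared_correlator_identity(self, ideal_chain):
        modes = m.rouse_modes(ideal_chain, p_max=1)
        lag, C = mode_autocorrelation(modes[0])
        modulus = m.relaxation_modulus(modes, p_max=1)
        np.testing.assert_allclose(modulus.G_norm, C**2, atol=1e-12)
        assert modulus.G_norm[0] == 1.0

    def test_ideal_chain_matches_closed_form_sum(self, ideal_chain):
        modulus = m.relaxation_modulus(m.rouse_modes(ideal_chain, p_max=3))
        theory = np.mean(
            [
                np.exp(-2 * modulus.t / rouse_tau_theory(10, p, 1.0, 1.0))
                for p in (1, 2, 3)
            ],
            axis=0,
        )
        window = modulus.t < 3 * rouse_tau_theory(10, 1, 1.0, 1.0)
        assert np.abs(modulus.G_norm[window] - theory[window]).max() < 0.1

    def test_sticky_modulus_lies_above_plain(self, ideal_chain, sticky_chain):
        plain = m.relaxation_modulus(m.rouse_modes(ideal_chain, p_max=3))
        sticky = m.relaxation_modulus(m.rouse_modes(sticky_chain, p_max=3))
        n = min(plain.G_norm.size, sticky.G_norm.size)
        resolved = (plain.G_norm[:n] > 0.05) & (plain.t[:n] > 0)
        assert np.all(
            sticky.G_norm[:n][resolved] >= plain.G_norm[:n][resolved] - 0.005
        )


class TestGreenKubo:
    def test_ou_stress_matches_analytic_integral(self):
        p = m.OUStressParams(amplitude_A=200.0, tau_c=0.01, V=1e-22, T=300.0,
                             dt=5e-4, n_steps=400_000, seed=3)
        gk = m.green_kubo_viscosity(m.gen_ou_stress(p))
        expected = p.V * p.amplitude_A * p.tau_c / (K_B * p.T)
        assert gk.eta == pytest.approx(expected, rel=0.10)

    def test_fit_and_plateau_methods_agree(self):
        p = m.OUStressParams(amplitude_A=100.0, tau_c=0.02, V=1e-22, T=300.0,
                             dt=1e-3, n_steps=400_000, seed=4)
        s = m.gen_ou_stress(p)
        eta_fit = m.green_kubo_viscosity(s, method="fit")
        eta_plateau = m.green_kubo_viscosity(s, method="plateau")
        assert eta_plateau.eta == pytest.approx(eta_fit.eta, rel=0.15)

    def test_constructed_condensate_scale_value(self):
        # A tau_c V / kB T chosen to equal 3.3 Pa.s
        T, V, tau_c = 300.0, 1e-22, 0.01
        A = 3.3 * K_B * T / (V * tau_c)
        p = m.OUStressParams(amplitude_A=A, tau_c=tau_c, V=V, T=T,
                             dt=5e-4, n_steps=400_000, seed=5)
        gk = m.green_kubo_viscosity(m.gen_ou_stress(p))
        assert gk.eta == pytest.approx(3.3, rel=0.10)

    def test_white_noise_stress_has_negligible_viscosity(self):
        rng = np.random.default_rng(6)
        t = np.arange(200_000) * 1e-3
        s = StressSeries(t=t, sigma_xy=rng.standard_normal(t.size) * 100.0,
                         V=1e-22, T=300.0)
        gk = m.green_kubo_viscosity(s)
        scale = s.V * 100.0**2 * 1e-3 / (K_B * 300.0)  # one-step integral scale
        assert abs(gk.eta) < scale

    def test_short_series_rejected(self):
        p = m.OUStressParams(tau_c=0.5, dt=0.01, n_steps=2000, seed=0)
        with pytest.raises(ValueError, match="100"):
            m.green_kubo_viscosity(m.gen_ou_stress(p))

    def test_arrhenius_composability_with_thermal_sweep(self):
        # Green-Kubo viscosities generated on an Arrhenius ladder feed the
        # thermorheology fitter and return the generating barrier
        E_A = 30e3
        temps = (280.0, 295.0, 310.0, 325.0)
        points = []
        for i, T in enumerate(temps):
            eta_true = 1e-4 * math.exp(E_A / (R_GAS * T))
            A = eta_true * K_B * T / (1e-22 * 0.01)
            p = m.OUStressParams(amplitude_A=A, tau_c=0.01, V=1e-22, T=T,
                                 dt=5e-4, n_steps=600_000, seed=100 + i)
            gk = m.green_kubo_viscosity(m.gen_ou_stress(p))
            points.append(m.ViscosityPoint(T=T, eta=gk.eta))
        fit = m.arrhenius_fit(points, random_state=0)
        assert fit.E_A_ == pytest.approx(E_A, rel=0.10)


class TestCoexistence:
    def test_noiseless_profile_recovered_exactly(self):
        p = m.SlabProfileParams(noise_sd=0.0, temperatures=(330.0,))
        (prof,) = m.gen_slab_profiles(p)
        point = m.fit_density_profile(prof)
        from microrheo.synthgen import coexistence_densities

        rho_l, rho_d = coexistence_densities(p, 330.0)
        assert point.rho_dense == pytest.approx(rho_d, rel=1e-3)
        assert point.rho_dilute == pytest.approx(rho_l, rel=1e-3)
        assert point.coexisting

    def test_uniform_profile_flagged_no_coexistence(self):
        z = np.linspace(-15, 15, 200)
        rng = np.random.default_rng(2)
        prof = DensityProfile(z=z, rho=300.0 + rng.standard_normal(200), T=400.0)
        assert not m.fit_density_profile(prof).coexisting

    def test_noisy_profiles_monte_carlo(self):
        from microrheo.synthgen import coexistence_densities

        # moderately subcritical so both coexisting densities are O(100)
        # and a 5% of rho_dense noise floor leaves them resolvable
        ok = 0
        T = 420.0
        base = m.SlabProfileParams(temperatures=(T,))
        rho_l, rho_d = coexistence_densities(base, T)
        for seed in range(100):
            p = m.SlabProfileParams(temperatures=(T,),
                                    noise_sd=0.05 * rho_d, seed=seed)
            (prof,) = m.gen_slab_profiles(p)
            point = m.fit_density_profile(prof)
            if (abs(point.rho_dense / rho_d - 1) < 0.05
                    and abs(point.rho_dilute / rho_l - 1) < 0.05):
                ok += 1
        assert ok >= 95


class TestCriticalPoint:
    def test_noiseless_tc_recovery(self):
        p = m.SlabProfileParams(noise_sd=0.0, Tc_true=450.0)
        points = [m.fit_density_profile(pr) for pr in m.gen_slab_profiles(p)]
        fit = m.estimate_tc(points)
        assert fit.Tc_ == pytest.approx(450.0, abs=0.5)
        assert fit.rho_c_ == pytest.approx(p.rho_c, rel=0.01)

    def test_noisy_tc_monte_carlo(self):
        errs = []
        for seed in range(60):
            p = m.SlabProfileParams(noise_sd=0.02 * 1000.0, Tc_true=450.0, seed=seed)
            points = [m.fit_density_profile(pr) for pr in m.gen_slab_profiles(p)]
            errs.append(abs(m.estimate_tc(points).Tc_ / 450.0 - 1))
        assert np.quantile(errs, 0.9) < 0.02

    def test_too_few_temperatures_rejected(self):
        p = m.SlabProfileParams(noise_sd=0.0, temperatures=(300.0, 330.0, 360.0))
        points = [m.fit_density_profile(pr) for pr in m.gen_slab_profiles(p)]
        with pytest.raises(ValueError, match=">= 4"):
            m.estimate_tc(points)

    def test_non_monotonic_gap_rejected(self):
        pts = [
            polymer.CoexistencePoint(T=300.0, rho_dilute=100.0, rho_dense=900.0),
            polymer.CoexistencePoint(T=330.0, rho_dilute=150.0, rho_dense=850.0),
            polymer.CoexistencePoint(T=360.0, rho_dilute=120.0, rho_dense=880.0),
            polymer.CoexistencePoint(T=390.0, rho_dilute=200.0, rho_dense=800.0),
        ]
        with pytest.raises(ValueError, match="monotonically"):
            m.estimate_tc(pts)
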