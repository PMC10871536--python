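"""Particle-tracking rheology: MSD, diffusivity, Stokes–Einstein, Arrhenius."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microrheo as m
from microrheo.constants import KB_PNUM, R_GAS
from microrheo.datatypes import MSDCurve, ParticleTrackSet, ViscosityPoint
from microrheo.vpt import _msd_1d


def _trackset(frames, dt=1.0, T=300.0, a=0.1):
    dfs = []
    for pid, (x, y) in enumerate(frames):
        t = np.arange(len(x), dtype=float) * dt
        dfs.append(pd.DataFrame({"particle_id": pid, "t": t, "x": x, "y": y}))
    return ParticleTrackSet(tracks=pd.concat(dfs, ignore_index=True),
                            T=T, a=a, dt_frame=dt)


class TestMSD:
    def test_hand_enumerated_displacement_pairs(self):
        # x = [0,1,2,3]: all ordered pairs give MSD(1)=1, MSD(2)=4, MSD(3)=9
        np.testing.assert_allclose(
            _msd_1d(np.array([0.0, 1.0, 2.0, 3.0])), [0.0, 1.0, 4.0, 9.0],
            atol=1e-10,
        )

    def test_linear_track_ensemble_average(self):
        x = np.arange(9.0)
        ts = _trackset([(x, np.zeros_like(x))])
        msd = m.compute_msd(ts)
        assert msd.msd[0] == pytest.approx(0.0, abs=1e-10)
        assert msd.msd[1] == pytest.approx(1.0, abs=1e-10)
        assert msd.msd[2] == pytest.approx(4.0, abs=1e-10)

    def test_stationary_track_has_zero_msd(self):
        x = np.zeros(50)
        ts = _trackset([(x, x)])
        np.testing.assert_allclose(m.compute_msd(ts).msd, 0.0, atol=1e-12)

    def test_short_tracks_excluded_with_warning(self):
        good = (np.arange(50.0), np.zeros(50))
        short = (np.zeros(3), np.zeros(3))
        with pytest.warns(UserWarning, match="excluded"):
            msd = m.compute_msd(_trackset([good, short]))
        assert msd.msd[1] == pytest.approx(1.0, abs=1e-10)

    def test_all_tracks_excluded_is_error(self):
        short = (np.zeros(3), np.zeros(3))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="nothing to average"):
                m.compute_msd(_trackset([short]))

    def test_brownian_tracks_recover_einstein_slope(self):
        p = m.VPTSimParams(E_A=0.0, eta_ref=1.0, temperatures=(300.15,),
                           sigma_loc=0.0, n_frames=1500, n_particles=8, seed=5)
        (ts,) = m.gen_vpt_tracks(p)
        D = KB_PNUM * 300.15 / (6 * math.pi * p.a * 1.0)
        msd = m.compute_msd(ts)
        fit = m.fit_diffusivity(msd, model="powerlaw", fit_window=(0, 2.0))
        assert fit.D_ == pytest.approx(D, rel=0.10)


class TestDiffusivityFit:
    def test_ballistic_exponent(self):
        lag = np.linspace(0.1, 10, 50)
        msd = MSDCurve(lag=lag, msd=0.3 * lag**2, n_pairs=np.full(50, 100.0))
        fit = m.fit_diffusivity(msd, model="powerlaw")
        assert fit.alpha_ == pytest.approx(2.0, abs=1e-9)

    def test_exact_diffusive_curve_self_consistency(self):
        D = 0.001
        lag = np.linspace(0.0, 10, 101)
        msd = MSDCurve(lag=lag, msd=4 * D * lag, n_pairs=np.full(101, 100.0))
        for model in ("powerlaw", "linear+offset"):
            fit = m.fit_diffusivity(msd, model=model)
            assert fit.D_ == pytest.approx(D, rel=1e-3)
        assert m.fit_diffusivity(msd, model="powerlaw").alpha_ == pytest.approx(
            1.0, abs=1e-6
        )

    def test_offset_model_beats_powerlaw_under_localization_noise(self):
        # Monte-Carlo: with sigma_loc = 0.02 um the offset model stays
        # unbiased while the raw power law under-reads alpha at short lags
        D_true = 2e-4
        sigma = 0.02
        D_offsets, alphas_raw = [], []
        for seed in range(30):
            p = m.VPTSimParams(E_A=0.0, eta_ref=KB_PNUM * 300.15 / (6 * math.pi * 0.1 * D_true),
                               T_ref=300.15, temperatures=(300.15,),
                               sigma_loc=sigma, n_frames=600, n_particles=10,
                               dt_frame=0.1, seed=seed)
            (ts,) = m.gen_vpt_tracks(p)
            msd = m.compute_msd(ts)
            fit = m.fit_diffusivity(msd, fit_window=(0, 2.05))
            D_offsets.append(fit.D_)
            raw = m.fit_diffusivity(msd, model="powerlaw", fit_window=(0, 2.05))
            alphas_raw.append(raw.alpha_)
        assert np.mean(D_offsets) == pytest.approx(D_true, rel=0.10)
        assert np.mean(alphas_raw) < 0.9  # noise floor flattens short lags

    def test_offset_absorbs_localization_floor(self):
        sigma = 0.05
        lag = np.linspace(0.0, 10, 101)
        msd = MSDCurve(lag=lag, msd=4 * 0.01 * lag + 4 * sigma**2,
                       n_pairs=np.full(101, 50.0))
        fit = m.fit_diffusivity(msd, model="linear+offset")
        assert fit.offset_ == pytest.approx(4 * sigma**2, rel=1e-6)
        assert fit.D_ == pytest.approx(0.01, rel=1e-6)

    def test_nonpositive_msd_rejected_by_powerlaw(self):
        lag = np.linspace(0.0, 5, 30)
        msd = MSDCurve(lag=lag, msd=np.zeros(30), n_pairs=np.full(30, 10.0))
        with pytest.raises(ValueError, match="non-positive"):
            m.fit_diffusivity(msd, model="powerlaw")


class TestStokesEinstein:
    def test_identity(self):
        D = KB_PNUM * 300.0 / (6 * math.pi * 0.1 * 1.0)
        assert m.viscosity_from_D(D, 0.1, 300.0).eta == pytest.approx(1.0, rel=1e-12)

    def test_paper_scale_arithmetic(self):
        point = m.viscosity_from_D(6.66e-4, 0.1, 300.15)
        assert point.eta == pytest.approx(3.3, rel=0.01)

    def test_error_propagation(self):
        point = m.viscosity_from_D(1e-3, 0.1, 300.0, D_err=1e-4)
        assert point.eta_err == pytest.approx(0.1 * point.eta, rel=1e-12)

    @given(scale=st.floats(min_value=0.5, max_value=4.0))
    @settings(max_examples=25, deadline=None)
    def test_radius_scaling(self, scale):
        base = m.viscosity_from_D(1e-3, 0.1, 300.0).eta
        assert m.viscosity_from_D(1e-3, 0.1 * scale, 300.0).eta == pytest.approx(
            base / scale, rel=1e-9
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.viscosity_from_D(-1e-3, 0.1, 300.0)


def _points_on_arrhenius(E_A, eta0, temps, c=0.0):
    return [
        ViscosityPoint(T=T, eta=eta0 * math.exp(E_A / (R_GAS * T)) + c)
        for T in temps
    ]


class TestArrhenius:
    TEMPS = (284.15, 295.15, 308.15, 328.15)

    def test_constant_viscosity_has_zero_activation_energy(self):
        points = [ViscosityPoint(T=T, eta=2.0) for T in self.TEMPS]
        fit = m.arrhenius_fit(points)
        assert abs(fit.E_A_RT_) < 1e-9

    def test_two_point_closed_form_slope(self):
        # E_A = R ln(eta1/eta2) / (1/T1 - 1/T2) for points on the exact line
        E_expected = R_GAS * math.log(3.3 / 0.784) / (1 / 300.15 - 1 / 328.15)
        assert E_expected == pytest.approx(42.0e3, rel=0.005)
        eta0 = 3.3 / math.exp(E_expected / (R_GAS * 300.15))
        points = _points_on_arrhenius(E_expected, eta0, (300.15, 310.15, 320.15, 328.15))
        fit = m.arrhenius_fit(points)
        assert fit.E_A_ == pytest.approx(E_expected, rel=1e-6)

    def test_noiseless_grid_recovered_exactly(self):
        E_A = 42.14e3
        points = _points_on_arrhenius(E_A, 1e-7, self.TEMPS)
        for form in ("linear", "exp+const"):
            fit = m.arrhenius_fit(points, form=form)
            assert fit.E_A_ == pytest.approx(E_A, rel=1e-3)

    def test_exp_const_form_recovers_additive_offset(self):
        E_A = 40e3
        points = _points_on_arrhenius(E_A, 1e-7, (280.0, 290.0, 300.0, 310.0, 320.0),
                                      c=0.5)
        fit = m.arrhenius_fit(points, form="exp+const")
        assert fit.offset_c_ == pytest.approx(0.5, rel=0.01)
        assert fit.E_A_ == pytest.approx(E_A, rel=0.01)

    def test_linear_and_exp_forms_agree_on_clean_data(self):
        E_A = 35e3
        points = _points_on_arrhenius(
            E_A, 1e-6, (280.0, 292.0, 304.0, 316.0, 328.0)
        )
        lin = m.arrhenius_fit(points, form="linear")
        exp = m.arrhenius_fit(points, form="exp+const")
        assert abs(lin.E_A_ - exp.E_A_) < 1e-3 * E_A

    def test_small_temperature_span_rejected(self):
        points = _points_on_arrhenius(40e3, 1e-6, (300.0, 305.0, 310.0, 315.0))
        with pytest.raises(ValueError, match="span"):
            m.arrhenius_fit(points)

    def test_fitted_viscosity_decreases_with_temperature(self):
        points = _points_on_arrhenius(42e3, 1e-7, self.TEMPS)
        fit = m.arrhenius_fit(points, form="exp+const")
        T = np.linspace(284.0, 328.0, 40)
        assert np.all(np.diff(fit.predict(T)) < 0)

    def test_bootstrap_error_is_seeded(self):
        rng = np.random.default_rng(0)
        points = [
            ViscosityPoint(T=T, eta=1e-6 * math.exp(42e3 / (R_GAS * T))
                           * (1 + 0.05 * rng.standard_normal()))
            for T in (280.0, 292.0, 304.0, 316.0, 328.0)
        ]
        a = m.arrhenius_fit(points, random_state=7)
        b = m.arrhenius_fit(points, random_state=7)
        assert a.E_A_err_ == b.E_A_err_ and a.E_A_err_ > 0


class TestActivationEnergyConversion:
    def test_17_RT_is_about_42_kJ_per_mol(self):
        E_A = 17 * R_GAS * 298.15
        out = m.convert_activation_energy(E_A)
        assert out["E_A_kJmol"] == pytest.approx(42.1, rel=0.01)
        assert out["E_A_RT"] == pytest.approx(17.0, rel=1e-12)

    def test_zero_maps_to_zero(self):
        out = m.convert_activation_energy(0.0)
        assert out["E_A_RT"] == 0.0 and out["E_A_kJmol"] == 0.0

    def test_26_RT(self):
        out = m.convert_activation_energy(26 * R_GAS * 298.15)
        assert out["E_A_kJmol"] == pytest.approx(26 * 8.3145 * 298.15 / 1000, rel=1e-4)

    @given(rt=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_through_joules(self, rt):
        E_A = rt * R_GAS * 298.15
        assert m.convert_activation_energy(E_A)["E_A_RT"] == pytest.approx(
            rt, rel=1e-12
        )


class TestEndToEnd:
    def test_activation_energy_recovered_from_tracks(self):
        E_A = 17 * R_GAS * 298.15
        params = m.VPTSimParams(E_A=E_A, eta_ref=3.3, T_ref=300.15, seed=0)
        points, diag = m.viscosity_vs_temperature(m.gen_vpt_tracks(params))
        assert len(points) >= 4
        fit = m.arrhenius_fit(points, random_state=0)
        assert fit.E_A_RT_ == pytest.approx(17.0, abs=2.0)

    def test_prefactor_change_leaves_slope_invariant(self):
        # datasets with eta_ref differing 10x share the Arrhenius slope
        E_A = 17 * R_GAS * 298.15
        fits = []
        for eta_ref, seed in [(3.3, 0), (33.0, 1)]:
            params = m.VPTSimParams(E_A=E_A, eta_ref=eta_ref, T_ref=300.15, seed=seed)
            points, _ = m.viscosity_vs_temperature(m.gen_vpt_tracks(params))
            fits.append(m.arrhenius_fit(points, random_state=seed))
        joint = math.hypot(fits[0].E_A_err_, fits[1].E_A_err_)
        assert abs(fits[0].E_A_ - fits[1].E_A_) < joint
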