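"""Helicity, Boltzmann fits, van't Hoff enthalpy and LEM free energies."""

import numpy as np
import pytest

from apostab import (
    boltzmann_fit,
    chem_denat_midpoint,
    helicity_from_theta222,
    lem_free_energy,
    vant_hoff_dH,
)
from apostab.estimators import BoltzmannSigmoid
from apostab.thermo import ChemDenatSeries, R_KCAL, mean_residue_ellipticity
from apostab.synthetic import simulate_cd_thermal, simulate_chem_denat


class TestHelicity:
    @pytest.mark.parametrize("theta,expected", [(3000.0, 0.0), (-36000.0, 100.0), (-16500.0, 50.0)])
    def test_calibration_anchors(self, theta, expected):
        res = helicity_from_theta222(theta)
        assert res.percent_helix == pytest.approx(expected)
        assert not res.clamped

    @pytest.mark.parametrize("theta,expected", [(10000.0, 0.0), (-50000.0, 100.0)])
    def test_out_of_range_clamped_and_flagged(self, theta, expected):
        res = helicity_from_theta222(theta)
        assert res.percent_helix == expected and res.clamped

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            helicity_from_theta222(float("nan"))

    def test_order_preserving(self):
        thetas = np.linspace(-30000, 0, 20)
        helix = [helicity_from_theta222(t).percent_helix for t in thetas]
        assert all(a >= b for a, b in zip(helix, helix[1:]))

    def test_mre_conversion(self):
        # 10 mdeg, 0.1 mg/ml, 0.1 cm path, MRW 115.4
        assert mean_residue_ellipticity(10.0, 0.1, 0.1) == pytest.approx(11540.0)


class TestBoltzmannFit:
    def test_selffit_recovers_parameters(self):
        x = np.linspace(20, 80, 61)
        y = 2.0 + (10.0 - 2.0) / (1.0 + np.exp((55.0 - x) / 3.0))
        fit = boltzmann_fit(x, y)
        assert fit.converged
        assert fit.midpoint == pytest.approx(55.0, rel=1e-6)
        assert fit.width == pytest.approx(3.0, rel=1e-6)

    def test_decreasing_orientation_handled(self):
        # CD: theta222 rises (less negative) through the transition; fit the
        # mirrored case where the signal falls instead
        x = np.linspace(20, 80, 61)
        y = 10.0 + (2.0 - 10.0) / (1.0 + np.exp((50.0 - x) / 4.0))
        fit = boltzmann_fit(x, y)
        assert fit.converged
        assert fit.midpoint == pytest.approx(50.0, rel=1e-6)
        assert fit.post < fit.pre

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_fit(np.arange(5.0), np.arange(5.0))

    def test_midpoint_outside_data_flagged_extrapolated(self):
        x = np.linspace(20, 40, 21)
        y = 1.0 / (1.0 + np.exp((55.0 - x) / 3.0))
        fit = boltzmann_fit(x, y)
        assert fit.extrapolated

    def test_sklearn_param_interface(self):
        est = BoltzmannSigmoid(sloped_baselines=True)
        assert est.get_params() == {"sloped_baselines": True}
        est.set_params(sloped_baselines=False)
        assert not est.sloped_baselines


class TestVantHoff:
    def test_closed_form_value(self):
        # Tm = 320 K (46.85 C), a = 2 K -> dH = R*320^2/2
        fit = boltzmann_fit(np.linspace(20, 80, 61),
                            1.0 / (1.0 + np.exp((46.85 - np.linspace(20, 80, 61)) / 2.0)))
        dh = vant_hoff_dH(fit)
        assert dh == pytest.approx(R_KCAL * 320.0**2 / 2.0, rel=1e-3)
        assert dh == pytest.approx(101.7, rel=1e-2)

    def test_broad_transition_gives_small_dh(self):
        x = np.linspace(20, 80, 61)
        broad = boltzmann_fit(x, 1.0 / (1.0 + np.exp((50.0 - x) / 12.0)))
        sharp = boltzmann_fit(x, 1.0 / (1.0 + np.exp((50.0 - x) / 2.0)))
        assert vant_hoff_dH(broad) < vant_hoff_dH(sharp) / 5

    def test_scale_invariance_of_observable(self):
        x = np.linspace(20, 80, 61)
        y = 1.0 / (1.0 + np.exp((50.0 - x) / 3.0))
        dh1 = vant_hoff_dH(boltzmann_fit(x, y))
        dh2 = vant_hoff_dH(boltzmann_fit(x, 1e4 * y - 2e4))
        assert dh1 == pytest.approx(dh2, rel=1e-6)

    @pytest.mark.parametrize("dh,tm", [(50.0, 47.0), (35.0, 47.0), (55.0, 65.0)])
    def test_roundtrip_from_generative_model(self, dh, tm):
        scan = simulate_cd_thermal(-18450.0, -4000.0, tm, dh)
        fit = boltzmann_fit(scan.temperatures, scan.theta222)
        assert vant_hoff_dH(fit) == pytest.approx(dh, rel=0.02)


class TestChemDenat:
    def test_noiseless_midpoint_is_dg0_over_m(self):
        series = simulate_chem_denat(5.0, 2.0)
        fit = chem_denat_midpoint(series)
        assert fit.converged
        assert fit.d_half == pytest.approx(2.5, rel=1e-6)

    def test_short_series_rejected(self):
        series = ChemDenatSeries("wt", [0.0, 3.0], [335.0, 355.0])
        with pytest.raises(ValueError):
            chem_denat_midpoint(series)

    def test_noisy_midpoint_within_tolerance(self, rng):
        errs = []
        for _ in range(50):
            series = simulate_chem_denat(5.0, 2.0, noise_sd_nm=0.3, rng=rng)
            errs.append(abs(chem_denat_midpoint(series).d_half - 2.5))
        assert np.median(errs) < 0.1


class TestLEM:
    def test_noiseless_machine_precision_recovery(self):
        series = simulate_chem_denat(5.0, 2.0)
        lem = lem_free_energy(series)
        assert lem.dg0 == pytest.approx(5.0, abs=1e-8)
        assert lem.m_value == pytest.approx(2.0, abs=1e-8)
        assert lem.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_free_energy_zero_at_midpoint(self):
        series = simulate_chem_denat(5.0, 2.0)
        lem = lem_free_energy(series)
        assert lem.dg0 - lem.m_value * 2.5 == pytest.approx(0.0, abs=1e-8)

    def test_consistency_identity_under_noise(self, rng):
        devs = []
        for _ in range(50):
            series = simulate_chem_denat(5.0, 2.0, noise_sd_nm=0.3, rng=rng)
            fit = chem_denat_midpoint(series)
            lem = lem_free_energy(series, fit)
            devs.append(abs(lem.dg0 - lem.m_value * fit.d_half) / lem.dg0)
        assert max(devs) < 0.05

    def test_too_few_transition_points_rejected(self):
        # very sharp transition: almost no points with f_u in (0.1, 0.9)
        series = simulate_chem_denat(40.0, 16.0, conc_grid_M=np.arange(0.0, 6.5, 1.0))
        with pytest.raises(ValueError, match="need >= 3"):
            lem_free_energy(series)

    def test_noisy_dg0_within_ten_percent(self, rng):
        errs = []
        for _ in range(100):
            series = simulate_chem_denat(5.0, 2.0, noise_sd_nm=0.3, rng=rng)
            errs.append(abs(lem_free_energy(series).dg0 - 5.0) / 5.0)
        assert np.median(errs) < 0.10
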