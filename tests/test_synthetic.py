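"""Generators: rosters, melt curves, screens, spectra, titrations; determinism."""

import hashlib
import pickle

import numpy as np
import pytest

from apostab.synthetic import (
    LibraryDef,
    ThermoModelParams,
    default_grid,
    fraction_unfolded,
    make_library_roster,
    paper_default,
    simulate_chem_denat,
    simulate_itc,
    simulate_melt_curve,
    simulate_screen,
    simulate_tm_dose,
)


class TestRoster:
    def test_study_libraries_total_956(self):
        roster = make_library_roster([LibraryDef("Pfizer", 81), LibraryDef("FDA", 875)])
        assert len(roster) == 956
        assert len({(r.plate, r.well) for r in roster}) == 956
        assert sum(r.library == "Pfizer" for r in roster) == 81

    def test_single_compound_at_plate1_a1(self):
        roster = make_library_roster([LibraryDef("X", 1)])
        assert roster[0].plate == 1 and roster[0].well == "A1"

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            make_library_roster([LibraryDef("X", 0)])


class TestMeltCurveModel:
    def test_half_unfolded_at_midpoint(self):
        grid = default_grid()
        assert fraction_unfolded(np.array([47.0]), 47.0, 35.0)[0] == pytest.approx(0.5, abs=1e-12)
        p = ThermoModelParams(tm_c=47.0, dh_vh=35.0)
        curve = simulate_melt_curve(p, grid)
        i = int(np.flatnonzero(grid == 47.0)[0])
        assert curve.fluorescence[i] == pytest.approx((p.f_base + p.f_amp) / 2.0, rel=1e-12)

    def test_noiseless_curve_nondecreasing_without_decay(self):
        curve = simulate_melt_curve(ThermoModelParams(47.0, 35.0), default_grid())
        assert np.all(np.diff(curve.fluorescence) >= 0)

    def test_two_state_fractions_sum_to_one(self):
        grid = default_grid()
        f = fraction_unfolded(grid, 47.0, 35.0)
        np.testing.assert_array_equal(f + (1.0 - f), np.ones_like(f))
        assert np.all(np.diff(f) > 0)

    def test_decay_produces_interior_maximum_above_tm(self):
        curve = simulate_melt_curve(
            ThermoModelParams(47.0, 35.0, decay_rate=0.05), default_grid())
        i = int(np.argmax(curve.fluorescence))
        assert 0 < i < len(curve.temperatures) - 1
        assert curve.temperatures[i] > 47.0

    def test_midpoint_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_melt_curve(ThermoModelParams(90.0, 35.0), default_grid())

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_melt_curve(ThermoModelParams(25.0, 35.0), [20.0, 24.0, 28.0, 32.0])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ThermoModelParams(47.0, -1.0)
        with pytest.raises(ValueError):
            ThermoModelParams(47.0, 35.0, decay_rate=-0.1)


class TestScreenSimulation:
    def test_paper_default_plants_18_wt_like_wells(self, scenario):
        plates = simulate_screen(scenario, seed=7)
        wt_like = [rec for rec, curve in plates.samples
                   if curve.metadata["params"].tm_c == scenario.wt.tm_c]
        assert len(wt_like) == 18
        assert sum(r.library == "Pfizer" for r in wt_like) == 7
        assert sum(r.library == "FDA" for r in wt_like) == 11

    def test_no_planted_hits_means_all_mutant(self, scenario):
        scen = paper_default()
        scen.hits = {"Pfizer": [], "FDA": []}
        plates = simulate_screen(scen, seed=7)
        assert all(c.metadata["params"].tm_c == scen.mutant.tm_c for _, c in plates.samples)

    def test_references_present_per_plate(self, scenario):
        plates = simulate_screen(scenario, seed=7)
        plate_ids = {rec.plate for rec, _ in plates.samples}
        assert set(plates.wt_refs) == plate_ids == set(plates.mut_refs)

    def test_determinism_byte_identical(self):
        # noisy variant: seed must matter, and equal seeds must reproduce bytes
        scen = paper_default()
        scen.wt = ThermoModelParams(65.0, 55.0, noise_sd=50.0)
        scen.mutant = ThermoModelParams(47.0, 35.0, noise_sd=50.0)
        scen.libraries = [LibraryDef("Pfizer", 40)]
        scen.hits = {"Pfizer": [8]}
        scen.named_compounds = {}

        def digest(seed):
            plates = simulate_screen(scen, seed=seed)
            payload = [(rec.compound_id, c.temperatures.tobytes(), c.fluorescence.tobytes())
                       for rec, c in plates.samples]
            payload += [(k, v.fluorescence.tobytes()) for k, v in sorted(plates.compound_alone.items())]
            return hashlib.sha256(pickle.dumps(payload)).hexdigest()

        assert digest(42) == digest(42)
        assert digest(42) != digest(43)

    def test_interference_wells_have_large_compound_alone_range(self, scenario):
        scen = paper_default()
        scen.interference = ["FDA-002"]
        plates = simulate_screen(scen, seed=7)
        quiet = plates.compound_alone["FDA-003"].dynamic_range
        loud = plates.compound_alone["FDA-002"].dynamic_range
        assert loud > 100 * max(quiet, 1e-9)


class TestScenarioValidation:
    def test_hit_index_out_of_range_rejected(self):
        scen = paper_default()
        with pytest.raises(ValueError, match="out of range"):
            type(scen)(**{**scen.__dict__, "hits": {"Pfizer": [99]}})

    def test_unknown_library_rejected(self):
        scen = paper_default()
        with pytest.raises(ValueError, match="unknown library"):
            type(scen)(**{**scen.__dict__, "hits": {"Nope": [1]}})

    def test_named_compounds_are_planted_hits(self, scenario):
        hit_ids = scenario.hit_ids()
        for name, loc in scenario.named_compounds.items():
            cid = f"{loc['library']}-{loc['index']:03d}"
            assert cid in hit_ids
            assert scenario.compound_name(cid) == name


class TestOtherGenerators:
    def test_chem_denat_limits(self):
        series = simulate_chem_denat(5.0, 2.0, lam_f_nm=335.0, lam_u_nm=355.0)
        i = int(np.argmin(np.abs(series.denaturant_M - 2.5)))
        assert series.lambda_max_nm[i] == pytest.approx(345.0, abs=1e-9)  # midpoint at D = dg0/m
        assert series.lambda_max_nm[0] == pytest.approx(335.0, abs=0.01)  # folded at D=0
        assert np.all(np.diff(series.lambda_max_nm) > 0)

    def test_chem_denat_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_chem_denat(-1.0, 2.0)
        with pytest.raises(ValueError):
            simulate_chem_denat(5.0, 2.0, lam_f_nm=355.0, lam_u_nm=335.0)
        with pytest.raises(ValueError):
            simulate_chem_denat(5.0, 2.0, conc_grid_M=[])

    def test_tm_dose_anchor_points(self):
        s = simulate_tm_dose(0.1, 47.0, 18.0, [0.0, 0.05, 0.1, 0.2, 1e6])
        assert s.tm_c[0] == 47.0
        assert s.tm_c[2] == pytest.approx(47.0 + 9.0)
        assert s.tm_c[-1] == pytest.approx(65.0, abs=1e-3)

    def test_itc_zero_qmax_gives_zero_corrected_heats(self):
        exp = simulate_itc(0.4, 0.0)
        np.testing.assert_allclose(exp.heats - exp.blank_heats, 0.0, atol=1e-12)

    def test_itc_concentration_passes_through_ec50(self):
        from apostab import correct_itc
        exp = simulate_itc(0.40, 100.0, syringe_conc_mM=5.0, n_injections=50)
        _, conc = correct_itc(exp)
        assert conc[0] < 0.40 < conc[-1]
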