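"""Hit calling against WT/mutant references and the ANS orthogonal screen."""

import numpy as np
import pytest

from apostab import (
    HitCriteria,
    ans_peak,
    ans_ratio_test,
    normalized_curve_rmsd,
    select_hits,
    tm_from_curve,
)
from apostab.meltcurves import MeltCurve
from apostab.screening import AnsSpectrum, CompoundRecord
from apostab.synthetic import simulate_ans_replicates, simulate_ans_spectrum, simulate_melt_curve


def affine(curve, a, b):
    return MeltCurve(curve.well, curve.temperatures, a * curve.fluorescence + b)


class TestNormalizedCurveRmsd:
    def test_identical_curves_zero(self, wt_curve):
        assert normalized_curve_rmsd(wt_curve, wt_curve) == 0.0

    def test_vertical_affine_invariance(self, wt_curve):
        assert normalized_curve_rmsd(wt_curve, affine(wt_curve, 3.7, -120.0)) == pytest.approx(0.0, abs=1e-12)

    def test_wt_vs_mutant_fixtures_exceed_threshold(self, wt_curve, mut_curve):
        # regression value computed on the default fixtures
        rmsd = normalized_curve_rmsd(wt_curve, mut_curve)
        assert rmsd == pytest.approx(0.384, abs=0.01)
        assert rmsd > HitCriteria().max_curve_rmsd

    def test_non_overlapping_ranges_rejected(self):
        a = MeltCurve("A1", np.linspace(20, 40, 21), np.linspace(0, 1, 21))
        b = MeltCurve("A2", np.linspace(50, 80, 31), np.linspace(0, 1, 31))
        with pytest.raises(ValueError):
            normalized_curve_rmsd(a, b)


def make_wells(scenario, grid, params_list):
    wells = []
    for i, params in enumerate(params_list):
        rec = CompoundRecord(f"C-{i:03d}", "lib", 1, f"A{i + 1}")
        curve = simulate_melt_curve(params, grid, well=rec.well)
        wells.append((rec, curve, tm_from_curve(curve)))
    return wells


@pytest.fixture()
def refs(scenario, grid, wt_curve, mut_curve):
    return ((tm_from_curve(wt_curve), wt_curve), (tm_from_curve(mut_curve), mut_curve))


class TestSelectHits:
    def test_mutant_only_plate_has_no_hits(self, scenario, grid, refs):
        wells = make_wells(scenario, grid, [scenario.mutant] * 6)
        results = select_hits(wells, *refs)
        assert not any(r.hit for r in results)
        assert all(r.reason == "shift_below_min" for r in results)

    def test_wt_like_well_is_a_hit(self, scenario, grid, refs):
        results = select_hits(make_wells(scenario, grid, [scenario.wt]), *refs)
        assert results[0].hit

    def test_no_call_well_is_non_hit_with_reason(self, scenario, grid, refs):
        rec = CompoundRecord("C-000", "lib", 1, "A1")
        flat = MeltCurve("A1", grid, np.full(len(grid), 500.0))
        results = select_hits([(rec, flat, tm_from_curve(flat))], *refs)
        assert not results[0].hit and results[0].reason == "no_tm_call"

    def test_interference_excludes_well(self, scenario, grid, refs):
        wells = make_wells(scenario, grid, [scenario.wt])
        big = wells[0][1].dynamic_range
        results = select_hits(
            wells, *refs,
            compound_alone_range={"C-000": big},
            median_sample_range=big,
        )
        assert results[0].interference and not results[0].hit

    def test_missing_reference_rejected(self, scenario, grid, refs):
        wells = make_wells(scenario, grid, [scenario.wt])
        bad_call = tm_from_curve(MeltCurve("A1", grid, np.full(len(grid), 1.0)))
        with pytest.raises(ValueError):
            select_hits(wells, (bad_call, wells[0][1]), refs[1])

    def test_monotone_in_criteria(self, scenario, grid, refs):
        from apostab.synthetic import ThermoModelParams
        params = [scenario.mutant, scenario.wt,
                  ThermoModelParams(tm_c=55.0, dh_vh=45.0),
                  ThermoModelParams(tm_c=62.0, dh_vh=50.0)]
        wells = make_wells(scenario, grid, params)
        strict = HitCriteria(min_shift=6.0, max_wt_gap=4.0, max_curve_rmsd=0.08)
        relaxed = HitCriteria(min_shift=3.0, max_wt_gap=8.0, max_curve_rmsd=0.2)
        hits_strict = {r.compound.compound_id for r in select_hits(wells, *refs, criteria=strict) if r.hit}
        hits_relaxed = {r.compound.compound_id for r in select_hits(wells, *refs, criteria=relaxed) if r.hit}
        assert hits_strict <= hits_relaxed

    def test_extreme_criteria_limits(self, scenario, grid, refs):
        from apostab.synthetic import ThermoModelParams
        wells = make_wells(scenario, grid,
                           [scenario.wt, ThermoModelParams(tm_c=55.0, dh_vh=45.0),
                            ThermoModelParams(tm_c=70.0, dh_vh=60.0)])
        none_crit = HitCriteria(min_shift=1e9)
        assert not any(r.hit for r in select_hits(wells, *refs, criteria=none_crit))
        all_crit = HitCriteria(min_shift=1e-9, max_wt_gap=1e9, max_curve_rmsd=1e9)
        results = select_hits(wells, *refs, criteria=all_crit)
        assert all(r.hit for r in results if r.call.ok and not r.interference)

    def test_permutation_safety(self, scenario, grid, refs, rng):
        from apostab.synthetic import ThermoModelParams
        params = [scenario.mutant, scenario.wt, ThermoModelParams(tm_c=58.0, dh_vh=45.0)] * 3
        wells = make_wells(scenario, grid, params)
        base = {r.compound.compound_id: r.hit for r in select_hits(wells, *refs)}
        shuffled = list(wells)
        rng.shuffle(shuffled)
        perm = {r.compound.compound_id: r.hit for r in select_hits(shuffled, *refs)}
        assert base == perm


class TestAnsPeak:
    def test_gaussian_band_peak_location(self):
        s = simulate_ans_spectrum(5.0, peak_nm=470.0)
        lam, intensity, flagged = ans_peak(s)
        assert abs(lam - 470.0) <= 1.0 and not flagged
        assert intensity == pytest.approx(5.0, rel=0.01)

    def test_flat_zero_spectrum_flagged(self):
        s = AnsSpectrum(np.arange(425.0, 601.0), np.zeros(176))
        _, intensity, flagged = ans_peak(s)
        assert flagged and intensity == 0.0

    def test_mutant_brighter_than_wt(self, scenario):
        wt = simulate_ans_spectrum(scenario.ans["wt_exposure"])
        mut = simulate_ans_spectrum(scenario.ans["mut_exposure"])
        assert ans_peak(mut)[1] > ans_peak(wt)[1]

    def test_corrected_mutant_close_to_wt(self, scenario):
        wt = simulate_ans_spectrum(scenario.ans["wt_exposure"])
        corrected = simulate_ans_spectrum(scenario.ans["corrected_exposure"])
        assert ans_peak(corrected)[1] == pytest.approx(ans_peak(wt)[1], rel=0.10)

    def test_out_of_band_grid_rejected(self):
        with pytest.raises(ValueError):
            AnsSpectrum(np.arange(400.0, 500.0), np.zeros(100))


class TestAnsRatio:
    def test_identical_spectra_ratio_one(self):
        s = [simulate_ans_spectrum(2.0) for _ in range(3)]
        res = ans_ratio_test(s, s, control_ratios=[0.5, 0.5, 0.5])
        assert res.ratio == pytest.approx(1.0, abs=1e-9)

    def test_double_intensity_gives_half_ratio(self):
        wt = [simulate_ans_spectrum(1.0) for _ in range(2)]
        mut = [simulate_ans_spectrum(2.0) for _ in range(2)]
        res = ans_ratio_test(wt, mut, control_ratios=[0.5, 0.5])
        assert res.ratio == pytest.approx(0.5, abs=1e-9)

    def test_scale_invariance(self, rng):
        wt, mut = simulate_ans_replicates(1.0, 2.0, rng=rng)
        control = [0.48, 0.50, 0.52]
        r1 = ans_ratio_test(wt, mut, control).ratio
        wt_scaled = [AnsSpectrum(s.wavelengths_nm, 7.0 * s.intensities) for s in wt]
        mut_scaled = [AnsSpectrum(s.wavelengths_nm, 7.0 * s.intensities) for s in mut]
        r2 = ans_ratio_test(wt_scaled, mut_scaled, control).ratio
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_corrector_fixture_passes_at_alpha(self, scenario, rng):
        cfg = scenario.ans
        wt0, mut0 = simulate_ans_replicates(cfg["wt_exposure"], cfg["mut_exposure"],
                                            noise_cv=cfg["noise_cv"], rng=rng)
        control = [ans_peak(w)[1] / ans_peak(m)[1] for w, m in zip(wt0, mut0)]
        wt, mut = simulate_ans_replicates(cfg["wt_exposure"], cfg["corrected_exposure"],
                                          noise_cv=cfg["noise_cv"], rng=rng)
        res = ans_ratio_test(wt, mut, control, alpha=0.01)
        assert res.passed

    def test_single_replicate_flagged_not_passed(self):
        wt = [simulate_ans_spectrum(1.0)]
        mut = [simulate_ans_spectrum(2.0)]
        res = ans_ratio_test(wt, mut, control_ratios=[0.5])
        assert not res.passed and "single_replicate" in res.flags and res.p_value is None
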