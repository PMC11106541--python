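"""End-to-end orchestration: screen -> ANS -> validation -> cell assays.

The pipeline runs the stages in the order a corrector-discovery campaign
does: the primary thermal-shift screen over the whole library, the ANS
orthogonal screen on the primary hits, concentration-dependent validation
(Tm dose-response EC50, ITC cross-check, CD/chemical-denaturation
thermodynamics) plus a macrophage-viability gate on the ANS-confirmed
candidates, and finally cholesterol-efflux recovery for the validated
correctors.  Every stage emits a TSV-able table; the report bundle carries
the funnel counts (screened -> TSA hits -> ANS-confirmed -> validated) and a
manifest sufficient to reproduce every table bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .cellassays import compare_groups, net_abca1_efflux, viability_percent
from .binding import correct_itc, fit_itc, fit_tm_dose
from .meltcurves import tm_from_curve
from .screening import HitCriteria, ans_peak, ans_ratio_test, select_hits
from .synthetic import ScreenScenario, simulate_screen
from .thermo import (
    boltzmann_fit,
    chem_denat_midpoint,
    helicity_from_theta222,
    lem_free_energy,
    vant_hoff_dH,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "write_report", "run_screen_stage"]

STAGES = ("screen", "ans", "validation", "cells")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    ``scenario_path`` None means the packaged ``paper_default`` scenario;
    ``seed`` None defers to the scenario's own seed.
    """

    scenario_path: str | None = None
    seed: int | None = None
    stages: tuple[str, ...] = STAGES
    criteria: HitCriteria = field(default_factory=HitCriteria)
    ans_alpha: float | None = None  # None -> scenario default
    min_viable_pct: float | None = None
    outdir: str | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.scenario_path is not None and not Path(self.scenario_path).exists():
            raise ValueError(f"scenario file not found: {self.scenario_path}")


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    funnel: dict[str, int] = field(default_factory=dict)
    failures: list[dict[str, str]] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _table_text(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", index=False, lineterminator="\n")


def run_screen_stage(scenario: ScreenScenario, criteria: HitCriteria, seed: int):
    """Simulate and call the primary screen; returns (table, hit ids, plates)."""
    plates = simulate_screen(scenario, seed=seed)
    median_range = float(np.median([c.dynamic_range for _, c in plates.samples]))
    flat_thr = 0.05 * median_range

    ref_calls = {}
    for plate in plates.wt_refs:
        wt_call = tm_from_curve(plates.wt_refs[plate], flat_threshold=flat_thr)
        mut_call = tm_from_curve(plates.mut_refs[plate], flat_threshold=flat_thr)
        ref_calls[plate] = (wt_call, mut_call)

    rows = []
    results = []
    for rec, curve in plates.samples:
        plate = rec.plate
        wt_call, mut_call = ref_calls[plate]
        call = tm_from_curve(curve, flat_threshold=flat_thr)
        alone = {rec.compound_id: plates.compound_alone[rec.compound_id].dynamic_range}
        res = select_hits(
            [(rec, curve, call)],
            wt_ref=(wt_call, plates.wt_refs[plate]),
            mut_ref=(mut_call, plates.mut_refs[plate]),
            criteria=criteria,
            compound_alone_range=alone,
            median_sample_range=median_range,
        )[0]
        results.append(res)
        rows.append({
            "compound": rec.compound_id,
            "library": rec.library,
            "plate": rec.plate,
            "well": rec.well,
            "tm_c": round(res.call.tm_c, 1) if res.call.ok else np.nan,
            "shift_c": round(res.shift_c, 1) if res.shift_c is not None else np.nan,
            "wt_gap_c": round(res.wt_gap_c, 1) if res.wt_gap_c is not None else np.nan,
            "curve_rmsd": round(res.curve_rmsd, 4) if res.curve_rmsd is not None else np.nan,
            "interference": res.interference,
            "hit": res.hit,
            "reason": res.reason,
        })
    table = pd.DataFrame(rows)
    hit_ids = [r.compound.compound_id for r in results if r.hit]
    return table, hit_ids, plates


def _ans_stage(scenario: ScreenScenario, hit_ids: list[str], seed: int):
    cfg = scenario.ans
    rng = np.random.default_rng(seed + 1)
    alpha = float(cfg.get("alpha", 0.01))
    correctors = set(cfg.get("correctors", []))
    n_rep = int(cfg.get("n_replicates", 3))
    cv = float(cfg.get("noise_cv", 0.02))
    peak = float(cfg.get("peak_nm", 470.0))

    wt0, mut0 = synthetic.simulate_ans_replicates(
        cfg["wt_exposure"], cfg["mut_exposure"], n_rep, cv, peak, rng)
    control_ratios = np.array([ans_peak(w)[1] / ans_peak(m)[1] for w, m in zip(wt0, mut0)])

    rows, passed = [], []
    for cid in sorted(hit_ids):
        name = scenario.compound_name(cid)
        mut_exposure = (cfg["corrected_exposure"]
                        if name in correctors else cfg["mut_exposure"])
        wt_reps, mut_reps = synthetic.simulate_ans_replicates(
            cfg["wt_exposure"], mut_exposure, n_rep, cv, peak, rng)
        res = ans_ratio_test(wt_reps, mut_reps, control_ratios, alpha=alpha, compound=cid)
        if res.passed:
            passed.append(cid)
        rows.append({
            "compound": cid,
            "name": name or "",
            "ratio": round(res.ratio, 4),
            "control_ratio": round(res.control_mean, 4),
            "p_value": np.nan if res.p_value is None else float(f"{res.p_value:.3e}"),
            "passed": res.passed,
        })
    return pd.DataFrame(rows), passed


def _validation_stage(scenario: ScreenScenario, candidate_ids: list[str],
                      criteria: HitCriteria, min_viable_pct: float, seed: int):
    dr, vb, itc_cfg = scenario.dose_response, scenario.viability, scenario.itc
    cd_cfg, chem_cfg = scenario.cd, scenario.chem_denat
    rng = np.random.default_rng(seed + 2)
    concs = np.asarray(dr["concs_mM"], dtype=float)
    tm0 = scenario.mutant.tm_c

    rows, validated = [], []
    for cid in sorted(candidate_ids):
        name = scenario.compound_name(cid)
        profile = dr["profiles"].get(name)
        if profile is None:
            rows.append({"compound": cid, "name": name or "", "ec50_tmdose_mM": np.nan,
                         "dtm_max_c": np.nan, "dose_pass": False, "ec50_itc_mM": np.nan,
                         "viability_pass": False, "validated": False,
                         "reason": "no_dose_profile"})
            continue
        series = synthetic.simulate_tm_dose(
            profile["ec50_mM"], tm0, profile["dtm_max_c"], concs,
            noise_sd=float(dr.get("noise_sd", 0.0)), rng=rng, compound=cid)
        fit = fit_tm_dose(series)
        dose_pass = bool(fit.converged and fit.amplitude >= criteria.min_shift)

        # viability at concentrations where the predicted Tm shift is corrective
        viab_profile = vb["profiles"].get(name, {})
        records = synthetic.simulate_viability(
            {float(k): float(v) for k, v in viab_profile.items()},
            n_replicates=int(vb.get("n_replicates", 3)),
            control_absorbance=float(vb.get("control_absorbance", 1.0)),
            noise_sd=float(vb.get("noise_sd", 0.0)), rng=rng, compound=cid)
        viable_effective = False
        for recd in records:
            shift = profile["dtm_max_c"] * recd.conc_mM / (profile["ec50_mM"] + recd.conc_mM)
            mean_pct, _ = viability_percent(recd)
            if shift >= criteria.min_shift and mean_pct >= min_viable_pct:
                viable_effective = True
                break

        # ITC cross-check where a titration profile exists
        ec50_itc = np.nan
        itc_profile = itc_cfg.get("profiles", {}).get(name)
        if itc_profile is not None:
            exp = synthetic.simulate_itc(
                itc_profile["ec50_mM"], itc_profile["q_max"],
                cell_conc_uM=float(itc_cfg["cell_conc_uM"]),
                cell_volume_ul=float(itc_cfg["cell_volume_ul"]),
                injection_volume_ul=float(itc_cfg["injection_volume_ul"]),
                syringe_conc_mM=itc_profile["syringe_conc_mM"],
                n_injections=int(itc_cfg["n_injections"]),
                dilution_heat=float(itc_cfg.get("dilution_heat", 0.0)),
                noise_sd=float(itc_cfg.get("noise_sd", 0.0)), rng=rng)
            heats, conc = correct_itc(exp)
            itc_fit = fit_itc(heats, conc)
            if itc_fit.converged:
                ec50_itc = itc_fit.ec50_mM

        ok = dose_pass and viable_effective
        if ok:
            validated.append(cid)
        reason = ("" if ok else
                  "no_dose_response" if not dose_pass else "toxic_at_effective_conc")
        rows.append({
            "compound": cid,
            "name": name or "",
            "ec50_tmdose_mM": round(fit.ec50_mM, 4) if fit.converged else np.nan,
            "dtm_max_c": round(fit.amplitude, 2) if fit.converged else np.nan,
            "dose_pass": dose_pass,
            "ec50_itc_mM": round(ec50_itc, 4) if np.isfinite(ec50_itc) else np.nan,
            "viability_pass": viable_effective,
            "validated": ok,
            "reason": reason,
        })

    # reference biophysics for both protein forms (helicity, dH, LEM)
    bio_rows = []
    for form in ("wt", "mutant"):
        cd_p = cd_cfg["profiles"][form]
        scan = synthetic.simulate_cd_thermal(
            cd_p["theta_native"], cd_p["theta_unfolded"], cd_p["tm_c"], cd_p["dh_vh"],
            noise_sd=float(cd_cfg.get("noise_sd", 0.0)), rng=rng, protein=form)
        fit = boltzmann_fit(scan.temperatures, scan.theta222, sloped_baselines=True)
        chem_p = chem_cfg["profiles"][form]
        series = synthetic.simulate_chem_denat(
            chem_p["dg0"], chem_p["m_value"],
            lam_f_nm=float(chem_cfg["lam_f_nm"]), lam_u_nm=float(chem_cfg["lam_u_nm"]),
            conc_grid_M=np.arange(0.0, float(chem_cfg["conc_max_M"]) + 1e-9,
                                  float(chem_cfg["conc_step_M"])),
            noise_sd_nm=float(chem_cfg.get("noise_sd_nm", 0.0)), rng=rng, protein=form)
        cfit = chem_denat_midpoint(series)
        lem = lem_free_energy(series, cfit)
        bio_rows.append({
            "protein": form,
            "helix_pct": round(helicity_from_theta222(cd_p["theta_native"]).percent_helix, 1),
            "tm_c": round(fit.midpoint, 2),
            "dh_kcal_mol": round(vant_hoff_dH(fit), 1),
            "d_half_M": round(lem.d_half, 3),
            "dg0_kcal_mol": round(lem.dg0, 3),
            "m_value": round(lem.m_value, 3),
        })
    return pd.DataFrame(rows), validated, pd.DataFrame(bio_rows)


def _cells_stage(scenario: ScreenScenario, validated_ids: list[str], seed: int):
    cfg = scenario.efflux
    rng = np.random.default_rng(seed + 3)
    wt_net = float(cfg["wt_net_pct"])
    conditions = [
        {"protein": "WT", "net_pct": wt_net},
        {"protein": "L178P", "net_pct": wt_net * float(cfg["mutant_net_fraction"])},
    ]
    for cid in sorted(validated_ids):
        name = scenario.compound_name(cid)
        cc = cfg.get("corrector_conditions", {}).get(name)
        if cc is not None:
            conditions.append({"protein": "L178P", "compound": cid,
                               "conc_mM": float(cc["conc_mM"]),
                               "net_pct": wt_net * float(cc["net_fraction"])})
    pairs = synthetic.simulate_efflux(
        conditions,
        baseline_pct=float(cfg["baseline_pct"]),
        total_cpm=float(cfg["total_cpm"]),
        n_replicates=int(cfg["n_replicates"]),
        noise_pct_sd=float(cfg.get("noise_pct_sd", 0.0)),
        rng=rng,
    )
    rows = []
    nets = {}
    for (plus, minus), cond in zip(pairs, conditions):
        net, sd = net_abca1_efflux(plus, minus)
        key = (cond["protein"], cond.get("compound"))
        nets[key] = (plus.efflux_percents() - minus.efflux_percents(), net)
        rows.append({
            "protein": cond["protein"],
            "compound": cond.get("compound") or "",
            "conc_mM": cond.get("conc_mM", np.nan),
            "net_efflux_pct": round(net, 3),
            "net_efflux_sd": round(sd, 3) if np.isfinite(sd) else np.nan,
        })
    # mutant-vs-WT comparison when both present
    wt_key, mut_key = ("WT", None), ("L178P", None)
    if wt_key in nets and mut_key in nets:
        cmpr = compare_groups(nets[wt_key][0], nets[mut_key][0], labels=("WT", "L178P"))
        for r in rows:
            if r["protein"] == "L178P" and r["compound"] == "":
                r["vs_wt_p"] = np.nan if np.isnan(cmpr.p_value) else float(f"{cmpr.p_value:.3e}")
                r["vs_wt_tier"] = cmpr.tier
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the enabled stages in order, collecting tables and funnel counts.

    A stage failure is recorded and dependent stages are skipped; the bundle
    then carries partial results plus the failure record.
    """
    config.validate()
    scenario = synthetic.load_scenario(config.scenario_path)
    seed = scenario.seed if config.seed is None else int(config.seed)
    alpha = scenario.ans.get("alpha", 0.01) if config.ans_alpha is None else config.ans_alpha
    min_viab = (float(scenario.viability.get("min_viable_pct", 70.0))
                if config.min_viable_pct is None else config.min_viable_pct)

    bundle = ReportBundle()
    funnel = bundle.funnel
    hit_ids: list[str] = []
    ans_pass: list[str] = []
    validated: list[str] = []

    def fail(stage: str, err: Exception) -> None:
        bundle.failures.append({"stage": stage, "error": f"{type(err).__name__}: {err}"})

    if "screen" in config.stages:
        try:
            table, hit_ids, _ = run_screen_stage(scenario, config.criteria, seed)
            bundle.tables["screen"] = table
            funnel["screened"] = len(table)
            funnel["tsa_hits"] = len(hit_ids)
        except Exception as e:  # noqa: BLE001 - stage isolation by design
            fail("screen", e)

    if "ans" in config.stages and not bundle.failures:
        try:
            scenario.ans["alpha"] = alpha
            table, ans_pass = _ans_stage(scenario, hit_ids, seed)
            bundle.tables["ans"] = table
            funnel["ans_confirmed"] = len(ans_pass)
        except Exception as e:  # noqa: BLE001
            fail("ans", e)

    if "validation" in config.stages and not bundle.failures:
        try:
            table, validated, bio = _validation_stage(
                scenario, ans_pass, config.criteria, min_viab, seed)
            bundle.tables["validation"] = table
            bundle.tables["biophysics"] = bio
            funnel["validated"] = len(validated)
        except Exception as e:  # noqa: BLE001
            fail("validation", e)

    if "cells" in config.stages and not bundle.failures:
        try:
            bundle.tables["efflux"] = _cells_stage(scenario, validated, seed)
        except Exception as e:  # noqa: BLE001
            fail("cells", e)

    bundle.manifest = {
        "scenario": scenario.name,
        "seed": seed,
        "stages": list(config.stages),
        "criteria": {
            "min_shift": config.criteria.min_shift,
            "max_wt_gap": config.criteria.max_wt_gap,
            "max_curve_rmsd": config.criteria.max_curve_rmsd,
            "interference_ratio": config.criteria.interference_ratio,
            "ans_alpha": alpha,
            "min_viable_pct": min_viab,
        },
        "funnel": dict(funnel),
        "tables": {name: hashlib.sha256(_table_text(df).encode()).hexdigest()
                   for name, df in bundle.tables.items()},
        "failures": bundle.failures,
    }
    return bundle


def _summary_text(bundle: ReportBundle) -> str:
    f = bundle.funnel
    lines = ["Structure-corrector screening funnel", "=" * 36]
    for label, key in (("compounds screened", "screened"),
                       ("TSA primary hits", "tsa_hits"),
                       ("ANS-confirmed candidates", "ans_confirmed"),
                       ("validated correctors", "validated")):
        if key in f:
            lines.append(f"{label:28s} {f[key]:6d}")
    if bundle.failures:
        lines.append("")
        lines.append("FAILURES:")
        for rec in bundle.failures:
            lines.append(f"  {rec['stage']}: {rec['error']}")
    return "\n".join(lines) + "\n"


def write_report(bundle: ReportBundle, outdir) -> list[Path]:
    """Write per-stage TSVs, a JSON manifest and a plain-text summary.

    Output is byte-stable: rewriting the same bundle reproduces identical
    files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in bundle.tables.items():
        p = out / f"{name}.tsv"
        p.write_text(_table_text(df), encoding="utf-8")
        written.append(p)
    p = out / "manifest.json"
    p.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written.append(p)
    p = out / "summary.txt"
    p.write_text(_summary_text(bundle), encoding="utf-8")
    written.append(p)
    return written
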