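"""Synthetic assay generators for every input the pipeline consumes.

Each generator produces data with exactly the statistical structure the
downstream analysis assumes — two-state van't Hoff unfolding, hyperbolic
one-site binding, proportional count partitioning, additive Gaussian noise —
so that every estimator in the package has a matching noiseless round-trip
oracle.  A :class:`ScreenScenario` bundles all generator parameters; the
packaged ``paper_default`` scenario encodes the study conditions this
pipeline is built around: a 956-compound screen (81 Pfizer-licensed + 875
FDA-approved drugs at 0.1 mM against 5 uM protein), a destabilized mutant
melting at 47 °C versus 65 °C for the wild type, 7+11 planted primary hits
of which 4 correct the ANS hydrophobic-exposure phenotype and 2 survive
dose-response and macrophage-viability gating.

Determinism contract: the same scenario and seed reproduce every artifact
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import numpy as np
import yaml

from .binding import DoseResponseSeries, ITCExperiment, ligand_concentration
from .cellassays import EffluxRecord, ViabilityRecord
from .meltcurves import MeltCurve
from .screening import AnsSpectrum, CompoundRecord
from .thermo import CDThermalScan, ChemDenatSeries, CELSIUS_OFFSET, R_KCAL

__all__ = [
    "ThermoModelParams",
    "LibraryDef",
    "ScreenScenario",
    "ScreenPlates",
    "AssayFixtureSet",
    "make_library_roster",
    "simulate_melt_curve",
    "simulate_screen",
    "simulate_ans_spectrum",
    "simulate_ans_replicates",
    "simulate_cd_thermal",
    "simulate_chem_denat",
    "simulate_tm_dose",
    "simulate_itc",
    "simulate_viability",
    "simulate_efflux",
    "paper_default",
    "load_scenario",
    "default_grid",
]

WELL_ROWS = "ABCDEFGH"
SAMPLE_COLS = 11  # columns 1-11 hold samples; column 12 holds references


@dataclass
class ThermoModelParams:
    """Generative parameters of one protein's dye-monitored melt curve.

    tm_c : transition midpoint, °C (must lie inside the simulated grid).
    dh_vh : van't Hoff enthalpy, kcal/mol (> 0; sets transition sharpness).
    f_base, f_amp : folded-state baseline and unfolded-state amplitude, AU.
    base_slope_f, base_slope_u : linear baseline slopes, AU/°C.
    decay_rate : post-transition signal decay constant, 1/°C (>= 0);
        nonzero values reproduce the peaked shape of real dye melts where
        fluorescence falls again after the transition.
    noise_sd : additive Gaussian noise SD, AU (>= 0).
    """

    tm_c: float
    dh_vh: float
    f_base: float = 1000.0
    f_amp: float = 9000.0
    base_slope_f: float = 0.0
    base_slope_u: float = 0.0
    decay_rate: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.dh_vh <= 0:
            raise ValueError("van't Hoff enthalpy must be positive")
        if self.decay_rate < 0:
            raise ValueError("decay rate must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")


@dataclass
class LibraryDef:
    name: str
    count: int

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValueError(f"library {self.name!r} must have a positive compound count")


@dataclass
class ScreenScenario:
    """Complete parameterization of the synthetic study.

    ``hits`` maps library name -> 1-based compound indices planted as
    structure-correcting (WT-like) wells.  ``named_compounds`` maps a drug
    name to its (library, index) so downstream stages (ANS, dose-response,
    viability, efflux, ITC) can look up its profile.  All remaining keys are
    per-assay parameter blocks; see ``data/paper_default.yaml`` for the
    shipped defaults.
    """

    name: str
    seed: int
    grid: dict[str, float]
    libraries: list[LibraryDef]
    wt: ThermoModelParams
    mutant: ThermoModelParams
    hits: dict[str, list[int]]
    named_compounds: dict[str, dict[str, Any]]
    interference: list[str] = field(default_factory=list)
    ans: dict[str, Any] = field(default_factory=dict)
    dose_response: dict[str, Any] = field(default_factory=dict)
    itc: dict[str, Any] = field(default_factory=dict)
    viability: dict[str, Any] = field(default_factory=dict)
    efflux: dict[str, Any] = field(default_factory=dict)
    chem_denat: dict[str, Any] = field(default_factory=dict)
    cd: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = {lib.name: lib.count for lib in self.libraries}
        for lib, idxs in self.hits.items():
            if lib not in sizes:
                raise ValueError(f"hit list references unknown library {lib!r}")
            if len(idxs) > sizes[lib]:
                raise ValueError(f"more planted hits than compounds in {lib!r}")
            if any(i < 1 or i > sizes[lib] for i in idxs):
                raise ValueError(f"planted hit index out of range for {lib!r}")
        for pname, p in (("wt", self.wt), ("mutant", self.mutant)):
            if not (self.grid["t_min"] < p.tm_c < self.grid["t_max"]):
                raise ValueError(f"{pname} midpoint must lie inside the temperature grid")

    def temperature_grid(self) -> np.ndarray:
        g = self.grid
        n = int(round((g["t_max"] - g["t_min"]) / g["t_step"])) + 1
        return g["t_min"] + g["t_step"] * np.arange(n)

    def compound_name(self, compound_id: str) -> str | None:
        for name, loc in self.named_compounds.items():
            if compound_id == _compound_id(loc["library"], loc["index"]):
                return name
        return None

    def hit_ids(self, library: str | None = None) -> set[str]:
        out: set[str] = set()
        for lib, idxs in self.hits.items():
            if library is None or lib == library:
                out |= {_compound_id(lib, i) for i in idxs}
        return out


@dataclass
class ScreenPlates:
    """One simulated primary screen: sample wells, references, compound-alone wells."""

    samples: list[tuple[CompoundRecord, MeltCurve]]
    wt_refs: dict[int, MeltCurve]
    mut_refs: dict[int, MeltCurve]
    compound_alone: dict[str, MeltCurve]
    scenario: str
    seed: int


@dataclass
class AssayFixtureSet:
    """Named bundle of generated artifacts with provenance metadata."""

    scenario: str
    seed: int
    artifacts: dict[str, Any] = field(default_factory=dict)
    generator_version: str = "1"


def _compound_id(library: str, index: int) -> str:
    return f"{library}-{index:03d}"


def _well_position(i: int) -> tuple[int, str]:
    """Plate (1-based) and well id for the i-th (0-based) compound overall."""
    per_plate = len(WELL_ROWS) * SAMPLE_COLS
    plate = i // per_plate + 1
    j = i % per_plate
    return plate, f"{WELL_ROWS[j // SAMPLE_COLS]}{j % SAMPLE_COLS + 1}"


def make_library_roster(library_defs: list[LibraryDef]) -> list[CompoundRecord]:
    """Lay the libraries out on 96-well plates (88 sample wells per plate).

    Column 12 is reserved for the per-plate WT and mutant reference wells.
    Compound ids are ``<library>-<index>``; the roster length equals the sum
    of the library sizes.
    """
    roster: list[CompoundRecord] = []
    i = 0
    for lib in library_defs:
        for k in range(1, lib.count + 1):
            plate, well = _well_position(i)
            roster.append(CompoundRecord(_compound_id(lib.name, k), lib.name, plate, well))
            i += 1
    return roster


def fraction_unfolded(t_c: np.ndarray, tm_c: float, dh_vh: float) -> np.ndarray:
    """Two-state van't Hoff unfolded fraction at temperatures t_c (°C)."""
    t_k = np.asarray(t_c, dtype=float) + CELSIUS_OFFSET
    tm_k = tm_c + CELSIUS_OFFSET
    u = (dh_vh / R_KCAL) * (1.0 / t_k - 1.0 / tm_k)
    return 1.0 / (1.0 + np.exp(np.clip(u, -500, 500)))


def simulate_melt_curve(
    params: ThermoModelParams,
    grid,
    rng: np.random.Generator | int | None = None,
    well: str = "A1",
    **curve_kwargs,
) -> MeltCurve:
    """Dye-monitored melt curve from the two-state van't Hoff model.

    Fluorescence is a population-weighted mix of the folded baseline and the
    unfolded amplitude, the latter optionally decaying above the midpoint:

        F(T) = (1-f)(f_base + s_f T) + f (f_amp + s_u T) exp(-k max(0, T-Tm))

    with f the unfolded fraction.  At ``decay_rate = 0`` and flat baselines
    the -dF/dT minimum sits exactly at Tm.
    """
    t = np.asarray(grid, dtype=float)
    if len(t) < 5:
        raise ValueError("temperature grid needs at least 5 points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("temperature grid must be strictly increasing")
    if not (t[0] < params.tm_c < t[-1]):
        raise ValueError("midpoint must lie strictly inside the grid")
    rng = np.random.default_rng(rng)
    f = fraction_unfolded(t, params.tm_c, params.dh_vh)
    folded = params.f_base + params.base_slope_f * t
    unfolded = (params.f_amp + params.base_slope_u * t) * np.exp(
        -params.decay_rate * np.maximum(0.0, t - params.tm_c)
    )
    y = (1.0 - f) * folded + f * unfolded
    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, size=len(t))
    meta = dict(curve_kwargs.pop("metadata", {}))
    meta["params"] = params
    return MeltCurve(well=well, temperatures=t, fluorescence=y, metadata=meta, **curve_kwargs)


def simulate_screen(scenario: ScreenScenario, seed: int | None = None) -> ScreenPlates:
    """Simulate the full primary screen defined by the scenario.

    Planted-hit wells melt with WT-like parameters; all other sample wells
    with mutant parameters.  Each plate carries WT (well A12) and mutant
    (B12) reference wells.  Every compound also gets a protein-free
    (compound-alone) well — near-flat unless the compound is on the
    scenario's interference list, in which case it shows a large
    temperature-dependent signal of its own.
    """
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    grid = scenario.temperature_grid()
    roster = make_library_roster(scenario.libraries)
    hit_ids = scenario.hit_ids()
    interference = set(scenario.interference)

    samples: list[tuple[CompoundRecord, MeltCurve]] = []
    compound_alone: dict[str, MeltCurve] = {}
    plates: set[int] = set()
    for rec in roster:
        plates.add(rec.plate)
        params = scenario.wt if rec.compound_id in hit_ids else scenario.mutant
        curve = simulate_melt_curve(
            params, grid, rng, well=rec.well,
            protein="L178P", compound=rec.compound_id, conc_mM=rec.conc_mM,
            metadata={"plate": rec.plate, "role": "sample"},
        )
        samples.append((rec, curve))
        # matching protein-free well
        if rec.compound_id in interference:
            y = 150.0 + 4000.0 / (1.0 + np.exp((55.0 - grid) / 3.0))
        else:
            y = np.full_like(grid, 150.0)
        if scenario.mutant.noise_sd > 0:
            y = y + rng.normal(0.0, scenario.mutant.noise_sd, size=len(grid))
        compound_alone[rec.compound_id] = MeltCurve(
            well=rec.well, temperatures=grid, fluorescence=y,
            compound=rec.compound_id,
            metadata={"plate": rec.plate, "role": "compound_alone"},
        )

    wt_refs: dict[int, MeltCurve] = {}
    mut_refs: dict[int, MeltCurve] = {}
    for plate in sorted(plates):
        wt_refs[plate] = simulate_melt_curve(
            scenario.wt, grid, rng, well="A12", protein="WT",
            metadata={"plate": plate, "role": "wt_ref"},
        )
        mut_refs[plate] = simulate_melt_curve(
            scenario.mutant, grid, rng, well="B12", protein="L178P",
            metadata={"plate": plate, "role": "mut_ref"},
        )
    return ScreenPlates(samples, wt_refs, mut_refs, compound_alone,
                        scenario=scenario.name, seed=seed)


def simulate_ans_spectrum(
    exposure_level: float,
    peak_nm: float = 470.0,
    grid=None,
    rng: np.random.Generator | int | None = None,
    band_sd_nm: float = 40.0,
    noise_sd: float = 0.0,
    **kwargs,
) -> AnsSpectrum:
    """Gaussian ANS emission band scaled by the hydrophobic-exposure level.

    Fixture amplitudes are arbitrary units: only WT/mutant intensity ratios
    carry meaning.  More exposed hydrophobic surface (the destabilized
    mutant) means a brighter band.
    """
    if grid is None:
        grid = np.arange(425.0, 601.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(rng)
    y = exposure_level * np.exp(-0.5 * ((grid - peak_nm) / band_sd_nm) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(grid))
    return AnsSpectrum(grid, y, **kwargs)


def simulate_ans_replicates(
    wt_exposure: float,
    mut_exposure: float,
    n_replicates: int = 3,
    noise_cv: float = 0.02,
    peak_nm: float = 470.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[AnsSpectrum], list[AnsSpectrum]]:
    """Matched WT/mutant replicate spectra with lognormal-free CV noise.

    Replicate-to-replicate scatter multiplies each spectrum's exposure by
    ``1 + N(0, noise_cv)`` — the dominant variability of plate-reader
    fluorescence is a per-well gain, not per-wavelength noise.
    """
    rng = np.random.default_rng(rng)
    wt_reps, mut_reps = [], []
    for _ in range(n_replicates):
        g_wt = wt_exposure * max(1e-6, 1.0 + rng.normal(0.0, noise_cv))
        g_mut = mut_exposure * max(1e-6, 1.0 + rng.normal(0.0, noise_cv))
        wt_reps.append(simulate_ans_spectrum(g_wt, peak_nm, rng=rng, protein="WT"))
        mut_reps.append(simulate_ans_spectrum(g_mut, peak_nm, rng=rng, protein="L178P"))
    return wt_reps, mut_reps


def simulate_cd_thermal(
    theta_native: float,
    theta_unfolded: float,
    tm_c: float,
    dh_vh: float,
    grid=None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> CDThermalScan:
    """theta222 versus temperature from the same two-state van't Hoff model."""
    if grid is None:
        grid = np.arange(20.0, 80.5, 1.0)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(rng)
    f = fraction_unfolded(grid, tm_c, dh_vh)
    y = theta_native + (theta_unfolded - theta_native) * f
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(grid))
    kwargs.setdefault("protein", "WT")
    return CDThermalScan(temperatures=grid, theta222=y, **kwargs)


def simulate_chem_denat(
    dg0: float,
    m_value: float,
    lam_f_nm: float = 335.0,
    lam_u_nm: float = 355.0,
    conc_grid_M=None,
    noise_sd_nm: float = 0.0,
    rng: np.random.Generator | int | None = None,
    temperature_k: float = 298.15,
    **kwargs,
) -> ChemDenatSeries:
    """Tryptophan lambda-max versus GdnHCl from the linear-extrapolation model.

    ``dG(D) = dg0 - m*D``; ``f_u = K/(1+K)`` with ``K = exp(-dG/RT)``;
    lambda-max interpolates linearly between the folded and unfolded bands.
    """
    if dg0 <= 0 or m_value <= 0:
        raise ValueError("dg0 and m-value must be positive")
    if lam_u_nm <= lam_f_nm:
        raise ValueError("unfolded lambda-max must exceed the folded one")
    if conc_grid_M is None:
        conc_grid_M = np.arange(0.0, 6.25, 0.25)
    d = np.asarray(conc_grid_M, dtype=float)
    if len(d) == 0:
        raise ValueError("denaturant grid is empty")
    rng = np.random.default_rng(rng)
    k = np.exp(-(dg0 - m_value * d) / (R_KCAL * temperature_k))
    f_u = k / (1.0 + k)
    lam = lam_f_nm + (lam_u_nm - lam_f_nm) * f_u
    if noise_sd_nm > 0:
        lam = lam + rng.normal(0.0, noise_sd_nm, size=len(d))
    kwargs.setdefault("protein", "WT")
    return ChemDenatSeries(denaturant_M=d, lambda_max_nm=lam, **kwargs)


def simulate_tm_dose(
    ec50_mM: float,
    tm0_c: float,
    dtm_max_c: float,
    concs_mM,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    compound: str = "compound",
    protein: str = "L178P",
) -> DoseResponseSeries:
    """Apparent Tm versus compound concentration from the one-site hyperbola."""
    if ec50_mM <= 0:
        raise ValueError("ec50 must be positive")
    c = np.asarray(concs_mM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    rng = np.random.default_rng(rng)
    tm = tm0_c + dtm_max_c * c / (ec50_mM + c)
    if noise_sd > 0:
        tm = tm + rng.normal(0.0, noise_sd, size=len(c))
    return DoseResponseSeries(compound=compound, protein=protein, conc_mM=c, tm_c=tm)


def simulate_itc(
    ec50_mM: float,
    q_max: float,
    cell_conc_uM: float = 10.0,
    cell_volume_ul: float = 350.0,
    injection_volume_ul: float = 1.0,
    syringe_conc_mM: float = 5.0,
    n_injections: int = 50,
    dilution_heat: float = 0.5,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> ITCExperiment:
    """Titration of ligand into the protein cell plus a matched blank.

    Per-injection heat is the increment of the cumulative hyperbolic heat
    ``Q(c) = q_max*c/(ec50 + c)`` along the perfusion-dilution ligand
    schedule, plus a constant heat of dilution; the blank (drug into buffer)
    carries the dilution term only.
    """
    if min(ec50_mM, cell_conc_uM, cell_volume_ul, injection_volume_ul,
           syringe_conc_mM, n_injections) <= 0:
        raise ValueError("all concentrations, volumes and n_injections must be positive")
    rng = np.random.default_rng(rng)
    vols = np.full(n_injections, float(injection_volume_ul))
    conc = ligand_concentration(cell_volume_ul, syringe_conc_mM, vols)
    q = q_max * conc / (ec50_mM + conc)
    dq = np.diff(np.concatenate([[0.0], q]))
    blank = np.full(n_injections, float(dilution_heat))
    heats = dq + blank
    if noise_sd > 0:
        heats = heats + rng.normal(0.0, noise_sd, size=n_injections)
        blank = blank + rng.normal(0.0, noise_sd, size=n_injections)
    return ITCExperiment(
        cell_volume_ul=cell_volume_ul,
        cell_conc_uM=cell_conc_uM,
        syringe_conc_mM=syringe_conc_mM,
        injection_volumes_ul=vols,
        heats=heats,
        blank_heats=blank,
    )


def simulate_viability(
    dose_effect: dict[float, float],
    n_replicates: int = 3,
    control_absorbance: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    compound: str = "compound",
) -> list[ViabilityRecord]:
    """MTT absorbances proportional to the surviving fraction per dose.

    ``dose_effect`` maps concentration (mM) to the surviving fraction in
    [0, 1]; untreated control wells sit at ``control_absorbance``.
    """
    rng = np.random.default_rng(rng)
    if any(not (0.0 <= f <= 1.0) for f in dose_effect.values()):
        raise ValueError("surviving fractions must lie in [0, 1]")
    controls = np.full(n_replicates, control_absorbance)
    if noise_sd > 0:
        controls = controls + rng.normal(0.0, noise_sd, size=n_replicates)
    records = []
    for conc in sorted(dose_effect):
        a = np.full(n_replicates, control_absorbance * dose_effect[conc])
        if noise_sd > 0:
            a = a + rng.normal(0.0, noise_sd, size=n_replicates)
        records.append(ViabilityRecord(compound, conc, np.clip(a, 0, None), controls.copy()))
    return records


def simulate_efflux(
    conditions: list[dict[str, Any]],
    baseline_pct: float = 4.0,
    total_cpm: float = 50000.0,
    n_replicates: int = 3,
    noise_pct_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[EffluxRecord, EffluxRecord]]:
    """(+cAMP, -cAMP) record pairs partitioning a fixed total count.

    Each condition dict needs ``protein`` and ``net_pct`` (the cAMP-dependent
    efflux in percentage points) and may carry ``compound``/``conc_mM``.
    The -cAMP arm effluxes ``baseline_pct``; the +cAMP arm
    ``baseline_pct + net_pct``.
    """
    rng = np.random.default_rng(rng)

    def make(protein, compound, conc, pct, camp):
        p = np.full(n_replicates, pct)
        if noise_pct_sd > 0:
            p = p + rng.normal(0.0, noise_pct_sd, size=n_replicates)
        p = np.clip(p, 0.0, 100.0)
        med = total_cpm * p / 100.0
        return EffluxRecord(protein=protein, camp_treated=camp, cpm_medium=med,
                            cpm_cells=total_cpm - med, compound=compound, conc_mM=conc)

    out = []
    for cond in conditions:
        protein = cond["protein"]
        compound = cond.get("compound")
        conc = cond.get("conc_mM")
        plus = make(protein, compound, conc, baseline_pct + cond["net_pct"], True)
        minus = make(protein, compound, conc, baseline_pct, False)
        out.append((plus, minus))
    return out


def default_grid() -> np.ndarray:
    """The default 20-80 °C, 0.5 °C-step melt grid."""
    return 20.0 + 0.5 * np.arange(121)


def _params_from_dict(d: dict[str, Any]) -> ThermoModelParams:
    return ThermoModelParams(**d)


def load_scenario(path=None) -> ScreenScenario:
    """Load a scenario from YAML; defaults to the packaged ``paper_default``."""
    if path is None:
        text = (resources.files("apostab") / "data" / "paper_default.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return ScreenScenario(
        name=raw["name"],
        seed=int(raw["seed"]),
        grid={k: float(v) for k, v in raw["grid"].items()},
        libraries=[LibraryDef(**d) for d in raw["libraries"]],
        wt=_params_from_dict(raw["proteins"]["wt"]),
        mutant=_params_from_dict(raw["proteins"]["mutant"]),
        hits={k: list(v) for k, v in raw["hits"].items()},
        named_compounds=raw.get("named_compounds", {}),
        interference=list(raw.get("interference", [])),
        ans=raw.get("ans", {}),
        dose_response=raw.get("dose_response", {}),
        itc=raw.get("itc", {}),
        viability=raw.get("viability", {}),
        efflux=raw.get("efflux", {}),
        chem_denat=raw.get("chem_denat", {}),
        cd=raw.get("cd", {}),
    )


def paper_default() -> ScreenScenario:
    """The packaged default scenario mirroring the study's printed conditions."""
    return load_scenario(None)
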