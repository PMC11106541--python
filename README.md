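# apostab

Analytics for discovering and validating small-molecule **structure
correctors** of a destabilized apolipoprotein A-I variant (apoA-I[L178P]),
covering the full screening funnel:

1. **Primary thermal shift assay (TSA/DSF) screen** — apparent melting
   temperatures called from SYPRO-Orange melt curves by smoothing, the
   negative first derivative −dF/dT, and its minimum; hits are compounds
   that make the mutant melt like the wild type.
2. **ANS orthogonal screen** — the WT/mutant ratio of
   8-anilinonaphthalene-1-sulfonate peak fluorescence reports hydrophobic
   surface exposure; correctors raise the ratio toward 1.
3. **Biophysical validation** — Boltzmann two-state fits of thermal (CD
   θ₂₂₂) and chemical (Trp λ_max vs GdnHCl) denaturation, apparent van't
   Hoff enthalpy ΔH = R·Tm²/a, linear-extrapolation free energies
   ΔG_D° and m-values, and one-site EC₅₀ fits of Tm dose-responses and
   blank-corrected ITC titrations, response(c) = base + amp·c/(EC₅₀ + c).
4. **Cell assays** — MTT viability normalization and ABCA1-mediated
   (cAMP-dependent) cholesterol efflux, % efflux = 100·cpm_med/(cpm_med +
   cpm_cells), with Welch-test group comparisons.

A synthetic-data module generates every assay input with the statistical
structure the analysis assumes, so the whole pipeline runs end-to-end with
no external data.  The packaged `paper_default` scenario encodes the study
conditions the package targets: a 956-compound marketed-drug library
(81 + 875) screened at 0.1 mM against 5 µM protein, a mutant melting at
47 °C versus 65 °C for WT, 18 planted primary hits, 4 ANS-confirmed
candidates, and 2 validated correctors (atorvastatin, bexarotene).

The two nonlinear fitters at the core — `BoltzmannSigmoid` and
`HyperbolicBinding` — are scikit-learn-style estimators (`fit`/`predict`,
`get_params`, fitted attributes ending in `_`) and compose with sklearn
tooling; the module-level functions (`boltzmann_fit`, `fit_tm_dose`,
`fit_itc`, …) are thin wrappers over them.

## Worked example

```python
import numpy as np
from apostab import paper_default, tm_from_curve, fit_tm_dose
from apostab.synthetic import simulate_melt_curve, simulate_tm_dose

scen = paper_default()
grid = scen.temperature_grid()            # 20-80 °C at 0.5 °C steps

mut = simulate_melt_curve(scen.mutant, grid)
wt = simulate_melt_curve(scen.wt, grid)
print(round(tm_from_curve(mut).tm_c, 1))  # 46.6   (mutant apparent Tm, °C)
print(round(tm_from_curve(wt).tm_c, 1))   # 64.8   (WT apparent Tm, °C)

dose = simulate_tm_dose(0.32, 47.0, 18.0, [0, 0.01, 0.05, 0.1, 0.2, 0.5])
print(round(fit_tm_dose(dose).ec50_mM, 3))  # 0.32  (EC50, mM)
```

The mutant melts ~18 °C below the wild type; the dose-response fit returns
the half-saturating corrector concentration.  The full funnel runs from the
command line:

```bash
apostab report --outdir out/ --seed 1
```

which prints the stage counts (956 screened → 18 TSA hits → 4
ANS-confirmed → 2 validated correctors) and writes per-stage TSV tables, a
JSON manifest with table hashes, and a plain-text summary to `out/`.

## Layout

- `apostab.synthetic` — assay generators + the `paper_default` scenario
- `apostab.meltcurves` — smoothing, −dF/dT, Tm calling with quality flags
- `apostab.screening` — hit criteria, curve-similarity RMSD, ANS ratio test
- `apostab.thermo` — helicity, two-state fits, van't Hoff ΔH, LEM ΔG_D°
- `apostab.binding` — Tm-dose and ITC EC₅₀ fitting, dilution bookkeeping
- `apostab.cellassays` — viability %, efflux %, net ABCA1 efflux, Welch tests
- `apostab.pipeline` / `apostab.cli` — orchestration, report bundle, CLI
- `docs/methods.md` — models, assumptions, parameter defaults, limitations
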