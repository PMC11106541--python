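# Methods

This note documents the models, estimators and design choices behind
`apostab`, in the spirit of a statistical methods appendix: what is
computed, under which assumptions, and what the synthetic fixtures do and
do not establish about real instrument data.

## Melt-curve model and Tm calling

A dye-monitored melt curve is generated from a two-state van't Hoff
equilibrium.  With temperatures in Kelvin, the unfolded fraction is

    f(T) = 1 / (1 + exp[(ΔH_vH/R)(1/T − 1/Tm)])

(R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹; all interfaces use °C, converted by
T_K = T_C + 273.15).  Fluorescence mixes a folded baseline and an unfolded
amplitude, each optionally with a linear slope, and the unfolded signal may
decay exponentially above the midpoint:

    F(T) = (1−f)(F_b + s_f·T) + f·(F_a + s_u·T)·exp(−k·max(0, T−Tm)) + ε

The decay term reproduces the peaked shape of real SYPRO-Orange melts
(dye release from aggregating unfolded protein); with k = 0 and flat
baselines the −dF/dT minimum is exactly invertible to Tm, which is why the
default fixtures set k = 0.  Noise ε is additive i.i.d. Gaussian per point;
heteroscedastic or autocorrelated instrument noise is not modeled.

Tm calling follows instrument practice: Savitzky–Golay smoothing (window 7,
order 2 — no smaller window suppresses plate-reader noise, no larger one
distorts the transition at 0.5 °C steps), −dF/dT by central divided
differences (one-sided at the ends, non-uniform grids supported), and the
global minimum of −dF/dT inside a search window that excludes 2 °C at each
end of the ramp (edge minima are artifacts of one-sided differences).  A
3-point parabola refines the grid minimum, removing grid-step bias without
fit assumptions.  Quality flags: `flat_curve` (no call) when the curve's
dynamic range falls below 5% of the plate's median sample range — this is
what keeps dye-only and compound-only wells out of the Tm table —
`edge_minimum`, and `multiple_minima` when a second local minimum comes
within 10% of the global depth (the global minimum is reported, never an
average).

Because SG(7,2) is exact only on local quadratics, smoothing perturbs even
a noiseless sigmoid slightly; on the default fixture the maximum change is
0.06 AU against a 7,900 AU range, three orders of magnitude below any
realistic noise floor.

Default thermodynamic parameters: mutant Tm 47 °C, WT Tm 65 °C (the 18 °C
stability gap between the variant and the wild type); ΔH_vH 35 kcal/mol
(mutant) and 55 kcal/mol (WT) — molten-globule-like apolipoprotein
transitions are broad, and the destabilized variant is the less cooperative
of the two.  Derivative calling on the van't Hoff curve carries a small
systematic offset (the 1/T² factor skews the derivative peak below Tm by
~0.4 °C at ΔH = 35), which is why called values are reported to 0.1 °C and
compared at one-grid-step tolerance.

## Screening

A compound is a primary hit when the mutant+compound well satisfies all of:
Tm shift over the mutant reference ≥ 5 °C, |Tm − Tm(WT)| ≤ 5 °C, and
min–max-normalized curve RMSD versus the WT reference ≤ 0.10 (the
normalization makes the comparison invariant to vertical affine transforms;
the default WT-vs-mutant fixtures sit at RMSD 0.38).  Wells whose
protein-free (compound-alone) twin shows a dynamic range above 0.5× the
median sample range are excluded as compound interference.  All four
thresholds are configuration-exposed; hit calling is deterministic and
order-independent, and monotone in the thresholds.

The ANS orthogonal screen computes, per replicate pair, the ratio of WT to
mutant peak intensity — each protein's own smoothed spectrum maximum, so the
statistic is robust to small peak-wavelength shifts and to any common
scaling.  The destabilized mutant exposes roughly twice the hydrophobic
surface (default exposure 2.0 vs 1.0, arbitrary units — only ratios are
meaningful), so the ratio sits near 0.5 without compound and near 0.95 when
a corrector restores the mutant fold.  Candidates pass when a Welch
two-sample t-test of compound ratios against no-compound control ratios
gives p < 0.01 with the mean increased.  Replicate scatter is a per-well
gain factor 1 + N(0, 2%); it is deliberately nonzero even in the otherwise
noiseless default scenario because a zero-variance t-test is undefined.

## Two-state thermodynamics

Percent α-helix from mean residue ellipticity uses the linear calibration
%helix = (−[Θ]₂₂₂ + 3,000)/(36,000 + 3,000) × 100, clamped to [0, 100] with
a flag; a machine-units conversion [Θ] = θ·MRW/(10·l·c) with MRW 115.4
(243-residue apoA-I) is available at ingestion.

Thermal and chemical transitions are fitted with the Boltzmann sigmoid
y = y_pre + (y_post − y_pre)/(1 + exp((x₅₀ − x)/a)) by bounded nonlinear
least squares, initialized from data quantiles (x₅₀ at half dynamic range,
a at range/10) with sign-agnostic orientation; non-convergence returns a
flagged object rather than raising, so plate-scale batch fits never abort.
Sloped baselines are fit for CD thermal scans (real θ₂₂₂ baselines drift)
and off for Trp λ_max (a bounded observable).

The apparent van't Hoff enthalpy is ΔH = R·Tm_K²/a_K: at the midpoint
d ln K/dT = 1/a for a Boltzmann transition, and ΔH = R·T²·d ln K/dT.  It
depends only on the transition's location and width in temperature units —
invariant to the observable's scale — and is labeled *apparent/relative*
in outputs.  Note a deliberate asymmetry: the generator is logistic in 1/T
(van't Hoff) while the fitted sigmoid is logistic in T (field convention),
so the round-trip is not an identity.  The residual bias is < 2% for
transitions whose unfolded baseline is adequately sampled when the fit's
baseline model matches the data's (flat here); adding baseline slopes to a
flat-baseline curve inflates the width bias to ~2.2% for the WT profile,
whose transition at 65 °C leaves only 15 °C of post-transition baseline in
a 20–80 °C scan.

Chemical denaturation uses the linear extrapolation model
ΔG(D) = ΔG_D° − m·D.  Per-point unfolded fractions come from the fitted
baselines; points with f_u ∈ (0.1, 0.9) (outside this window the log-ratio
amplifies baseline error) define K = f_u/(1−f_u) and ΔG = −RT ln K at
25 °C (298.15 K — the measurement temperature; the free energies refer to
it), regressed linearly on D: intercept ΔG_D°, negated slope m.  The
identity ΔG_D° = m·D½ holds exactly on noiseless series and to a few
tenths of a percent under 0.3 nm λ_max noise.  Defaults: WT ΔG_D° 5.0
kcal/mol, m 2.0 kcal·mol⁻¹·M⁻¹ (D½ 2.5 M); mutant 2.6/2.0 (D½ 1.3 M) —
typical exchangeable-apolipoprotein stabilities with the mutant roughly
half as stable.

## Binding

Both response families use the one-site hyperbola on *total* ligand
concentration, response(c) = baseline + amplitude·c/(EC₅₀ + c) — no
free-ligand correction and no stoichiometry parameter, consistent with
reporting an EC₅₀ rather than Kd/n.  Tm dose-responses are weighted by
1/SD² when replicate SDs are present; the zero-dose baseline can be pinned.

ITC bookkeeping uses the perfusion (overflow) convention: the cell volume V
is constant and each injection of volume v attenuates the cell contents by
(1 − v/V) while adding (v/V)·c_syringe; stated explicitly because
instrument conventions differ (the volume-addition convention differs by
v/V ≈ 0.3% per injection here).  Raw per-injection heats are corrected by
subtracting a drug-into-buffer blank injection-for-injection, then the
cumulative corrected heat is fitted to Q(c) = q_max·c/(EC₅₀ + c) through
the origin; the per-injection (increment) form is kept as an internal
cross-check and agrees exactly on noiseless data.  Fits are flagged
`extrapolated` when the titration never reaches the fitted EC₅₀.  The
default schedule — 50 × 1 µl injections of 5 mM (atorvastatin) or 2 mM
(bexarotene) stock into a 350 µl cell of 10 µM protein — sweeps the cell
concentration to ~0.67/0.27 mM, through both default EC₅₀s (0.40 and
0.098 mM).

EC₅₀ estimation from a saturating design is well-conditioned only when the
EC₅₀ lies inside the dose grid.  On the default 0–0.5 mM grid with 2%
response noise and quadruplicate means, the interior EC₅₀ (0.059 mM)
recovers with ~4% median bias; an EC₅₀ above the second-highest dose
(0.32 mM) cannot do better than ~7–8% under the same design — a property of
hyperbolic regression, not of the implementation.

## Cell assays

Viability is 100 × absorbance / control mean per replicate, summarized as
mean ± SD; efflux is 100 × cpm_medium/(cpm_medium + cpm_cells), bounded in
[0, 100] and invariant to count scaling; net ABCA1-mediated efflux is
mean(+cAMP) − mean(−cAMP) with independent-group quadrature SD.  Group
comparisons use Welch's t-test with significance tiers at 0.05/0.005/0.0001;
per-comparison reporting is the default (no multiplicity correction),
matching single-contrast assay practice — a Holm option exists for users
comparing many conditions.  Efflux defaults: background (−cAMP) efflux 4%,
WT net efflux 10 percentage points, mutant net efflux 0.65× WT; correctors
at their optimum concentration restore the mutant to the WT level.
Viability defaults encode bexarotene's 25%/75% reductions at 0.2/0.5 mM,
adapalene's toxicity at every tested concentration, and no effect for
atorvastatin or lovastatin.

## Pipeline and funnel

Stages run in campaign order: screen → ANS → validation → cells.  The
validation gate operationalizes the narrative criteria a campaign applies:
a candidate is validated iff (a) its Tm dose-response fit converges with
saturating amplitude ≥ the hit-calling shift threshold, and (b) viability
is ≥ 70% at at least one concentration whose predicted Tm shift meets that
threshold.  Under the default scenario this removes lovastatin (flat dose-
response) and adapalene (toxic at all effective concentrations), leaving
atorvastatin and bexarotene — the 956 → 18 → 4 → 2 funnel.  Stage failures
are recorded and dependent stages skipped; the report bundle (TSV tables,
JSON manifest with SHA-256 table hashes, text summary) is byte-stable under
a fixed scenario and seed.

## What the synthetic fixtures do and do not show

The generators produce exactly the structure the estimators assume:
two-state transitions, one-site binding, proportional count partitioning,
Gaussian noise.  Passing tests therefore demonstrate correctness of the
analysis chain (including exact noiseless parameter recovery and the
stated noise robustness), not robustness to phenomena the generators omit:
multi-state unfolding, aggregation kinetics, dye photophysics,
heteroscedastic or drifting instrument response, plate positional effects,
or compound absorbance overlapping the ANS band.  The planted-hit screen is
idealized — hit wells melt with exactly WT-like parameters; partial
correction levels are configurable but default to binary.

## Problem sizes

Default analyses are desk-scale by construction: the full 956-well screen
with per-well derivative calling and curve RMSD runs in ~2 s; the 200-seed
robustness simulations in the test suite run in under a minute; the whole
suite completes in well under a minute on one core.
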