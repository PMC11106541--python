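# Default scenario: the study conditions the pipeline is built around.
# A 956-compound marketed-drug screen (81 Pfizer-licensed + 875 FDA-approved,
# 0.1 mM compound vs 5 uM protein) against a destabilized apoA-I variant
# melting at 47 C, 18 C below the wild type.  7 + 11 planted primary hits;
# 4 correct the ANS hydrophobic-exposure phenotype; 2 (atorvastatin,
# bexarotene) survive dose-response and macrophage-viability gating.
name: paper_default
seed: 197802  # L178P -> arbitrary fixed default; override per run

grid:
  t_min: 20.0
  t_max: 80.0
  t_step: 0.5

libraries:
  - {name: Pfizer, count: 81}
  - {name: FDA, count: 875}

proteins:
  # Melt-curve model: two-state van't Hoff fraction x linear state baselines
  # x optional post-transition decay.  Noiseless defaults; the acceptance
  # fixtures use decay_rate 0 so derivative Tm calling is exactly invertible.
  wt:     {tm_c: 65.0, dh_vh: 55.0, f_base: 1000.0, f_amp: 9000.0,
           base_slope_f: 0.0, base_slope_u: 0.0, decay_rate: 0.0, noise_sd: 0.0}
  mutant: {tm_c: 47.0, dh_vh: 35.0, f_base: 1000.0, f_amp: 9000.0,
           base_slope_f: 0.0, base_slope_u: 0.0, decay_rate: 0.0, noise_sd: 0.0}

# 1-based compound indices within each library planted as WT-like wells.
hits:
  Pfizer: [8, 19, 30, 41, 52, 63, 74]
  FDA: [44, 101, 178, 245, 333, 410, 497, 564, 651, 738, 825]

named_compounds:
  atorvastatin: {library: Pfizer, index: 8}
  bexarotene:   {library: FDA, index: 44}
  adapalene:    {library: FDA, index: 101}
  lovastatin:   {library: FDA, index: 178}

interference: []

ans:
  # 310 uM ANS with 2.2 uM protein, em 425-600 nm / ex 395 nm.  Amplitudes
  # are arbitrary units; only the WT/mutant ratio matters.  The destabilized
  # mutant exposes ~2x the hydrophobic surface of WT.
  wt_exposure: 1.0
  mut_exposure: 2.0
  corrected_exposure: 1.05  # mutant + corrector: near-WT exposure
  peak_nm: 470.0
  n_replicates: 3
  noise_cv: 0.02
  alpha: 0.01
  correctors: [atorvastatin, bexarotene, adapalene, lovastatin]

dose_response:
  concs_mM: [0.0, 0.01, 0.05, 0.1, 0.2, 0.5]
  noise_sd: 0.0
  profiles:
    atorvastatin: {ec50_mM: 0.32, dtm_max_c: 18.0}
    bexarotene:   {ec50_mM: 0.059, dtm_max_c: 18.0}
    adapalene:    {ec50_mM: 0.05, dtm_max_c: 18.0}
    lovastatin:   {ec50_mM: 0.10, dtm_max_c: 0.0}   # no dose-dependent correction

itc:
  # 10 uM protein in a 350 ul cell, 1 ul injections, drug-into-buffer blanks.
  cell_volume_ul: 350.0
  cell_conc_uM: 10.0
  injection_volume_ul: 1.0
  n_injections: 50
  dilution_heat: 0.5
  noise_sd: 0.0
  profiles:
    atorvastatin: {syringe_conc_mM: 5.0, ec50_mM: 0.40, q_max: 100.0}
    bexarotene:   {syringe_conc_mM: 2.0, ec50_mM: 0.098, q_max: 60.0}

viability:
  n_replicates: 3
  control_absorbance: 1.0
  noise_sd: 0.0
  min_viable_pct: 70.0
  profiles:  # conc (mM) -> surviving fraction of control
    atorvastatin: {0.05: 1.0, 0.1: 1.0, 0.2: 1.0, 0.5: 1.0}
    bexarotene:   {0.01: 1.0, 0.05: 1.0, 0.1: 1.0, 0.2: 0.75, 0.5: 0.25}
    adapalene:    {0.01: 0.40, 0.05: 0.30, 0.1: 0.20, 0.2: 0.10, 0.5: 0.05}
    lovastatin:   {0.01: 1.0, 0.05: 1.0, 0.1: 1.0, 0.2: 1.0, 0.5: 1.0}

efflux:
  # 1 uM protein acceptor, +/- cpt-cAMP; mutant net efflux 0.65x WT.
  baseline_pct: 4.0
  wt_net_pct: 10.0
  mutant_net_fraction: 0.65
  total_cpm: 50000.0
  n_replicates: 3
  noise_pct_sd: 0.0
  corrector_conditions:  # mutant + compound at its optimum: fully restored
    atorvastatin: {conc_mM: 0.2, net_fraction: 1.0}
    bexarotene:   {conc_mM: 0.05, net_fraction: 1.0}

chem_denat:
  # Intrinsic tryptophan lambda-max vs GdnHCl (310-420 nm observation band).
  lam_f_nm: 335.0
  lam_u_nm: 355.0
  conc_max_M: 6.0
  conc_step_M: 0.25
  noise_sd_nm: 0.0
  profiles:
    wt:     {dg0: 5.0, m_value: 2.0}
    mutant: {dg0: 2.6, m_value: 2.0}

cd:
  # theta222 thermal scans, 20-80 C at 1 C steps.
  noise_sd: 0.0
  profiles:
    wt:     {theta_native: -18450.0, theta_unfolded: -4000.0, tm_c: 65.0, dh_vh: 55.0}
    mutant: {theta_native: -13000.0, theta_unfolded: -4000.0, tm_c: 47.0, dh_vh: 35.0}
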