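# Reference parameter set for the sunitinib/GIST simulation framework.
#
# Units convention (package-wide): time h, concentration ng/ml, dose mg,
# volumes L, clearances L/h, cell counts 1e9 cells/L, tumor SLD mm, dBP mmHg.
#
# Model structures follow the published source models named in each
# provenance entry; values are representative magnitudes fixed once at
# design time (see docs/methods.md). Nothing here is estimated from data.

drug: sunitinib

fixed_effects:
  # --- PK: parent + active metabolite (SU12662), 1-cpt each, 1st-order absorption
  ka: 0.195            # 1/h
  cl_parent: 51.8      # L/h (apparent, at reference weight)
  v_parent: 2030.0     # L
  fm: 0.21             # fraction of parent clearance forming SU12662
  cl_met: 29.6         # L/h
  v_met: 3080.0        # L
  wt_ref: 70.0         # kg, reference weight for allometry
  wt_exp_cl: 0.75      # allometric exponent on clearances
  wt_exp_v: 1.0        # allometric exponent on volumes
  # --- sVEGFR-3: indirect response, Imax inhibition of k_in by total conc
  base_svegfr3: 63.9   # ng/ml
  mrt_svegfr3_h: 100.0 # mean residence time = 1/k_out
  imax_svegfr3: 1.0
  ic50_svegfr3: 75.0   # ng/ml total (sunitinib + SU12662)
  # --- sKIT: indirect response, slower turnover
  base_skit: 39.9      # ng/ml
  mrt_skit_h: 1200.0
  imax_skit: 1.0
  ic50_skit: 20.0
  # --- ANC: transit-compartment myelosuppression, drive = sVEGFR-3 rel. decrease
  base_anc: 5.0        # 1e9 cells/L (population baseline)
  mtt_anc_h: 135.0     # mean transit time over 3 transit compartments
  gamma_anc: 0.17      # feedback exponent (base/circ)^gamma
  slope_anc: 0.24      # proliferation inhibition per unit rel. sVEGFR-3 decrease
  # --- Platelets: transit-compartment model, drive = daily total AUC
  base_plt: 240.0      # 1e9 cells/L
  mtt_plt_h: 135.0
  gamma_plt: 0.17
  emax_plt: 0.21       # maximal proliferation inhibition by daily AUC
  auc50_plt: 1000.0    # ng*h/ml daily AUC at half-maximal inhibition
  # --- Diastolic BP: indirect response, linear stimulation of k_in by daily AUC
  base_dbp: 78.0       # mmHg
  mrt_dbp_h: 96.0
  slope_dbp: 7.0e-5    # fractional k_in stimulation per (ng*h/ml) daily AUC
  # --- Fatigue: proportional-odds Markov model (grades 0-3), daily evaluation
  fat_int_g1: -4.6     # logit intercept for P(grade >= 1)
  fat_int_g2: -12.0
  fat_int_g3: -13.5
  fat_beta_v3: 2.0     # effect of rel. sVEGFR-3 decrease on the linear predictor
  fat_kappa: 2.5       # Markov dependence per unit previous grade
  # --- Hand-foot syndrome: proportional-odds Markov model (grades 0-3)
  hfs_int_g1: -5.2
  hfs_int_g2: -11.1
  hfs_int_g3: -12.5
  hfs_beta_v3: 2.8
  hfs_kappa: 3.2
  # --- Tumor growth inhibition with exponential resistance on the kill term
  tum_kg: 2.0e-4       # 1/h net growth rate
  tum_kv3: 6.0e-4      # kill per unit rel. sVEGFR-3 decrease, 1/h
  tum_kskit: 1.0e-4    # kill per unit rel. sKIT decrease, 1/h
  tum_kauc_max: 3.0e-4 # maximal AUC-driven kill, 1/h
  tum_auc50: 1000.0    # ng*h/ml daily AUC at half-maximal kill
  tum_lambda_res: 1.2e-4  # 1/h resistance appearance rate
  tum_tmax: 1200.0     # mm carrying capacity of SLD growth
  # --- OS, toxicity-driven model (TAD): Weibull baseline x exp(lp)
  os_tad_weib_scale_h: 9400.0
  os_tad_weib_shape: 1.2
  os_tad_beta_dbp: -3.0    # per unit rel. dBP increase (rise = response marker)
  os_tad_beta_anc: 2.7     # per unit scaled ANC change (drop = response marker)
  os_tad_beta_bsld: 0.004  # per mm baseline SLD above reference
  # --- OS, sVEGFR-3-driven model (BAD)
  os_bad_weib_scale_h: 11500.0
  os_bad_weib_shape: 1.2
  os_bad_beta_v3: 2.5      # per unit rel. sVEGFR-3 change (decrease lowers hazard)
  os_bad_beta_bsld: 0.004
  bsld_ref: 182.7          # mm, centering constant for baseline SLD
  # --- Dropout: exponential baseline, progression + tumor size covariates
  drop_lambda_h: 2.0e-5
  drop_beta_prog: 0.7
  drop_beta_sld: 0.1       # per 100 mm current SLD

iiv:   # variances of log-normal inter-individual random effects
  cl_parent: 0.152
  v_parent: 0.10
  ka: 0.30
  cl_met: 0.10
  base_svegfr3: 0.06
  ic50_svegfr3: 0.25
  base_skit: 0.05
  ic50_skit: 0.25
  base_anc: 0.05
  slope_anc: 0.20
  mtt_anc_h: 0.03
  base_plt: 0.06
  emax_plt: 0.20
  base_dbp: 0.01
  slope_dbp: 0.25
  tum_kg: 0.15
  tum_kv3: 0.20

residual_errors:   # y = f*(1 + eps_prop) + eps_add
  conc:      {proportional: 0.30, additive: 0.0}
  svegfr3:   {proportional: 0.20, additive: 0.0}
  skit:      {proportional: 0.20, additive: 0.0}
  anc:       {proportional: 0.30, additive: 0.0}
  platelets: {proportional: 0.25, additive: 0.0}
  dbp:       {proportional: 0.06, additive: 0.0}

provenance:
  ka: "structure/magnitude after Houk et al. 2009 popPK of sunitinib and SU12662"
  cl_parent: "after Houk et al. 2009"
  v_parent: "after Houk et al. 2009"
  fm: "after Houk et al. 2009"
  cl_met: "after Houk et al. 2009"
  v_met: "after Houk et al. 2009"
  wt_ref: "package allometry convention"
  wt_exp_cl: "standard allometric exponent"
  wt_exp_v: "standard allometric exponent"
  base_svegfr3: "structure after Hansson et al. 2013 (indirect response)"
  mrt_svegfr3_h: "after Hansson et al. 2013, representative"
  imax_svegfr3: "full inhibition assumed"
  ic50_svegfr3: "representative, typical 37.5 mg suppression ~35% (sub-saturating)"
  base_skit: "after Hansson et al. 2013"
  mrt_skit_h: "after Hansson et al. 2013, representative"
  imax_skit: "full inhibition assumed"
  ic50_skit: "representative"
  base_anc: "population baseline 5e9 cells/L"
  mtt_anc_h: "after Friberg et al. 2002 myelosuppression model"
  gamma_anc: "after Friberg et al. 2002"
  slope_anc: "representative, typical steady-state ANC ~2.6e9 cells/L"
  base_plt: "representative normal platelet count"
  mtt_plt_h: "after Friberg et al. 2002"
  gamma_plt: "after Friberg et al. 2002"
  emax_plt: "Emax exposure-effect, representative (mild typical thrombocytopenia)"
  auc50_plt: "representative"
  base_dbp: "representative normotensive baseline"
  mrt_dbp_h: "representative BP turnover"
  slope_dbp: "linear AUC-dBP relationship, representative"
  fat_int_g1: "proportional-odds Markov structure after Hansson et al. 2013"
  fat_int_g2: "see fat_int_g1"
  fat_int_g3: "see fat_int_g1"
  fat_beta_v3: "see fat_int_g1"
  fat_kappa: "see fat_int_g1"
  hfs_int_g1: "proportional-odds Markov structure after Hansson et al. 2013"
  hfs_int_g2: "see hfs_int_g1"
  hfs_int_g3: "see hfs_int_g1"
  hfs_beta_v3: "see hfs_int_g1"
  hfs_kappa: "see hfs_int_g1"
  tum_kg: "TGI structure after Claret et al. 2009; representative GIST growth"
  tum_kv3: "representative"
  tum_kskit: "representative"
  tum_kauc_max: "Emax exposure-effect, representative"
  tum_auc50: "representative"
  tum_lambda_res: "representative resistance kinetics"
  tum_tmax: "saturating growth, representative maximal tumor burden"
  os_tad_weib_scale_h: "design-time calibration, see docs/methods.md"
  os_tad_weib_shape: "design-time calibration"
  os_tad_beta_dbp: "sign per toxicity-response association"
  os_tad_beta_anc: "sign per toxicity-response association"
  os_tad_beta_bsld: "larger baseline tumor -> worse OS"
  os_bad_weib_scale_h: "design-time calibration, see docs/methods.md"
  os_bad_weib_shape: "design-time calibration"
  os_bad_beta_v3: "sVEGFR-3 decrease -> better OS"
  os_bad_beta_bsld: "larger baseline tumor -> worse OS"
  bsld_ref: "population mean baseline SLD"
  drop_lambda_h: "representative background discontinuation"
  drop_beta_prog: "progression raises dropout"
  drop_beta_sld: "tumor burden raises dropout"
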